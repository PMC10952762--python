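#!/usr/bin/env python
"""Correlation structure of candidate summaries and of the biotic indices.

Reads the design matrix and index table written by 03, computes pairwise
Pearson correlations within determinands (across windows) and within
windows (across determinands), the per-determinand-pair averages, and the
inter-index relationships (pooled and site-adjusted).  The index
inter-correlations show the common-sensitivity effect: indices built on
the same community composition co-vary even though they target different
stressors.
"""
from pathlib import Path

import pandas as pd

from bioassess.correlations import (average_correlations,
                                    index_pairwise_relationships,
                                    pearson_pairwise)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    design = pd.read_csv(ROOT / "scratch" / "design_matrix.csv")
    indices = pd.read_csv(out / "indices_study.csv")

    across = pearson_pairwise(design, "within_window_across_determinands")
    averages = average_correlations(across)
    averages.to_csv(out / "correlation_averages.csv", index=False,
                    float_format="%.3f")

    rel = index_pairwise_relationships(
        indices, ["aspt_whpt", "life", "psi", "epsi", "cofsi", "trpi",
                  "spear", "ntaxa_whpt", "log_abundance"])
    rel.to_csv(out / "index_relationships.csv", index=False,
               float_format="%.4f")

    print("determinand-pair average correlations:")
    print(averages.to_string(index=False))
    strongest = rel.loc[rel["r_pooled"].abs().idxmax()]
    print(f"\nstrongest index pair: {strongest['index_x']} ~ "
          f"{strongest['index_y']}  r={strongest['r_pooled']:.3f}")


if __name__ == "__main__":
    main()
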