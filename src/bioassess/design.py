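"""Assembly of the driver-selection design matrix.

One row per replicate kick sample; one candidate column per
(determinand, statistic, window) triple, named with the grammar
``{determinand}__{statistic}__{window}d``; plus the structural identifier
columns ``site_id``, ``sample_date``, ``occasion`` and ``replicate_id``.
Replicates are kept as separate rows.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import BioSample, HydroSeries, SummarySpec
from .windows import DEFAULT_MIN_COVERAGE, extract_window, summarise_window
from .types import STATISTICS

__all__ = ["candidate_name", "parse_candidate_name", "build_design_matrix",
           "ID_COLUMNS"]

log = logging.getLogger(__name__)

ID_COLUMNS = ["site_id", "sample_date", "occasion", "replicate_id"]


def candidate_name(determinand: str, statistic: str, window_days: int) -> str:
    return f"{determinand}__{statistic}__{window_days}d"


def parse_candidate_name(name: str) -> tuple[str, str, int]:
    det, stat, wind = name.split("__")
    return det, stat, int(wind.removesuffix("d"))


def build_design_matrix(
    bio_samples: list[BioSample],
    hydro_series: list[HydroSeries],
    specs: list[SummarySpec],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_missing_fraction: float = 0.5,
    standardize: bool = False,
) -> pd.DataFrame:
    """Design table linking biological samples to antecedent summaries.

    Candidate columns missing in more than ``max_missing_fraction`` of rows
    are dropped (and logged).  With ``standardize=True`` the surviving
    candidates are z-scored so that every summary statistic enters the
    selection on an equal footing.

    Raises ``ValueError`` listing orphan samples whose site has no
    hydrochemical data at all.
    """
    series_by_site: dict[str, list[HydroSeries]] = {}
    for s in hydro_series:
        series_by_site.setdefault(s.site_id, []).append(s)

    orphans = sorted({b.site_id for b in bio_samples}
                     - set(series_by_site))
    if orphans:
        raise ValueError(
            f"bio samples with no matching hydrochemical site: {orphans}")

    # occasion = the site-wide sampling event (same date across replicates)
    rows = []
    windows = sorted({sp.window_days for sp in specs})
    stats_needed = sorted({sp.statistic for sp in specs})
    wanted = {(sp.statistic, sp.window_days) for sp in specs}

    # cache per (site, date, determinand, window) so replicate rows reuse it
    cache: dict[tuple, dict[str, float]] = {}
    for b in sorted(bio_samples, key=lambda s: s.key):
        row: dict[str, float | str] = {
            "site_id": b.site_id,
            "sample_date": b.sample_date.isoformat(),
            "occasion": b.sample_date.isoformat(),
            "replicate_id": b.replicate_id,
        }
        for series in series_by_site[b.site_id]:
            for w in windows:
                key = (b.site_id, b.sample_date, series.determinand, w)
                if key not in cache:
                    ts, vals, coverage = extract_window(series, b.sample_date, w)
                    if coverage >= min_coverage:
                        cache[key] = summarise_window(vals, ts)
                    else:
                        cache[key] = {s: float("nan") for s in STATISTICS}
                stats = cache[key]
                for stat in stats_needed:
                    if (stat, w) in wanted:
                        row[candidate_name(series.determinand, stat, w)] = \
                            stats[stat]
        rows.append(row)

    table = pd.DataFrame(rows)
    candidate_cols = [c for c in table.columns if c not in ID_COLUMNS]

    # drop mostly-missing candidates
    keep, dropped = [], []
    for c in candidate_cols:
        if table[c].isna().mean() > max_missing_fraction:
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        log.warning("dropping %d candidate column(s) with more than %.0f%% "
                    "missing rows: %s", len(dropped),
                    100 * max_missing_fraction, dropped[:10])
    table = table[ID_COLUMNS + keep]

    if standardize:
        for c in keep:
            col = table[c]
            sd = col.std(ddof=1)
            if sd > 0:
                table[c] = (col - col.mean()) / sd
    return table
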