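"""Macroinvertebrate biotic index calculators.

All calculators are score-table-driven: the taxon parameters live in
:class:`~bioassess.types.ScoreTable` objects loaded from CSV resources, so
published tables can replace the shipped synthetic fixtures without code
change.  Indices are computed per replicate sample; replicates are never
pooled.  A sample with no scoring taxa yields a *missing* value plus a flag
rather than an exception.

Abundance weighting uses the four conventional log-abundance classes of the
UK index family: 1-9, 10-99, 100-999, >=1000 individuals.
"""
from __future__ import annotations

import math

import numpy as np

from .types import BioSample, IndexResult, InvalidInputError, ScoreTable

__all__ = [
    "abundance_class",
    "compute_whpt",
    "compute_life",
    "compute_weighted_proportion_index",
    "compute_cofsi",
    "compute_trpi",
    "compute_log_abundance",
    "compute_index_suite",
]


def abundance_class(count: int) -> int:
    """Map an individual count to its abundance class 1-4.

    Classes: 1-9 -> 1, 10-99 -> 2, 100-999 -> 3, >=1000 -> 4.
    """
    if count <= 0 or int(count) != count:
        raise InvalidInputError(
            f"abundance class needs a positive integer count, got {count!r}")
    if count < 10:
        return 1
    if count < 100:
        return 2
    if count < 1000:
        return 3
    return 4


def _present_scoring_taxa(sample: BioSample, table: ScoreTable) -> list[str]:
    """Taxa present (count >= 1) that the table scores, sorted for determinism."""
    return sorted(t for t, c in sample.counts.items()
                  if c >= 1 and t in table.taxa)


def compute_whpt(
    sample: BioSample, table: ScoreTable,
) -> tuple[int, float | None, float | None]:
    """Abundance-weighted WHPT: (ntaxa, total score, average score per taxon).

    Each scoring taxon contributes the score of its abundance class
    (columns s1..s4); ASPT is the total divided by the number of scoring
    taxa, or missing when no taxa score.
    """
    if table.index_id != "WHPT":
        raise InvalidInputError("compute_whpt needs a WHPT table")
    taxa = _present_scoring_taxa(sample, table)
    if not taxa:
        return 0, None, None
    total = 0.0
    for t in taxa:
        cls = abundance_class(sample.counts[t])
        total += float(table.entries.at[t, f"s{cls}"])
    return len(taxa), total, total / len(taxa)


def compute_life(sample: BioSample, table: ScoreTable) -> float | None:
    """Flow-evaluation index: mean per-taxon flow score.

    Each scoring taxon's flow group (I-VI) and abundance class select a
    flow score from the configured matrix; the index is the mean score
    over scoring taxa.
    """
    if table.index_id != "LIFE":
        raise InvalidInputError("compute_life needs a LIFE table")
    taxa = _present_scoring_taxa(sample, table)
    if not taxa:
        return None
    total = 0.0
    for t in taxa:
        group = str(table.entries.at[t, "flow_group"])
        cls = abundance_class(sample.counts[t])
        total += float(table.matrix.at[group, str(cls)])
    return total / len(taxa)


def compute_weighted_proportion_index(
    sample: BioSample, table: ScoreTable, variant: str,
) -> float | None:
    """Percentage-form indices: PSI, ePSI and SPEAR.

    PSI: 100 x sum of abundance-class scores of sediment-sensitive taxa
    (groups A and B) over the sum for all scoring taxa.  ePSI: same form
    with empirical per-taxon weights in place of the group matrix.  SPEAR:
    100 x sum of log10(count+1) over at-risk taxa over the sum for all
    scoring taxa.  Missing when the denominator is zero.
    """
    if variant != table.index_id:
        raise InvalidInputError(
            f"variant {variant!r} does not match table {table.index_id!r}")
    taxa = _present_scoring_taxa(sample, table)
    if not taxa:
        return None
    num = 0.0
    den = 0.0
    for t in taxa:
        count = sample.counts[t]
        if variant == "PSI":
            group = str(table.entries.at[t, "group"])
            score = float(table.matrix.at[group, str(abundance_class(count))])
            sensitive = group in ("A", "B")
        elif variant == "ePSI":
            score = float(table.entries.at[t, "weight"]) * abundance_class(count)
            sensitive = bool(table.entries.at[t, "sensitive"])
        elif variant == "SPEAR":
            score = math.log10(count + 1)
            sensitive = bool(table.entries.at[t, "at_risk"])
        else:  # pragma: no cover - guarded above
            raise InvalidInputError(f"unknown variant {variant!r}")
        den += score
        if sensitive:
            num += score
    if den == 0:
        return None
    return min(100.0, max(0.0, 100.0 * num / den))


def _abundance_weighted_mean(
    sample: BioSample, table: ScoreTable, column: str,
) -> float | None:
    """Abundance-class-weighted mean of a per-taxon score column."""
    taxa = [t for t in _present_scoring_taxa(sample, table)
            if np.isfinite(table.entries.at[t, column])]
    if not taxa:
        return None
    weights = np.array([abundance_class(sample.counts[t]) for t in taxa],
                       dtype=float)
    scores = np.array([float(table.entries.at[t, column]) for t in taxa])
    return float((weights * scores).sum() / weights.sum())


def compute_cofsi(
    sample: BioSample, table: ScoreTable,
) -> tuple[float | None, list[str]]:
    """Combined fine-sediment index: weighted sum of two sub-indices.

    The organic (oFSI) and total (ToFSI) sub-indices are abundance-weighted
    means of their taxon scores; the combination weights are a table
    attribute (default 0.5/0.5).  If only one sub-index has scoring taxa
    the result falls back to that sub-index alone and is flagged partial.
    """
    if table.index_id != "CoFSI":
        raise InvalidInputError("compute_cofsi needs a CoFSI table")
    flags: list[str] = []
    ofsi = _abundance_weighted_mean(sample, table, "ofsi")
    tofsi = _abundance_weighted_mean(sample, table, "tofsi")
    w_o, w_t = table.weights
    if ofsi is None and tofsi is None:
        return None, ["CoFSI missing: no scoring taxa"]
    if ofsi is None or tofsi is None:
        flags.append("CoFSI partial: one sub-index had no scoring taxa")
        return (tofsi if ofsi is None else ofsi), flags
    return w_o * ofsi + w_t * tofsi, flags


def compute_trpi(
    sample: BioSample, table: ScoreTable,
) -> tuple[float | None, list[str]]:
    """Nutrient-enrichment index; undefined for summer samples.

    Abundance-class-weighted mean of the taxon scores for spring and
    autumn samples; summer samples return missing with a flag, because the
    index is not defined for summer communities.
    """
    if table.index_id != "TRPI":
        raise InvalidInputError("compute_trpi needs a TRPI table")
    if sample.season == "summer":
        return None, ["TRPI suppressed: summer sample"]
    value = _abundance_weighted_mean(sample, table, "score")
    if value is None:
        return None, ["TRPI missing: no scoring taxa"]
    return value, []


def compute_log_abundance(sample: BioSample) -> float:
    """log10(1 + total individuals); the +1 offset keeps empty samples finite."""
    return math.log10(1 + sample.total_abundance)


def compute_index_suite(
    sample: BioSample, tables: dict[str, ScoreTable],
) -> IndexResult:
    """All nine indices for one replicate sample.

    Sparse samples never raise: any index without scoring taxa is missing
    and flagged.  ``tables`` must cover the seven score-based indices.
    """
    from .types import INDEX_IDS

    missing_tables = [i for i in INDEX_IDS if i not in tables]
    if missing_tables:
        raise InvalidInputError(f"score tables missing for {missing_tables}")

    result = IndexResult(sample=sample)
    result.log_abundance = compute_log_abundance(sample)

    ntaxa, _total, aspt = compute_whpt(sample, tables["WHPT"])
    result.ntaxa_whpt = ntaxa
    result.aspt_whpt = aspt
    if aspt is None:
        result.flags.append("ASPT missing: no WHPT scoring taxa")

    result.life = compute_life(sample, tables["LIFE"])
    if result.life is None:
        result.flags.append("LIFE missing: no scoring taxa")

    for attr, variant in (("psi", "PSI"), ("epsi", "ePSI"), ("spear", "SPEAR")):
        value = compute_weighted_proportion_index(
            sample, tables[variant], variant)
        setattr(result, attr, value)
        if value is None:
            result.flags.append(f"{variant} missing: no scoring taxa")

    result.cofsi, cofsi_flags = compute_cofsi(sample, tables["CoFSI"])
    result.flags.extend(cofsi_flags)

    result.trpi, trpi_flags = compute_trpi(sample, tables["TRPI"])
    result.flags.extend(trpi_flags)

    unscored = sorted(
        t for t, c in sample.counts.items()
        if c >= 1 and all(t not in tables[i].taxa for i in INDEX_IDS))
    if unscored:
        result.flags.append(f"taxa unscored by every index: {unscored}")
    return result
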