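"""End-to-end orchestration: indices -> summaries -> selection -> partition.

`analyse` is the in-memory engine; `run_pipeline` wraps it with file I/O,
a run manifest and per-stage logging for the command-line interface.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio_io
from .correlations import (average_correlations, index_pairwise_relationships,
                           pearson_pairwise)
from .design import build_design_matrix, parse_candidate_name
from .indices import compute_index_suite
from .selection import (partition_variance, single_determinand_scan,
                        stepwise_select, window_profile)
from .types import (BioSample, HydroSeries, ScoreTable, SummarySpec,
                    STATISTICS, WINDOWS_DAYS, full_design_specs)
from .windows import DEFAULT_MIN_COVERAGE

__all__ = ["RunConfig", "PipelineResult", "compute_index_table", "analyse",
           "run_pipeline"]

log = logging.getLogger(__name__)

INDEX_COLUMNS = ["ntaxa_whpt", "aspt_whpt", "life", "psi", "epsi", "cofsi",
                 "trpi", "spear", "log_abundance"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    hydro_path: str
    abundance_path: str
    score_table_dir: str
    out_dir: str
    windows: tuple[int, ...] = WINDOWS_DAYS
    statistics: tuple[str, ...] = STATISTICS
    min_coverage: float = DEFAULT_MIN_COVERAGE
    max_missing_fraction: float = 0.5
    responses: tuple[str, ...] = tuple(INDEX_COLUMNS)
    include_structural: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.windows) - set(WINDOWS_DAYS)
        if bad:
            raise ValueError(f"unsupported window(s) {sorted(bad)}")
        bad = set(self.statistics) - set(STATISTICS)
        if bad:
            raise ValueError(f"unsupported statistic(s) {sorted(bad)}")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")
        bad = set(self.responses) - set(INDEX_COLUMNS)
        if bad:
            raise ValueError(f"unknown response index(es) {sorted(bad)}")

    def specs(self) -> list[SummarySpec]:
        return full_design_specs(self.statistics, self.windows)


@dataclass
class PipelineResult:
    index_table: pd.DataFrame
    design: pd.DataFrame
    correlations_within: pd.DataFrame
    correlations_across: pd.DataFrame
    correlation_averages: pd.DataFrame
    index_relationships: pd.DataFrame
    selections: dict[str, object]
    scans: dict[str, pd.DataFrame] = field(default_factory=dict)
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    partitions: dict[str, object] = field(default_factory=dict)


def compute_index_table(
    samples: list[BioSample], tables: dict[str, ScoreTable],
) -> pd.DataFrame:
    """One row per replicate sample with all nine index values."""
    rows = [compute_index_suite(s, tables).as_row()
            for s in sorted(samples, key=lambda s: s.key)]
    return pd.DataFrame(rows)


def _first_candidate_term(selection) -> str | None:
    for term in selection.selected_terms:
        if "__" in term:  # candidate grammar {det}__{stat}__{w}d
            return term
    return None


def analyse(
    hydro: list[HydroSeries],
    samples: list[BioSample],
    tables: dict[str, ScoreTable],
    specs: list[SummarySpec] | None = None,
    responses: list[str] | None = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_missing_fraction: float = 0.5,
    include_structural: bool = True,
    with_correlations: bool = True,
) -> PipelineResult:
    """Run the full analysis chain in memory.

    For each response index: stepwise BIC selection over all candidate
    summaries (plus structural site/occasion terms), a single-candidate
    scan, the antecedent-window profile of the winning (determinand,
    statistic) pair, and a variance partition with the winning candidate
    as covariate.
    """
    if specs is None:
        specs = full_design_specs()
    if responses is None:
        responses = INDEX_COLUMNS

    index_table = compute_index_table(samples, tables)
    design = build_design_matrix(
        samples, hydro, specs, min_coverage=min_coverage,
        max_missing_fraction=max_missing_fraction)

    if with_correlations:
        corr_within = pearson_pairwise(
            design, "within_determinand_across_windows")
        corr_across = pearson_pairwise(
            design, "within_window_across_determinands")
        corr_avg = average_correlations(corr_across)
        index_rel = index_pairwise_relationships(
            index_table, index_columns=[c for c in INDEX_COLUMNS
                                        if c in index_table.columns])
    else:
        corr_within = corr_across = corr_avg = index_rel = pd.DataFrame()

    selections, scans, profiles, partitions = {}, {}, {}, {}
    for response in responses:
        y = index_table[response].to_numpy(float)
        if np.isfinite(y).sum() < 8:
            continue
        sel = stepwise_select(design, y, response_name=response,
                              include_structural=include_structural)
        selections[response] = sel
        scans[response] = single_determinand_scan(design, y)
        winner = _first_candidate_term(sel)
        if winner is None and not scans[response].empty:
            winner = scans[response]["candidate"].iloc[0]
        if winner is not None:
            det, stat, _ = parse_candidate_name(winner)
            profiles[response] = window_profile(design, y, det, stat)
            partitions[response] = partition_variance(design, y, winner)
    return PipelineResult(
        index_table=index_table, design=design,
        correlations_within=corr_within, correlations_across=corr_across,
        correlation_averages=corr_avg, index_relationships=index_rel,
        selections=selections, scans=scans, profiles=profiles,
        partitions=partitions)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-to-file pipeline run with manifest, timers and tidy outputs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hydro = bio_io.read_hydro(config.hydro_path)
    samples = bio_io.read_abundance(config.abundance_path)
    tables = bio_io.read_score_tables(config.score_table_dir)
    log.info("loaded %d series, %d samples, %d score tables",
             len(hydro), len(samples), len(tables))

    result = analyse(
        hydro, samples, tables, specs=config.specs(),
        responses=list(config.responses), min_coverage=config.min_coverage,
        max_missing_fraction=config.max_missing_fraction,
        include_structural=config.include_structural)

    result.index_table.to_csv(out / "indices.csv", index=False)
    result.design.to_csv(out / "design_matrix.csv", index=False)
    result.correlations_within.to_csv(
        out / "correlations_within_determinand.csv", index=False)
    result.correlations_across.to_csv(
        out / "correlations_across_determinands.csv", index=False)
    result.correlation_averages.to_csv(
        out / "correlation_averages.csv", index=False)
    result.index_relationships.to_csv(
        out / "index_relationships.csv", index=False)

    sel_rows = []
    for response, sel in result.selections.items():
        sel_rows.append({
            "response": response,
            "selected_terms": ";".join(sel.selected_terms),
            "bic_final": sel.bic_trace[-1],
            "r_squared": sel.r_squared,
            "n_obs": sel.n_obs,
        })
        if response in result.profiles:
            result.profiles[response].to_csv(
                out / f"window_profile_{response}.csv", index=False)
        if response in result.partitions:
            shares = result.partitions[response].shares
            pd.DataFrame([shares]).to_csv(
                out / f"variance_partition_{response}.csv", index=False)
        result.scans[response].head(50).to_csv(
            out / f"scan_{response}.csv", index=False)
    pd.DataFrame(sel_rows).to_csv(out / "selection.csv", index=False)

    config_json = json.dumps(dataclasses.asdict(config), sort_keys=True,
                             default=str)
    manifest = {
        "created": dt.datetime.now().isoformat(timespec="seconds"),
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "n_hydro_series": len(hydro),
        "n_bio_samples": len(samples),
        "n_candidates": int(len(result.design.columns) - 4),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return result
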