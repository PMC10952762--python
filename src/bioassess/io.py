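"""Readers and writers for the pipeline's plain-text formats.

Hydrochemistry travels as long-format delimited text (site_id, timestamp,
determinand, value, unit); abundances as long-format rows (site_id,
sample_date, season, replicate_id, taxon_id, count); score tables as one
CSV per index with a strict schema; the truth record and run manifest as
JSON.  Every writer's output round-trips through its reader.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SyntheticDataset, TruthRecord
from .types import (BioSample, ConfigurationError, HydroSeries,
                    InvalidInputError, ScoreTable)

__all__ = [
    "read_hydro", "write_hydro", "read_abundance", "write_abundance",
    "read_score_tables", "write_score_tables", "read_truth", "write_truth",
    "write_dataset", "read_dataset", "packaged_score_table_dir",
]

log = logging.getLogger(__name__)

HYDRO_COLUMNS = ["site_id", "timestamp", "determinand", "value", "unit"]
ABUNDANCE_COLUMNS = ["site_id", "sample_date", "season", "replicate_id",
                     "taxon_id", "count"]


def packaged_score_table_dir() -> Path:
    """Directory of the synthetic score-table fixtures shipped with the
    package (invented taxa; drop in published tables to replace them)."""
    return Path(__file__).parent / "data" / "synthetic_score_tables"


def write_hydro(series_list: list[HydroSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "site_id": s.site_id,
            "timestamp": pd.DatetimeIndex(s.timestamps).strftime(
                "%Y-%m-%dT%H:%M:%S"),
            "determinand": s.determinand,
            "value": s.values,
            "unit": s.unit,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_hydro(path: str | Path) -> list[HydroSeries]:
    """Parse a long-format hydrochemistry file into HydroSeries objects.

    Timestamps must be ISO 8601 (a parse failure names the offending
    line); duplicate timestamps within a (site, determinand) series are
    reported and resolved keep-first.  Nominal resolution is inferred as
    the modal time step.
    """
    table = pd.read_csv(path, dtype={"site_id": str, "determinand": str})
    missing = [c for c in HYDRO_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"hydro file missing column(s) {missing}")
    ts = pd.to_datetime(table["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() & table["timestamp"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise InvalidInputError(
            f"{path}: non-ISO timestamp {table['timestamp'][bad].iloc[0]!r} "
            f"at line {line}")
    table = table.assign(_ts=ts)

    out = []
    for (sid, det), grp in table.groupby(["site_id", "determinand"],
                                         sort=True):
        grp = grp.sort_values("_ts", kind="stable")
        dup = grp["_ts"].duplicated()
        if dup.any():
            warnings.warn(
                f"{sid}/{det}: {int(dup.sum())} duplicate timestamp(s), "
                "keeping first", stacklevel=2)
            grp = grp[~dup]
        stamps = grp["_ts"].to_numpy(dtype="datetime64[ns]")
        if len(stamps) > 1:
            steps = np.diff(stamps).astype("timedelta64[m]").astype(int)
            resolution = int(np.bincount(steps[steps > 0]).argmax())
        else:
            resolution = 15
        out.append(HydroSeries(
            site_id=sid, determinand=det, timestamps=stamps,
            values=grp["value"].to_numpy(float),
            unit=str(grp["unit"].iloc[0]), nominal_resolution=resolution))
    return out


def write_abundance(samples: list[BioSample], path: str | Path) -> None:
    rows = []
    for s in sorted(samples, key=lambda b: b.key):
        for taxon, count in sorted(s.counts.items()):
            rows.append({
                "site_id": s.site_id,
                "sample_date": s.sample_date.isoformat(),
                "season": s.season,
                "replicate_id": s.replicate_id,
                "taxon_id": taxon,
                "count": count,
            })
    pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS).to_csv(path, index=False)


def read_abundance(path: str | Path) -> list[BioSample]:
    """Parse a long-format abundance file into replicate BioSamples."""
    table = pd.read_csv(path, dtype={"site_id": str, "replicate_id": str,
                                     "taxon_id": str})
    missing = [c for c in ABUNDANCE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(
            f"abundance file missing column(s) {missing}")
    if (table["count"] < 0).any():
        bad = table[table["count"] < 0].iloc[0]
        raise InvalidInputError(
            f"negative count for {bad['taxon_id']} at {bad['site_id']}/"
            f"{bad['sample_date']}")
    samples = []
    for (sid, date, season, rep), grp in table.groupby(
            ["site_id", "sample_date", "season", "replicate_id"], sort=True):
        samples.append(BioSample(
            site_id=sid, sample_date=dt.date.fromisoformat(str(date)),
            season=str(season), replicate_id=rep,
            counts={t: int(c) for t, c in
                    zip(grp["taxon_id"], grp["count"])}))
    return samples


_MATRIX_PREFIX = "matrix_"


def write_score_tables(tables: dict[str, ScoreTable],
                       directory: str | Path) -> None:
    """One CSV per index (plus matrix/weights side files where needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for index_id, table in tables.items():
        table.entries.to_csv(directory / f"{index_id}.csv",
                             index_label="taxon_id")
        if table.matrix is not None:
            table.matrix.to_csv(directory / f"{_MATRIX_PREFIX}{index_id}.csv",
                                index_label="group")
        if table.index_id == "CoFSI":
            (directory / "weights_CoFSI.json").write_text(
                json.dumps({"ofsi": table.weights[0],
                            "tofsi": table.weights[1]}))


def read_score_tables(directory: str | Path) -> dict[str, ScoreTable]:
    """Load all per-index score tables from a directory.

    Unknown index filenames are rejected; schema violations raise
    ConfigurationError naming the column.
    """
    from .types import INDEX_IDS

    directory = Path(directory)
    tables: dict[str, ScoreTable] = {}
    for path in sorted(directory.glob("*.csv")):
        if path.name.startswith(_MATRIX_PREFIX):
            continue
        index_id = path.stem
        if index_id not in INDEX_IDS:
            raise ConfigurationError(
                f"unrecognised score-table file {path.name!r} "
                f"(expected one of {INDEX_IDS})")
        entries = pd.read_csv(path, index_col="taxon_id")
        matrix = None
        matrix_path = directory / f"{_MATRIX_PREFIX}{index_id}.csv"
        if matrix_path.exists():
            matrix = pd.read_csv(matrix_path, index_col="group")
            matrix.columns = [str(c) for c in matrix.columns]
        weights = None
        if index_id == "CoFSI":
            wpath = directory / "weights_CoFSI.json"
            if wpath.exists():
                w = json.loads(wpath.read_text())
                weights = (float(w["ofsi"]), float(w["tofsi"]))
        tables[index_id] = ScoreTable(index_id, entries, matrix=matrix,
                                      weights=weights)
    return tables


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path: str | Path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Write a complete self-describing bundle readable by read_dataset."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_hydro(dataset.hydro, directory / "hydro.csv")
    write_abundance(dataset.bio_samples, directory / "abundance.csv")
    write_score_tables(dataset.score_tables, directory / "score_tables")
    write_truth(dataset.truth, directory / "truth.json")
    (directory / "config.json").write_text(json.dumps(
        {k: v for k, v in dataset.config.__dict__.items()},
        default=str, indent=1))


def read_dataset(directory: str | Path) -> tuple[
        list[HydroSeries], list[BioSample], dict[str, ScoreTable],
        TruthRecord | None]:
    directory = Path(directory)
    hydro = read_hydro(directory / "hydro.csv")
    samples = read_abundance(directory / "abundance.csv")
    tables = read_score_tables(directory / "score_tables")
    truth_path = directory / "truth.json"
    truth = read_truth(truth_path) if truth_path.exists() else None
    return hydro, samples, tables, truth
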