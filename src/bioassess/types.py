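"""Core domain types shared across the package.

The data model mirrors the structure of a replicated stream-biomonitoring
study: high-frequency hydrochemical series per site, replicate kick samples
per site and season, taxon score tables driving the biotic indices, and the
derived summary / model-selection result objects.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("spring", "summer", "autumn")

#: Northern-hemisphere meteorological season map (month -> season).
SEASON_OF_MONTH = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

INDEX_IDS = ("WHPT", "LIFE", "PSI", "ePSI", "CoFSI", "TRPI", "SPEAR")

#: Determinands the driver analysis can draw on.
DETERMINANDS = (
    "discharge", "velocity", "turbidity", "pH", "DO",
    "TP", "SRP", "TRP", "TDP", "DOP",
    "TN", "TDN", "NO3N", "NH4N", "NH3N", "DON", "PON",
    "DOC", "temperature", "conductivity", "chlorophyll_a",
)

STATISTICS = (
    "mean", "median", "min", "max",
    "Q5", "Q10", "Q90", "Q95",
    "cv", "range50", "range80", "range90",
    "days_exceeding_3xQ50",
)

WINDOWS_DAYS = (1, 5, 10, 20, 30, 60, 90)


def season_of(date: dt.date) -> str | None:
    """Season of a calendar date under the northern-hemisphere map.

    Returns None for winter months (no sampling occurs then).
    """
    return SEASON_OF_MONTH.get(date.month)


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a score table or run configuration is malformed."""


@dataclass(frozen=True)
class BioSample:
    """One replicate kick sample: a taxon -> count map with its context."""

    site_id: str
    sample_date: dt.date
    season: str
    replicate_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise InvalidInputError(
                f"season {self.season!r} not one of {SEASONS}")
        expected = season_of(self.sample_date)
        if expected is not None and expected != self.season:
            raise InvalidInputError(
                f"season {self.season!r} inconsistent with date "
                f"{self.sample_date} (expected {expected})")
        for taxon, count in self.counts.items():
            if count < 0 or int(count) != count:
                raise InvalidInputError(
                    f"count for {taxon!r} must be a non-negative integer, "
                    f"got {count!r}")

    @property
    def total_abundance(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site_id, self.sample_date.isoformat(), self.replicate_id)


@dataclass
class ScoreTable:
    """Per-index taxon parameters.

    ``entries`` is indexed by taxon_id; its columns depend on the index:

    ========  =======================================================
    index_id  columns
    ========  =======================================================
    WHPT      s1, s2, s3, s4   (score per abundance class)
    LIFE      flow_group       (Roman numeral I..VI)
    PSI       group            (A..D; A and B are sediment-sensitive)
    ePSI      weight, sensitive
    CoFSI     ofsi, tofsi      (organic / total fine-sediment scores)
    TRPI      score
    SPEAR     at_risk          (bool)
    ========  =======================================================

    ``matrix`` carries the group-by-abundance-class score matrix used by
    LIFE and PSI; ``weights`` the CoFSI sub-index combination weights.
    """

    index_id: str
    entries: pd.DataFrame
    matrix: pd.DataFrame | None = None
    weights: tuple[float, float] | None = None

    REQUIRED_COLUMNS = {
        "WHPT": ["s1", "s2", "s3", "s4"],
        "LIFE": ["flow_group"],
        "PSI": ["group"],
        "ePSI": ["weight", "sensitive"],
        "CoFSI": ["ofsi", "tofsi"],
        "TRPI": ["score"],
        "SPEAR": ["at_risk"],
    }
    LEGAL_GROUPS = {
        "LIFE": {"I", "II", "III", "IV", "V", "VI"},
        "PSI": {"A", "B", "C", "D"},
    }

    def __post_init__(self) -> None:
        if self.index_id not in INDEX_IDS:
            raise ConfigurationError(f"unknown index {self.index_id!r}")
        required = self.REQUIRED_COLUMNS[self.index_id]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ConfigurationError(
                f"{self.index_id} score table missing column(s) {missing}")
        if self.entries.index.has_duplicates:
            dups = self.entries.index[self.entries.index.duplicated()]
            raise ConfigurationError(
                f"{self.index_id} score table lists taxa more than once: "
                f"{sorted(set(dups))}")
        legal = self.LEGAL_GROUPS.get(self.index_id)
        if legal is not None:
            col = required[0]
            bad = set(self.entries[col].astype(str)) - legal
            if bad:
                raise ConfigurationError(
                    f"{self.index_id} group code(s) {sorted(bad)} outside "
                    f"legal set {sorted(legal)}")
        if self.index_id in ("LIFE", "PSI") and self.matrix is None:
            raise ConfigurationError(
                f"{self.index_id} requires a group x abundance-class "
                "score matrix")
        if self.index_id == "CoFSI" and self.weights is None:
            self.weights = (0.5, 0.5)

    @property
    def taxa(self) -> set[str]:
        return set(self.entries.index)


@dataclass
class IndexResult:
    """All index values for one replicate sample, with provenance flags."""

    sample: BioSample
    ntaxa_whpt: int | None = None
    aspt_whpt: float | None = None
    life: float | None = None
    psi: float | None = None
    epsi: float | None = None
    cofsi: float | None = None
    trpi: float | None = None
    spear: float | None = None
    log_abundance: float = 0.0
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "site_id": self.sample.site_id,
            "sample_date": self.sample.sample_date.isoformat(),
            "season": self.sample.season,
            "replicate_id": self.sample.replicate_id,
            "ntaxa_whpt": self.ntaxa_whpt,
            "aspt_whpt": self.aspt_whpt,
            "life": self.life,
            "psi": self.psi,
            "epsi": self.epsi,
            "cofsi": self.cofsi,
            "trpi": self.trpi,
            "spear": self.spear,
            "log_abundance": self.log_abundance,
            "flags": ";".join(self.flags),
        }


@dataclass
class HydroSeries:
    """One site's timestamped observations of one determinand."""

    site_id: str
    determinand: str
    timestamps: np.ndarray  # datetime64[ns], strictly increasing
    values: np.ndarray      # float, NaN marks missing
    unit: str = ""
    nominal_resolution: int = 15  # minutes

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise InvalidInputError("timestamps and values differ in length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps)
                                                   > np.timedelta64(0, "ns")):
            raise InvalidInputError(
                f"{self.site_id}/{self.determinand}: timestamps not "
                "strictly increasing")
        if self.determinand == "pH":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 14):
                raise InvalidInputError("pH values outside [0, 14]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SummarySpec:
    """One summary statistic over one antecedent window length."""

    statistic: str
    window_days: int

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise InvalidInputError(f"unknown statistic {self.statistic!r}")
        if self.window_days not in WINDOWS_DAYS:
            raise InvalidInputError(
                f"window {self.window_days} not in {WINDOWS_DAYS}")


def full_design_specs(
    statistics: Sequence[str] = STATISTICS,
    windows: Sequence[int] = WINDOWS_DAYS,
) -> list[SummarySpec]:
    """The default 13-statistic x 7-window grid (91 specs)."""
    return [SummarySpec(s, w) for s in statistics for w in windows]


@dataclass
class WindowSummary:
    """Value of one statistic of one determinand before one bio sample."""

    site_id: str
    sample_date: dt.date
    determinand: str
    spec: SummarySpec
    value: float | None
    n_obs: int
    coverage: float
    flags: list[str] = field(default_factory=list)


@dataclass
class SelectionResult:
    """Outcome of a stepwise model-selection run for one response index."""

    response: str
    selected_terms: list[str]
    bic_trace: list[float]
    r_squared: float
    coefficients: dict[str, float]
    n_obs: int

    @property
    def is_intercept_only(self) -> bool:
        return len(self.selected_terms) == 0


@dataclass
class VariancePartition:
    """Fractions of total SS credited to covariate / site / time / residual."""

    shares: dict[str, float]

    COMPONENTS = ("covariate", "site", "temporal", "residual")

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"variance shares sum to {total}, not 1")
        if any(v < -1e-12 for v in self.shares.values()):
            raise InvalidInputError("negative variance share")
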