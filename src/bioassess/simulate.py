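"""Synthetic hydrochemistry and macroinvertebrate community generator.

The generator emulates the statistical structure the driver analysis
assumes: several small agricultural headwater sites instrumented at 15-min
(sonde) and 30-min (nutrient) resolution over multiple years, with
episodic storm events that flush sediment, nutrients and organic matter
into the channel and depress dissolved oxygen (a post-storm "sag"), a diel
DO/temperature/pH cycle, and paired replicate kick samples in spring,
summer and autumn.

The macroinvertebrate community responds to a *known* driver: the trough
(low percentile) of DO saturation over a configurable antecedent window
D*.  Each taxon's expected abundance is suppressed through a threshold
hinge,

    E[count_i] = baseline_i * exp(-beta * sensitivity_i * max(0, thr - E))

where E is the exposure statistic, so communities sampled shortly after a
deep sag lose their sensitive taxa.  Counts are negative-binomial
(overdispersed, as kick-sample counts are); replicate pairs share the
expectation and differ only in sampling noise.  A truth record carrying
the driver determinand, statistic family, window and per-sample exposure
accompanies every dataset so recovery tests can score the pipeline.

Everything is reproducible bit-for-bit under a fixed seed.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import BioSample, HydroSeries, ScoreTable, season_of
from .windows import extract_window, quantile

__all__ = ["SimConfig", "TruthRecord", "simulate_storms", "simulate_hydro",
           "simulate_community", "generate_score_table_fixtures",
           "generate_dataset", "DeterminandModel", "DEFAULT_DETERMINANDS"]


@dataclass(frozen=True)
class DeterminandModel:
    """Functional form of one simulated determinand.

    baseline: typical value in the determinand's units
    diel_amplitude: half-range of the 24-h cycle (0 = no cycle)
    seasonal_amplitude: half-range of the annual cycle
    flush_coef: per-unit-magnitude additive storm response (negative for
        dilution); decay_days: e-folding time of the storm response
    noise_sd: additive Gaussian observation noise
    lower/upper: physical clipping bounds
    """

    baseline: float
    diel_amplitude: float = 0.0
    seasonal_amplitude: float = 0.0
    flush_coef: float = 0.0
    decay_days: float = 0.5
    noise_sd: float = 0.0
    lower: float = 0.0
    upper: float = float("inf")
    unit: str = ""


#: Invented but realistic lowland-stream parameterisations.
DEFAULT_DETERMINANDS: dict[str, DeterminandModel] = {
    "discharge": DeterminandModel(0.5, flush_coef=1.5, decay_days=1.0,
                                  noise_sd=0.02, unit="m3/s"),
    "velocity": DeterminandModel(0.3, flush_coef=0.4, decay_days=1.0,
                                 noise_sd=0.01, unit="m/s"),
    "turbidity": DeterminandModel(5.0, flush_coef=60.0, decay_days=0.4,
                                  noise_sd=1.0, unit="NTU"),
    "pH": DeterminandModel(7.8, diel_amplitude=0.15, flush_coef=-0.2,
                           decay_days=0.8, noise_sd=0.03,
                           lower=0.0, upper=14.0, unit="pH"),
    # DO has its own generator (photoperiod-asymmetric diel + storm sags);
    # baseline/amplitude/noise are still read from this record
    "DO": DeterminandModel(95.0, diel_amplitude=10.0, noise_sd=1.5,
                           lower=0.0, upper=150.0, unit="% sat"),
    "temperature": DeterminandModel(10.0, diel_amplitude=1.5,
                                    seasonal_amplitude=5.0, noise_sd=0.2,
                                    lower=-2.0, upper=35.0, unit="degC"),
    "TP": DeterminandModel(0.08, flush_coef=0.5, decay_days=0.5,
                           noise_sd=0.01, unit="mg/L"),
    "SRP": DeterminandModel(0.05, flush_coef=0.2, decay_days=0.5,
                            noise_sd=0.005, unit="mg/L"),
    "NH4N": DeterminandModel(0.05, flush_coef=0.3, decay_days=0.6,
                             noise_sd=0.005, unit="mg/L"),
    "NO3N": DeterminandModel(5.0, flush_coef=-1.0, decay_days=0.8,
                             noise_sd=0.1, unit="mg/L"),
    "TN": DeterminandModel(6.0, flush_coef=0.8, decay_days=0.7,
                           noise_sd=0.1, unit="mg/L"),
    "TDN": DeterminandModel(5.5, flush_coef=0.3, decay_days=0.7,
                            noise_sd=0.1, unit="mg/L"),
    "TDP": DeterminandModel(0.06, flush_coef=0.25, decay_days=0.5,
                            noise_sd=0.005, unit="mg/L"),
    "DOC": DeterminandModel(3.0, flush_coef=6.0, decay_days=0.6,
                            noise_sd=0.2, unit="mg/L"),
}

#: 30-min (bankside analyser) determinands; everything else is 15-min sonde.
NUTRIENT_DETERMINANDS = {"TP", "SRP", "NO3N", "TN", "TDN", "TDP", "DOC",
                         "NH4N"}

EFFECT_PRESETS = {"none": 0.0, "weak": 0.02, "strong": 0.06}


@dataclass
class SimConfig:
    """Study design and process parameters for one synthetic dataset."""

    n_sites: int = 7
    start_year: int = 2010
    n_years: int = 3
    sonde_resolution_min: int = 15
    nutrient_resolution_min: int = 30
    determinands: tuple[str, ...] = tuple(DEFAULT_DETERMINANDS)

    # storm process
    storm_rate_per_day: float = 0.12
    storm_magnitude_sigma: float = 0.6   # lognormal(0, sigma)
    storm_rise_hours: float = 4.0
    event_det_sigma: float = 1.0         # per-determinand event multiplier

    # DO model: photoperiod diel cycle, daytime "bloom" modulation and
    # saturating (bounded) post-storm sags -- DO cannot fall below zero,
    # so sag depth saturates in event magnitude
    bloom_sigma: float = 0.8             # day-to-day daytime modulation
    sag_max_depth: float = 40.0          # % saturation ceiling on sag depth
    sag_shape: float = 0.8               # saturation rate in event magnitude
    sag_event_sigma: float = 0.4         # sag-specific lognormal multiplier
    sag_probability: float = 0.6         # chance a storm depletes oxygen
    sag_decay_days: float = 1.5

    # community model
    n_taxa: int = 60
    exposure_window_days: int = 10
    exposure_statistic: str = "Q5"       # trough family
    exposure_threshold: float = 92.0     # % saturation hinge
    effect_preset: str = "strong"
    nb_dispersion: float = 20.0
    baseline_log_mean: float = 3.0       # ln-scale mean abundance (pool)
    baseline_log_sd: float = 0.5
    site_pool_sigma: float = 0.3         # site-level filter on shared pool
    score_correlation: float = 0.7

    # sampling calendar: (month, day) per season, 2 replicates per occasion
    sampling_dates: tuple[tuple[int, int], ...] = ((4, 25), (7, 15), (10, 5))
    replicates: tuple[str, ...] = ("A", "B")

    seed: int = 0

    @property
    def beta(self) -> float:
        return EFFECT_PRESETS[self.effect_preset]

    @property
    def start_date(self) -> dt.date:
        return dt.date(self.start_year, 1, 1)

    @property
    def end_date(self) -> dt.date:
        return dt.date(self.start_year + self.n_years, 1, 1)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i + 1:02d}" for i in range(self.n_sites)]

    def sampling_calendar(self) -> list[dt.date]:
        dates = [dt.date(self.start_year + y, m, d)
                 for y in range(self.n_years) for m, d in self.sampling_dates]
        return sorted(dates)


@dataclass
class TruthRecord:
    """Ground truth written alongside every generated dataset."""

    driver_determinand: str
    driver_statistic_family: str
    true_window_days: int
    effect_preset: str
    exposures: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "driver_determinand": self.driver_determinand,
            "driver_statistic_family": self.driver_statistic_family,
            "true_window_days": self.true_window_days,
            "effect_preset": self.effect_preset,
            "exposures": self.exposures.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            driver_determinand=d["driver_determinand"],
            driver_statistic_family=d["driver_statistic_family"],
            true_window_days=int(d["true_window_days"]),
            effect_preset=d["effect_preset"],
            exposures=pd.DataFrame(d["exposures"]),
        )


def _site_rng(config: SimConfig, site_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, site_index, stream]))


def simulate_storms(config: SimConfig, site_id: str | None = None) -> pd.DataFrame:
    """Poisson storm arrivals per site.

    Columns: site_id, start (datetime64), duration_h, magnitude.  Event
    counts are Poisson(rate x span); start times uniform over the span.
    """
    sites = config.site_ids if site_id is None else [site_id]
    frames = []
    for i, sid in enumerate(config.site_ids):
        if sid not in sites:
            continue
        rng = _site_rng(config, i, 0)
        n_events = rng.poisson(config.storm_rate_per_day * config.n_days)
        start_day = np.sort(rng.uniform(0, config.n_days, n_events))
        starts = (np.datetime64(config.start_date, "ns")
                  + (start_day * 86400e9).astype("timedelta64[ns]"))
        frames.append(pd.DataFrame({
            "site_id": sid,
            "start": starts,
            "duration_h": rng.lognormal(np.log(8.0), 0.4, n_events),
            "magnitude": rng.lognormal(0.0, config.storm_magnitude_sigma,
                                       n_events),
        }))
    if not frames:
        return pd.DataFrame(columns=["site_id", "start", "duration_h",
                                     "magnitude"])
    return pd.concat(frames, ignore_index=True)


def _time_grid(config: SimConfig, resolution_min: int) -> np.ndarray:
    n = config.n_days * 1440 // resolution_min
    return (np.datetime64(config.start_date, "ns")
            + (np.arange(n) * resolution_min * 60e9).astype("timedelta64[ns]"))


def _event_response(
    grid_days: np.ndarray, events_day: np.ndarray, amplitudes: np.ndarray,
    rise_days: float, decay_days: float,
) -> np.ndarray:
    """Sum of rise-then-decay kernels, one per event, on the day-unit grid."""
    out = np.zeros_like(grid_days)
    horizon = 8.0 * decay_days + rise_days
    step = grid_days[1] - grid_days[0] if len(grid_days) > 1 else 1.0
    for t0, a in zip(events_day, amplitudes):
        i0 = int(np.searchsorted(grid_days, t0))
        i1 = int(np.searchsorted(grid_days, t0 + horizon))
        if i0 >= len(grid_days):
            continue
        rel = grid_days[i0:i1] - t0
        out[i0:i1] += a * (1 - np.exp(-rel / rise_days)) * np.exp(
            -rel / decay_days)
    return out


def _simulate_do(
    config: SimConfig, rng: np.random.Generator, t_day: np.ndarray,
    ev_day: np.ndarray, magnitudes: np.ndarray,
) -> np.ndarray:
    """DO % saturation: asymmetric diel cycle plus bounded storm sags.

    Daylight (a seasonally varying window of 8.5-15.5 h centred at 14:00)
    carries a photosynthetic plateau whose height is modulated day to day
    (bloom state); night sits a fixed respiration depression below
    baseline, so troughs track storms while peaks, means and medians also
    move with the independent bloom/photoperiod processes.  Sag depth
    saturates in event magnitude (a sag cannot exceed ``sag_max_depth``),
    and only a fraction of storms produce a sag at all -- oxygen
    depletion requires an organic load the storm may or may not carry.
    """
    model = DEFAULT_DETERMINANDS["DO"]
    doy = t_day % 365.25
    daylight_h = 12.0 + 3.5 * np.sin(2 * np.pi * (doy - 80.0) / 365.25)
    hour = (t_day % 1.0) * 24.0
    ramp_h = 1.5
    dayness = np.clip((daylight_h / 2 - np.abs(hour - 14.0)) / ramp_h + 0.5,
                      0.0, 1.0)
    day_idx = t_day.astype(int)
    bloom = rng.lognormal(0.0, config.bloom_sigma, day_idx.max() + 1)
    values = model.baseline + model.diel_amplitude * (
        dayness * bloom[day_idx] - (1.0 - dayness))
    if len(ev_day):
        mult = rng.lognormal(0.0, config.sag_event_sigma, len(ev_day))
        sagged = rng.random(len(ev_day)) < config.sag_probability
        depths = sagged * config.sag_max_depth * (
            1.0 - np.exp(-config.sag_shape * magnitudes * mult))
        values -= _event_response(
            t_day, ev_day, depths,
            config.storm_rise_hours / 24.0, config.sag_decay_days)
    if model.noise_sd:
        values = values + rng.normal(0.0, model.noise_sd, len(values))
    return np.clip(values, model.lower, model.upper)


def simulate_hydro(
    config: SimConfig, events: pd.DataFrame | None = None,
) -> list[HydroSeries]:
    """Hydrochemical series for every site and configured determinand.

    Each determinand is baseline + seasonal and diel sinusoids + storm
    flush kernels + Gaussian noise, clipped to physical bounds; DO has a
    dedicated model (photoperiod-asymmetric diel cycle, bloom modulation
    and bounded post-storm sags).  Sonde determinands are 15-min,
    nutrients 30-min.
    """
    if events is None:
        events = simulate_storms(config)
    out: list[HydroSeries] = []
    models = {d: DEFAULT_DETERMINANDS[d] for d in config.determinands}
    for i, sid in enumerate(config.site_ids):
        ev = events[events["site_id"] == sid]
        ev_day = ((ev["start"].to_numpy(dtype="datetime64[ns]")
                   - np.datetime64(config.start_date, "ns"))
                  / np.timedelta64(1, "D")).astype(float)
        magnitudes = ev["magnitude"].to_numpy(float)
        rng = _site_rng(config, i, 1)
        for det, model in models.items():
            res = (config.nutrient_resolution_min
                   if det in NUTRIENT_DETERMINANDS
                   else config.sonde_resolution_min)
            grid = _time_grid(config, res)
            t_day = (np.arange(len(grid)) * res) / 1440.0
            if det == "DO":
                do_rng = _site_rng(config, i, 3)
                values = _simulate_do(config, do_rng, t_day, ev_day,
                                      magnitudes)
                out.append(HydroSeries(
                    site_id=sid, determinand=det, timestamps=grid,
                    values=values, unit=model.unit, nominal_resolution=res))
                continue
            values = np.full(len(grid), model.baseline)
            if model.seasonal_amplitude:
                values += model.seasonal_amplitude * np.sin(
                    2 * np.pi * (t_day - 110.0) / 365.25)
            if model.diel_amplitude:
                # minimum in the early morning (~05:00)
                values += model.diel_amplitude * np.sin(
                    2 * np.pi * (t_day - 11.0 / 24.0))
            if model.flush_coef and len(ev_day):
                mult = rng.lognormal(0.0, config.event_det_sigma,
                                     len(ev_day))
                values += _event_response(
                    t_day, ev_day, model.flush_coef * magnitudes * mult,
                    config.storm_rise_hours / 24.0, model.decay_days)
            if model.noise_sd:
                values = values + rng.normal(0.0, model.noise_sd, len(grid))
            values = np.clip(values, model.lower, model.upper)
            out.append(HydroSeries(
                site_id=sid, determinand=det, timestamps=grid,
                values=values, unit=model.unit, nominal_resolution=res))
    return out


def _gaussian_copula_scores(
    rng: np.random.Generator, base: np.ndarray, rho: float, n_draws: int,
) -> np.ndarray:
    """Latents correlated ``rho`` with a shared base, as uniforms in (0,1)."""
    from scipy.stats import norm

    z_base = norm.ppf(base)
    z = rho * z_base[:, None] + np.sqrt(max(0.0, 1 - rho ** 2)) \
        * rng.standard_normal((len(base), n_draws))
    return norm.cdf(z)


def generate_score_table_fixtures(
    pool_size: int = 60, seed: int = 0, correlation: float | None = None,
) -> tuple[dict[str, ScoreTable], np.ndarray]:
    """Synthetic score tables for all seven indices over an invented pool.

    A shared latent "pollution sensitivity" per taxon drives every index's
    parameters through a Gaussian copula with configurable correlation, so
    the fixture reproduces the common-sensitivity structure that makes
    stressor-specific indices co-vary.  Returns (tables, sensitivity).
    Taxa are named ``taxon_000``..; each index scores a large random subset
    of the pool so some taxa go unscored per index.
    """
    rho = 0.7 if correlation is None else correlation
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    taxa = np.array([f"taxon_{i:03d}" for i in range(pool_size)])
    sensitivity = (rng.permutation(pool_size) + 0.5) / pool_size
    latents = _gaussian_copula_scores(rng, sensitivity, rho, 7)

    def subset(frac: float = 0.9) -> np.ndarray:
        keep = rng.random(pool_size) < frac
        if not keep.any():
            keep[0] = True
        return keep

    tables: dict[str, ScoreTable] = {}

    u = latents[:, 0]
    keep = subset()
    base = 1.0 + 9.0 * u[keep]
    # abundance weighting runs with sensitivity: scores of sensitive taxa
    # rise with abundance class, scores of tolerant taxa fall
    slope = 0.5 * (base - 5.5) / 4.5
    whpt = pd.DataFrame({
        f"s{c}": np.round(np.maximum(0.1, base + (c - 2.5) * slope), 2)
        for c in (1, 2, 3, 4)
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    tables["WHPT"] = ScoreTable("WHPT", whpt)

    u = latents[:, 1]
    keep = subset()
    groups = np.array(["VI", "V", "IV", "III", "II", "I"])
    life = pd.DataFrame({
        "flow_group": groups[np.minimum((u[keep] * 6).astype(int), 5)],
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    life_matrix = pd.DataFrame(
        [[9, 10, 11, 12], [8, 9, 10, 11], [7, 7, 7, 7],
         [6, 5, 4, 3], [5, 4, 3, 2], [4, 3, 2, 1]],
        index=["I", "II", "III", "IV", "V", "VI"],
        columns=["1", "2", "3", "4"], dtype=float)
    tables["LIFE"] = ScoreTable("LIFE", life, matrix=life_matrix)

    u = latents[:, 2]
    keep = subset()
    psi_groups = np.array(["D", "C", "B", "A"])
    psi = pd.DataFrame({
        "group": psi_groups[np.minimum((u[keep] * 4).astype(int), 3)],
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    psi_matrix = pd.DataFrame(
        [[2, 3, 4, 5], [1, 2, 3, 4], [1, 2, 3, 4], [0.5, 1, 1.5, 2]],
        index=["A", "B", "C", "D"], columns=["1", "2", "3", "4"],
        dtype=float)
    tables["PSI"] = ScoreTable("PSI", psi, matrix=psi_matrix)

    u = latents[:, 3]
    keep = subset()
    epsi = pd.DataFrame({
        "weight": np.round(0.1 + 0.9 * u[keep], 2),
        "sensitive": u[keep] > 0.5,
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    tables["ePSI"] = ScoreTable("ePSI", epsi)

    u = latents[:, 4]
    keep = subset()
    cofsi = pd.DataFrame({
        "ofsi": np.round(10.0 * u[keep], 2),
        "tofsi": np.round(np.clip(
            10.0 * u[keep] + rng.normal(0, 1.0, keep.sum()), 0, 10), 2),
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    tables["CoFSI"] = ScoreTable("CoFSI", cofsi, weights=(0.5, 0.5))

    u = latents[:, 5]
    keep = subset()
    trpi = pd.DataFrame({
        "score": np.round(1.0 + 9.0 * u[keep], 1),
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    tables["TRPI"] = ScoreTable("TRPI", trpi)

    u = latents[:, 6]
    keep = subset()
    spear = pd.DataFrame({
        "at_risk": u[keep] > 0.6,
    }, index=pd.Index(taxa[keep], name="taxon_id"))
    tables["SPEAR"] = ScoreTable("SPEAR", spear)

    return tables, sensitivity


def simulate_community(
    config: SimConfig,
    hydro: list[HydroSeries],
    sensitivity: np.ndarray | None = None,
) -> tuple[list[BioSample], TruthRecord]:
    """Replicate kick samples responding to DO-trough exposure.

    For each site and sampling date the exposure E is the configured trough
    statistic of DO over the true window D*; expected abundances shrink
    through the threshold hinge; counts are negative-binomial draws shared
    in expectation between the two replicates.
    """
    if sensitivity is None:
        _, sensitivity = generate_score_table_fixtures(
            config.n_taxa, config.seed, config.score_correlation)
    taxa = [f"taxon_{i:03d}" for i in range(config.n_taxa)]
    do_by_site = {s.site_id: s for s in hydro if s.determinand == "DO"}
    beta = config.beta
    q = {"Q5": 0.05, "Q10": 0.10, "min": 0.0}[config.exposure_statistic]

    # shared regional pool; each site filters it by a lognormal factor
    pool_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 55]))
    pool = np.exp(pool_rng.normal(config.baseline_log_mean,
                                  config.baseline_log_sd, config.n_taxa))

    samples: list[BioSample] = []
    exposure_rows = []
    for i, sid in enumerate(config.site_ids):
        rng = _site_rng(config, i, 2)
        baselines = pool * rng.lognormal(0.0, config.site_pool_sigma,
                                         config.n_taxa)
        series = do_by_site.get(sid)
        for date in config.sampling_calendar():
            if series is not None:
                _, vals, coverage = extract_window(
                    series, date, config.exposure_window_days)
                exposure = quantile(vals, q) if vals.size else float("nan")
            else:
                exposure, coverage = float("nan"), 0.0
            deficit = (max(0.0, config.exposure_threshold - exposure)
                       if np.isfinite(exposure) else 0.0)
            lam = baselines * np.exp(-beta * sensitivity * deficit)
            for rep in config.replicates:
                k = config.nb_dispersion
                counts = rng.negative_binomial(k, k / (k + lam))
                samples.append(BioSample(
                    site_id=sid, sample_date=date,
                    season=season_of(date), replicate_id=rep,
                    counts={t: int(c) for t, c in zip(taxa, counts)
                            if c > 0}))
            exposure_rows.append({
                "site_id": sid, "sample_date": date.isoformat(),
                "exposure": exposure, "deficit": deficit,
                "coverage": coverage})
    truth = TruthRecord(
        driver_determinand="DO",
        driver_statistic_family="trough",
        true_window_days=config.exposure_window_days,
        effect_preset=config.effect_preset,
        exposures=pd.DataFrame(exposure_rows))
    return samples, truth


@dataclass
class SyntheticDataset:
    """In-memory bundle: everything the pipeline reads, plus the truth."""

    config: SimConfig
    events: pd.DataFrame
    hydro: list[HydroSeries]
    bio_samples: list[BioSample]
    score_tables: dict[str, ScoreTable]
    sensitivity: np.ndarray
    truth: TruthRecord


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full deterministic bundle for one seed: storms, hydro, community,
    score tables and the truth record."""
    events = simulate_storms(config)
    hydro = simulate_hydro(config, events)
    tables, sensitivity = generate_score_table_fixtures(
        config.n_taxa, config.seed, config.score_correlation)
    samples, truth = simulate_community(config, hydro, sensitivity)
    return SyntheticDataset(
        config=config, events=events, hydro=hydro, bio_samples=samples,
        score_tables=tables, sensitivity=sensitivity, truth=truth)
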