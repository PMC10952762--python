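"""Synthetic-data generator: determinism, closed forms, truth labelling."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bioassess.indices import compute_whpt
from bioassess.simulate import (SimConfig, generate_dataset,
                                generate_score_table_fixtures,
                                simulate_community, simulate_hydro,
                                simulate_storms, _event_response)
from bioassess.windows import extract_window, quantile


def small_config(**kw):
    defaults = dict(n_sites=2, n_years=1, sonde_resolution_min=30,
                    determinands=("DO", "discharge"), seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestStorms:
    def test_zero_rate_no_events(self):
        events = simulate_storms(small_config(storm_rate_per_day=0.0))
        assert len(events) == 0

    def test_poisson_expectation(self):
        # rate 0.2/day over 3 years: mean count ~ 219 per site
        counts = []
        for seed in range(60):
            config = SimConfig(n_sites=1, n_years=3,
                               determinands=("DO",),
                               storm_rate_per_day=0.2, seed=seed)
            counts.append(len(simulate_storms(config)))
        expected = 0.2 * config.n_days
        tol = 3 * np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < tol

    def test_determinism(self):
        config = small_config(seed=9)
        a = simulate_storms(config)
        b = simulate_storms(config)
        pd.testing.assert_frame_equal(a, b)


class TestHydro:
    def test_quiet_do_trough_near_baseline_minus_amplitude(self):
        config = small_config(storm_rate_per_day=0.0, bloom_sigma=0.0)
        hydro = simulate_hydro(config)
        do = next(s for s in hydro if s.determinand == "DO")
        import datetime as dt
        _, vals, _ = extract_window(do, dt.date(config.start_year, 6, 1), 10)
        # night plateau sits one diel amplitude below baseline
        assert quantile(vals, 0.05) == pytest.approx(95.0 - 10.0, abs=2.0)

    def test_single_event_turbidity_peak_within_bounds(self):
        config = small_config(determinands=("turbidity",),
                              storm_rate_per_day=0.0)
        events = pd.DataFrame({
            "site_id": ["site01"],
            "start": [np.datetime64("2010-06-10T06:00:00", "ns")],
            "duration_h": [8.0], "magnitude": [2.0]})
        hydro = simulate_hydro(config, events)
        turb = next(s for s in hydro if s.site_id == "site01")
        peak_idx = int(np.argmax(turb.values))
        peak_time = turb.timestamps[peak_idx]
        assert np.datetime64("2010-06-10") <= peak_time
        assert peak_time <= np.datetime64("2010-06-13")
        other = next(s for s in hydro if s.site_id == "site02")
        assert other.values.max() < turb.values.max()

    def test_sag_depth_closed_form(self):
        config = small_config(storm_rate_per_day=0.0, bloom_sigma=0.0,
                              sag_event_sigma=0.0, sag_probability=1.0)
        events = pd.DataFrame({
            "site_id": ["site01"],
            "start": [np.datetime64("2010-06-10T00:00:00", "ns")],
            "duration_h": [8.0], "magnitude": [3.0]})
        hydro = simulate_hydro(config, events)
        do = next(s for s in hydro if s.site_id == "site01"
                  and s.determinand == "DO")
        depth = config.sag_max_depth * (
            1 - np.exp(-config.sag_shape * 3.0))
        # kernel peak factor evaluated from the generator's closed form
        rise = config.storm_rise_hours / 24.0
        decay = config.sag_decay_days
        rel = np.linspace(0, 10, 20001)
        kernel_peak = ((1 - np.exp(-rel / rise)) * np.exp(-rel / decay)).max()
        expected_min = 95.0 - 10.0 - depth * kernel_peak
        window = (do.timestamps >= np.datetime64("2010-06-10")) & \
                 (do.timestamps < np.datetime64("2010-06-13"))
        assert do.values[window].min() == pytest.approx(expected_min,
                                                        abs=2.5)

    def test_resolutions(self):
        config = small_config(determinands=("DO", "TP"))
        hydro = simulate_hydro(config)
        res = {s.determinand: s.nominal_resolution for s in hydro}
        assert res["DO"] == config.sonde_resolution_min
        assert res["TP"] == config.nutrient_resolution_min

    def test_physical_bounds(self):
        hydro = simulate_hydro(small_config(seed=3))
        for s in hydro:
            assert np.isfinite(s.values).all()
            if s.determinand == "DO":
                assert s.values.min() >= 0 and s.values.max() <= 150


class TestScoreFixtures:
    def test_zero_knob_decorrelates(self):
        tables, sens = generate_score_table_fixtures(60, seed=2,
                                                     correlation=0.0)
        whpt = tables["WHPT"].entries
        aligned = sens[[int(t.split("_")[1]) for t in whpt.index]]
        r = sps.spearmanr(aligned, whpt["s2"]).statistic
        assert abs(r) < 0.35

    def test_full_knob_rank_identical(self):
        tables, sens = generate_score_table_fixtures(60, seed=2,
                                                     correlation=1.0)
        whpt = tables["WHPT"].entries
        aligned = sens[[int(t.split("_")[1]) for t in whpt.index]]
        r = sps.spearmanr(aligned, whpt["s2"]).statistic
        assert r > 0.999

    def test_partial_knob_mean_correlation(self):
        rs = []
        for seed in range(25):
            tables, sens = generate_score_table_fixtures(60, seed=seed,
                                                         correlation=0.7)
            whpt = tables["WHPT"].entries
            aligned = sens[[int(t.split("_")[1]) for t in whpt.index]]
            rs.append(sps.spearmanr(aligned, whpt["s2"]).statistic)
        assert abs(np.mean(rs) - 0.7) < 0.15

    def test_schema_valid_for_all_indices(self, score_tables):
        assert set(score_tables) == {"WHPT", "LIFE", "PSI", "ePSI",
                                     "CoFSI", "TRPI", "SPEAR"}


class TestCommunity:
    def test_replicates_share_expectation_not_counts(self):
        config = small_config(effect_preset="strong", seed=4)
        hydro = simulate_hydro(config)
        samples, truth = simulate_community(config, hydro)
        by_occasion = {}
        for s in samples:
            by_occasion.setdefault((s.site_id, s.sample_date), []).append(s)
        assert all(len(v) == 2 for v in by_occasion.values())
        differing = sum(a.counts != b.counts
                        for a, b in by_occasion.values())
        assert differing > 0

    def test_null_preset_uncorrelated_with_exposure(self):
        rs = []
        for seed in range(10):
            config = small_config(effect_preset="none", seed=seed,
                                  n_sites=3)
            hydro = simulate_hydro(config)
            samples, truth = simulate_community(config, hydro)
            tables, _ = generate_score_table_fixtures(config.n_taxa,
                                                      config.seed)
            exposures = truth.exposures.set_index(
                ["site_id", "sample_date"])["exposure"]
            pairs = [(exposures[(s.site_id, s.sample_date.isoformat())],
                      compute_whpt(s, tables["WHPT"])[2])
                     for s in samples]
            x, y = zip(*[(a, b) for a, b in pairs if b is not None])
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_strong_preset_positive_rank_correlation(self):
        config = small_config(effect_preset="strong", seed=6, n_sites=3,
                              n_years=2)
        hydro = simulate_hydro(config)
        samples, truth = simulate_community(config, hydro)
        tables, _ = generate_score_table_fixtures(config.n_taxa, config.seed)
        exposures = truth.exposures.set_index(
            ["site_id", "sample_date"])["exposure"]
        pairs = [(exposures[(s.site_id, s.sample_date.isoformat())],
                  compute_whpt(s, tables["WHPT"])[2]) for s in samples]
        x, y = zip(*[(a, b) for a, b in pairs if b is not None])
        rho = sps.spearmanr(x, y).statistic
        assert rho > 0.4  # higher exposure (better oxygen) -> higher ASPT


class TestGenerateDataset:
    def test_default_design_arithmetic(self):
        config = SimConfig(seed=0, determinands=("DO",))
        ds = generate_dataset(config)
        # 7 sites x 3 years x 3 seasons x 2 replicates
        assert len(ds.bio_samples) == 126
        assert len({s.site_id for s in ds.bio_samples}) == 7
        assert len(ds.hydro) == 7

    def test_seed_changes_values_not_schema(self):
        a = generate_dataset(small_config(seed=1))
        b = generate_dataset(small_config(seed=2))
        assert len(a.bio_samples) == len(b.bio_samples)
        assert not np.array_equal(a.hydro[0].values, b.hydro[0].values)

    def test_bit_reproducible(self):
        a = generate_dataset(small_config(seed=7))
        b = generate_dataset(small_config(seed=7))
        for sa, sb in zip(a.hydro, b.hydro):
            np.testing.assert_array_equal(sa.values, sb.values)
        assert [s.counts for s in a.bio_samples] == \
            [s.counts for s in b.bio_samples]


def test_event_response_kernel_shape():
    grid = np.linspace(0, 20, 2000)
    out = _event_response(grid, np.array([5.0]), np.array([2.0]),
                          rise_days=0.2, decay_days=1.0)
    assert out[grid < 5].max() == 0.0
    assert out.max() <= 2.0
    peak = grid[np.argmax(out)]
    assert 5.0 < peak < 6.5
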