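"""Biotic index calculators against hand-tallied oracles and invariants."""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bioassess.indices import (abundance_class, compute_cofsi,
                               compute_index_suite, compute_life,
                               compute_log_abundance, compute_trpi,
                               compute_weighted_proportion_index,
                               compute_whpt)
from bioassess.types import InvalidInputError, ScoreTable
from conftest import make_sample


class TestAbundanceClass:
    @pytest.mark.parametrize("count,expected", [
        (1, 1), (9, 1), (10, 2), (99, 2), (100, 3), (999, 3),
        (1000, 4), (50000, 4),
    ])
    def test_band_edges(self, count, expected):
        assert abundance_class(count) == expected

    @pytest.mark.parametrize("count", [0, -1, -100])
    def test_nonpositive_rejected(self, count):
        with pytest.raises(InvalidInputError):
            abundance_class(count)


class TestWhpt:
    def test_flat_scores_mean(self, whpt_flat_table):
        sample = make_sample({"mayfly": 3, "worm": 40})
        ntaxa, total, aspt = compute_whpt(sample, whpt_flat_table)
        assert (ntaxa, total, aspt) == (2, 14.0, 7.0)

    def test_no_scoring_taxa_missing(self, whpt_flat_table):
        sample = make_sample({"beetle": 5})
        ntaxa, total, aspt = compute_whpt(sample, whpt_flat_table)
        assert ntaxa == 0 and aspt is None

    def test_class_dependent_hand_tally(self):
        # classes selected by counts {5, 150, 2000} -> {1, 3, 4}
        entries = pd.DataFrame(
            {"s1": [5.1, 2.0, 9.0], "s2": [4.8, 2.2, 8.5],
             "s3": [4.5, 2.4, 8.0], "s4": [4.2, 2.6, 7.5]},
            index=pd.Index(["a", "b", "c"], name="taxon_id"))
        table = ScoreTable("WHPT", entries)
        sample = make_sample({"a": 5, "b": 150, "c": 2000})
        ntaxa, total, aspt = compute_whpt(sample, table)
        assert ntaxa == 3
        assert total == pytest.approx(5.1 + 2.4 + 7.5)
        assert aspt == pytest.approx((5.1 + 2.4 + 7.5) / 3)

    def test_taxa_absent_from_table_ignored(self, whpt_flat_table):
        base = make_sample({"mayfly": 3})
        extended = make_sample({"mayfly": 3, "unknown_bug": 500})
        assert compute_whpt(base, whpt_flat_table) == \
            compute_whpt(extended, whpt_flat_table)


@pytest.fixture
def life_table():
    entries = pd.DataFrame(
        {"flow_group": ["I", "II", "III", "V", "VI"]},
        index=pd.Index(list("abcde"), name="taxon_id"))
    matrix = pd.DataFrame(
        [[9, 10, 11, 12], [8, 9, 10, 11], [7, 7, 7, 7],
         [5, 4, 3, 2], [4, 3, 2, 1]],
        index=["I", "II", "III", "V", "VI"],
        columns=["1", "2", "3", "4"], dtype=float)
    return ScoreTable("LIFE", entries, matrix=matrix)


class TestLife:
    def test_single_taxon_identity(self, life_table):
        # group I at class 1 maps to flow score 9
        assert compute_life(make_sample({"a": 5}), life_table) == 9.0

    def test_two_taxon_average(self, life_table):
        # group I class 1 -> 9; group V class 1 -> 5
        assert compute_life(make_sample({"a": 5, "d": 5}), life_table) == 7.0

    def test_five_taxon_hand_tally(self, life_table):
        counts = {"a": 5, "b": 50, "c": 500, "d": 5000, "e": 1}
        # independent tally: group x class lookups
        expected = (9 + 9 + 7 + 2 + 4) / 5
        assert compute_life(make_sample(counts), life_table) == \
            pytest.approx(expected)

    def test_illegal_flow_group_rejected(self):
        entries = pd.DataFrame({"flow_group": ["VII"]},
                               index=pd.Index(["a"], name="taxon_id"))
        with pytest.raises(Exception):
            ScoreTable("LIFE", entries, matrix=pd.DataFrame())


@pytest.fixture
def psi_table():
    entries = pd.DataFrame(
        {"group": ["A", "B", "C", "D"]},
        index=pd.Index(list("abcd"), name="taxon_id"))
    matrix = pd.DataFrame(
        [[2, 3, 4, 5], [1, 2, 3, 4], [1, 2, 3, 4], [0.5, 1, 1.5, 2]],
        index=["A", "B", "C", "D"], columns=["1", "2", "3", "4"],
        dtype=float)
    return ScoreTable("PSI", entries, matrix=matrix)


class TestProportionIndices:
    def test_psi_all_sensitive_is_100(self, psi_table):
        assert compute_weighted_proportion_index(
            make_sample({"a": 5, "b": 10}), psi_table, "PSI") == 100.0

    def test_psi_no_sensitive_is_0(self, psi_table):
        assert compute_weighted_proportion_index(
            make_sample({"c": 5, "d": 10}), psi_table, "PSI") == 0.0

    def test_psi_hand_tally(self, psi_table):
        # a: A class2 -> 3 (sensitive); c: C class1 -> 1; d: D class3 -> 1.5
        value = compute_weighted_proportion_index(
            make_sample({"a": 10, "c": 5, "d": 150}), psi_table, "PSI")
        assert value == pytest.approx(100 * 3 / (3 + 1 + 1.5))

    def test_spear_closed_form(self):
        entries = pd.DataFrame({"at_risk": [True, False]},
                               index=pd.Index(["r", "n"], name="taxon_id"))
        table = ScoreTable("SPEAR", entries)
        value = compute_weighted_proportion_index(
            make_sample({"r": 9, "n": 99}), table, "SPEAR")
        assert value == pytest.approx(
            100 * math.log10(10) / (math.log10(10) + math.log10(100)))

    def test_empty_sample_missing(self, psi_table):
        assert compute_weighted_proportion_index(
            make_sample({}), psi_table, "PSI") is None


class TestCofsi:
    def make_table(self, weights=(0.5, 0.5)):
        entries = pd.DataFrame(
            {"ofsi": [6.0, 2.0, np.nan], "tofsi": [np.nan, 4.0, 8.0]},
            index=pd.Index(["o", "both", "t"], name="taxon_id"))
        return ScoreTable("CoFSI", entries, weights=weights)

    def test_symmetric_combination(self):
        entries = pd.DataFrame({"ofsi": [50.0], "tofsi": [50.0]},
                               index=pd.Index(["x"], name="taxon_id"))
        value, flags = compute_cofsi(make_sample({"x": 5}),
                                     ScoreTable("CoFSI", entries))
        assert value == 50.0 and not flags

    def test_partial_flagged(self):
        value, flags = compute_cofsi(make_sample({"o": 5}), self.make_table())
        assert value == 6.0
        assert any("partial" in f for f in flags)

    def test_hand_combined(self):
        table = self.make_table(weights=(0.3, 0.7))
        sample = make_sample({"o": 5, "both": 150, "t": 20})
        # abundance classes: o->1, both->3, t->2
        ofsi = (1 * 6.0 + 3 * 2.0) / (1 + 3)
        tofsi = (3 * 4.0 + 2 * 8.0) / (3 + 2)
        value, flags = compute_cofsi(sample, table)
        assert value == pytest.approx(0.3 * ofsi + 0.7 * tofsi)


class TestTrpi:
    @pytest.fixture
    def trpi_table(self):
        entries = pd.DataFrame(
            {"score": [2.0, 5.0, 8.0, 10.0]},
            index=pd.Index(list("abcd"), name="taxon_id"))
        return ScoreTable("TRPI", entries)

    def test_summer_suppressed(self, trpi_table):
        value, flags = compute_trpi(
            make_sample({"a": 5}, season="summer"), trpi_table)
        assert value is None
        assert flags == ["TRPI suppressed: summer sample"]

    def test_single_taxon_identity(self, trpi_table):
        value, _ = compute_trpi(make_sample({"b": 7}), trpi_table)
        assert value == 5.0

    def test_four_taxon_autumn_hand_tally(self, trpi_table):
        sample = make_sample({"a": 5, "b": 50, "c": 500, "d": 5000},
                             season="autumn")
        expected = (1 * 2 + 2 * 5 + 3 * 8 + 4 * 10) / (1 + 2 + 3 + 4)
        value, _ = compute_trpi(sample, trpi_table)
        assert value == pytest.approx(expected)


class TestLogAbundance:
    @pytest.mark.parametrize("counts,expected", [
        ({}, 0.0), ({"a": 99}, 2.0), ({"a": 9000, "b": 999}, 4.0),
    ])
    def test_offset_log(self, counts, expected):
        assert compute_log_abundance(make_sample(counts)) == \
            pytest.approx(expected)


class TestIndexSuite:
    def test_rich_sample_matches_single_ops(self, score_tables):
        sample = make_sample({f"taxon_{i:03d}": 5 * (i + 1)
                              for i in range(0, 40, 2)})
        result = compute_index_suite(sample, score_tables)
        ntaxa, _, aspt = compute_whpt(sample, score_tables["WHPT"])
        assert result.ntaxa_whpt == ntaxa
        assert result.aspt_whpt == aspt
        assert result.life == compute_life(sample, score_tables["LIFE"])
        assert result.psi == compute_weighted_proportion_index(
            sample, score_tables["PSI"], "PSI")
        assert result.spear == compute_weighted_proportion_index(
            sample, score_tables["SPEAR"], "SPEAR")

    def test_empty_sample_all_missing(self, score_tables):
        result = compute_index_suite(make_sample({}), score_tables)
        assert result.log_abundance == 0.0
        assert result.aspt_whpt is None and result.life is None
        assert result.trpi is None and result.spear is None

    def test_summer_sample_trpi_missing_others_present(self, score_tables):
        sample = make_sample({f"taxon_{i:03d}": 20 for i in range(30)},
                             season="summer")
        result = compute_index_suite(sample, score_tables)
        assert result.trpi is None
        assert "TRPI suppressed: summer sample" in result.flags
        assert result.aspt_whpt is not None


# -- property tests ---------------------------------------------------------

communities = st.dictionaries(
    st.sampled_from([f"taxon_{i:03d}" for i in range(60)]),
    st.integers(min_value=1, max_value=50000), min_size=1, max_size=30)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(counts=communities)
def test_percentage_indices_bounded(counts):
    from bioassess.simulate import generate_score_table_fixtures
    tables, _ = generate_score_table_fixtures(60, seed=11)
    sample = make_sample(dict(counts))
    for variant in ("PSI", "ePSI", "SPEAR"):
        value = compute_weighted_proportion_index(
            sample, tables[variant], variant)
        if value is not None:
            assert 0.0 <= value <= 100.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(counts=communities, data=st.data())
def test_aspt_invariant_to_class_preserving_perturbation(counts, data):
    """Any abundance change that keeps every taxon's class keeps ASPT."""
    from bioassess.simulate import generate_score_table_fixtures
    tables, _ = generate_score_table_fixtures(60, seed=11)
    sample = make_sample(dict(counts))
    bands = {1: (1, 9), 2: (10, 99), 3: (100, 999), 4: (1000, 50000)}
    perturbed = {}
    for taxon, count in counts.items():
        from bioassess.indices import abundance_class
        lo, hi = bands[abundance_class(count)]
        perturbed[taxon] = data.draw(st.integers(lo, hi))
    a1 = compute_whpt(sample, tables["WHPT"])[2]
    a2 = compute_whpt(make_sample(perturbed), tables["WHPT"])[2]
    assert a1 == a2


def test_ntaxa_matches_brute_force_on_random_communities(score_tables):
    rng = np.random.default_rng(42)
    taxa = [f"taxon_{i:03d}" for i in range(60)]
    scoring = score_tables["WHPT"].taxa
    for _ in range(300):
        k = rng.integers(1, 40)
        chosen = rng.choice(taxa, size=k, replace=False)
        counts = {t: int(rng.integers(1, 2000)) for t in chosen}
        sample = make_sample(counts)
        ntaxa, _, _ = compute_whpt(sample, score_tables["WHPT"])
        assert ntaxa == sum(1 for t in counts if t in scoring)


def test_permutation_invariance(score_tables):
    rng = np.random.default_rng(7)
    taxa = [f"taxon_{i:03d}" for i in range(40)]
    counts = {t: int(rng.integers(1, 3000)) for t in taxa}
    shuffled = dict(reversed(list(counts.items())))
    r1 = compute_index_suite(make_sample(counts), score_tables)
    r2 = compute_index_suite(make_sample(shuffled), score_tables)
    assert r1.as_row() == {**r2.as_row()}


def test_removing_lowest_scoring_taxon_never_decreases_aspt(score_tables):
    rng = np.random.default_rng(13)
    table = score_tables["WHPT"]
    taxa = sorted(table.taxa)
    for _ in range(50):
        chosen = rng.choice(taxa, size=8, replace=False)
        counts = {t: int(rng.integers(1, 2000)) for t in chosen}
        sample = make_sample(counts)
        _, _, aspt = compute_whpt(sample, table)
        # find the taxon contributing the lowest class score
        def score_of(t):
            from bioassess.indices import abundance_class
            return float(table.entries.at[t, f"s{abundance_class(counts[t])}"])
        lowest = min(chosen, key=score_of)
        reduced = {t: c for t, c in counts.items() if t != lowest}
        _, _, aspt2 = compute_whpt(make_sample(reduced), table)
        assert aspt2 >= aspt - 1e-12
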