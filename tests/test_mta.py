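"""Marker-trait association: test routing, post hoc, BH-FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from applegap.data_io import DataError, MarkerDef
from applegap.mta import (
    ANOVA,
    KRUSKAL_WALLIS,
    MANN_WHITNEY,
    T_TEST,
    GenotypeGroups,
    InsufficientGroupsError,
    bh_adjust,
    choose_test,
    dunn_bonferroni,
    group_by_genotype,
    run_mta,
    tukey_posthoc,
)
from applegap.simdata import default_panel, simulate_cross

MARKER = MarkerDef("SIZE0001", "Chr01", 1_000_000, "C", "A")


def make_groups(*arrays, labels=("CC", "CA", "AA")):
    return GenotypeGroups("SIZE0001", dict(zip(labels, map(np.asarray, arrays))))


class TestGrouping:
    def test_mendelian_marker_gives_three_groups(self):
        panel = default_panel(1)
        matrix = simulate_cross(np.array([1]), np.array([1]), 88, seed=3, panel=panel)
        phen = pd.Series(
            np.random.default_rng(0).normal(180, 25, 88), index=matrix.individual_ids
        )
        groups = group_by_genotype(
            matrix.calls[:, 0], panel[0], phen, matrix.individual_ids
        )
        assert groups.n_groups == 3

    def test_backcross_marker_gives_two_groups(self):
        panel = default_panel(1)
        matrix = simulate_cross(np.array([0]), np.array([1]), 88, seed=3, panel=panel)
        phen = pd.Series(
            np.random.default_rng(0).normal(180, 25, 88), index=matrix.individual_ids
        )
        groups = group_by_genotype(
            matrix.calls[:, 0], panel[0], phen, matrix.individual_ids
        )
        assert groups.n_groups == 2

    def test_small_groups_dropped(self):
        calls = np.array([0] * 50 + [1] * 2 + [2] * 48)
        ids = [f"i{k}" for k in range(100)]
        phen = pd.Series(np.arange(100, dtype=float) + 100, index=ids)
        groups = group_by_genotype(calls, MARKER, phen, ids, min_group_n=3)
        assert groups.n_groups == 2
        assert set(groups.group_ns.values()) == {50, 48}

    def test_fewer_than_two_groups_is_untested(self):
        calls = np.array([0] * 10 + [1] * 2)
        ids = [f"i{k}" for k in range(12)]
        phen = pd.Series(np.linspace(100, 200, 12), index=ids)
        with pytest.raises(InsufficientGroupsError):
            group_by_genotype(calls, MARKER, phen, ids)


class TestChooseTest:
    def test_normal_equal_variance_routes_to_anova(self):
        rng = np.random.default_rng(11)
        groups = make_groups(*(rng.normal(180, 25, 40) for _ in range(3)))
        assert choose_test(groups) == ANOVA

    def test_two_normal_groups_route_to_t_test(self):
        rng = np.random.default_rng(11)
        groups = make_groups(rng.normal(180, 25, 40), rng.normal(190, 25, 40),
                             labels=("CC", "CA"))
        assert choose_test(groups) == T_TEST

    def test_skewed_two_groups_route_to_mann_whitney(self):
        rng = np.random.default_rng(11)
        groups = make_groups(rng.lognormal(5, 1, 60), rng.lognormal(5.2, 1, 60),
                             labels=("CC", "CA"))
        assert choose_test(groups) == MANN_WHITNEY

    def test_heteroscedastic_three_groups_route_to_kruskal(self):
        rng = np.random.default_rng(11)
        groups = make_groups(
            rng.normal(180, 5, 40), rng.normal(180, 5, 40), rng.normal(180, 125, 40)
        )
        assert choose_test(groups) == KRUSKAL_WALLIS


class TestPosthoc:
    def test_tukey_flags_separated_pair(self):
        rng = np.random.default_rng(4)
        groups = make_groups(
            rng.normal(150, 10, 30), rng.normal(180, 10, 30), rng.normal(210, 10, 30)
        )
        comparisons = tukey_posthoc(groups)
        assert len(comparisons) == 3
        assert all(c.significant for c in comparisons)

    def test_dunn_flags_separated_pair_and_caps_p(self):
        rng = np.random.default_rng(4)
        groups = make_groups(
            rng.normal(150, 10, 30), rng.normal(150, 10, 30), rng.normal(250, 10, 30)
        )
        comparisons = dunn_bonferroni(groups)
        by_pair = {c.pair: c for c in comparisons}
        assert by_pair["CC-AA"].significant
        assert by_pair["CA-AA"].significant
        assert not by_pair["CC-CA"].significant
        assert all(0.0 <= c.adjusted_p <= 1.0 for c in comparisons)

    def test_dunn_handles_ties(self):
        groups = make_groups(
            np.array([1.0, 1.0, 1.0, 2.0]), np.array([1.0, 2.0, 2.0, 2.0]),
            labels=("CC", "CA"),
        )
        comparisons = dunn_bonferroni(groups)
        assert np.isfinite(comparisons[0].adjusted_p)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvalues,expected",
        [
            ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
        ],
    )
    def test_step_up_hand_cases(self, pvalues, expected):
        assert bh_adjust(pvalues) == pytest.approx(expected)

    def test_matches_direct_quadratic_definition(self):
        """Oracle: q(i) = min over j>=i of p(j) m / j, computed the slow way."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            order = np.argsort(p)
            ranks = np.empty(m, dtype=int)
            ranks[order] = np.arange(1, m + 1)
            oracle = np.array(
                [
                    min(
                        min(p[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]),
                        1.0,
                    )
                    for i in range(m)
                ]
            )
            assert bh_adjust(p) == pytest.approx(oracle, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(60)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert bh_adjust(p) == pytest.approx(q_sm, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_monotone_and_dominates_raw_p(self, pvalues):
        q = bh_adjust(pvalues)
        order = np.argsort(pvalues, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= np.asarray(pvalues) - 1e-12)
        assert np.all(q <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])


class TestRunMta:
    def _study(self, effect, n=100, seed=0, n_markers=10):
        panel = default_panel(n_markers)
        rng = np.random.default_rng(seed)
        matrix = simulate_cross(
            np.ones(n_markers, dtype=np.int8), np.ones(n_markers, dtype=np.int8),
            n, rng, panel=panel,
        )
        sd = 25.0
        phen = rng.normal(180.0, sd, n) + effect * sd * matrix.calls[:, 0]
        return matrix, pd.Series(phen, index=matrix.individual_ids), panel

    def test_planted_effect_detected(self):
        matrix, phen, panel = self._study(effect=1.5)
        records = run_mta(matrix, phen, [m.marker_id for m in panel])
        by_id = {r.marker_id: r for r in records}
        assert by_id["SIZE0001"].significant
        assert by_id["SIZE0001"].q_value < 0.05

    def test_single_marker_q_equals_raw_p(self):
        matrix, phen, panel = self._study(effect=0.5, n_markers=1)
        records = run_mta(matrix, phen, ["SIZE0001"])
        assert records[0].q_value == pytest.approx(records[0].raw_p)

    def test_permutation_null_controlled(self):
        matrix, phen, panel = self._study(effect=0.0, n=150, n_markers=30, seed=7)
        records = run_mta(matrix, phen, [m.marker_id for m in panel])
        assert sum(r.significant for r in records) == 0

    def test_empty_eligible_set_gives_empty_list(self):
        matrix, phen, _ = self._study(effect=0.0)
        assert run_mta(matrix, phen, []) == []

    def test_power_increases_with_effect_size(self):
        hits = []
        for effect in (0.0, 0.6, 1.5):
            count = 0
            for seed in range(8):
                matrix, phen, panel = self._study(effect=effect, seed=seed,
                                                  n_markers=5)
                records = run_mta(matrix, phen, [m.marker_id for m in panel])
                count += sum(r.significant and r.marker_id == "SIZE0001"
                             for r in records)
            hits.append(count)
        assert hits[0] <= hits[1] <= hits[2]
        assert hits[2] >= 7

    def test_significant_record_invariants(self):
        matrix, phen, panel = self._study(effect=1.5)
        for rec in run_mta(matrix, phen, [m.marker_id for m in panel]):
            assert rec.q_value >= rec.raw_p - 1e-12
            if rec.significant:
                assert rec.raw_p < 0.05 and rec.q_value < 0.05
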