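"""GAP model fitting, prediction, and Pearson accuracy."""

import numpy as np
import pandas as pd
import pytest

from applegap.data_io import DataError, GenotypeMatrix
from applegap.gap import GapModel, accuracy, fit_gap, predict, significance_stars
from applegap.screening import MarkerCombination
from applegap.simdata import (
    SimConfig,
    default_panel,
    simulate_cross,
    simulate_phenotypes,
)


def combo(marker_ids, name="mta"):
    return MarkerCombination(name, "testpop", list(marker_ids))


def phen(values, ids):
    return pd.Series(np.asarray(values, dtype=float), index=list(ids),
                     name="fruit_weight")


def additive_study(n, n_markers, effect, noise_sd, seed, het_parents=True):
    """One segregating cross with the first marker(s) causal."""
    panel = default_panel(n_markers)
    rng = np.random.default_rng(seed)
    parents = np.ones(n_markers, dtype=np.int8)
    matrix = simulate_cross(parents, parents, n, rng, panel=panel)
    config = SimConfig(
        populations=[], panel=panel,
        effect_map={m.marker_id: e for m, e in zip(panel, effect)},
        base_mean=200.0, noise_sd=noise_sd, missing_rate=0.0, seed=seed,
    )
    weights = simulate_phenotypes(matrix, config, rng)
    return matrix, weights, panel


class TestFitGap:
    def test_single_marker_effects_are_group_mean_deviations(self):
        # 10 hom-ref individuals at 150 g, 10 hom-alt at 250 g -> mu = 200
        calls = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        ids = [f"i{k}" for k in range(20)]
        matrix = GenotypeMatrix(ids, default_panel(1), calls)
        weights = phen([150.0] * 10 + [250.0] * 10, ids)
        model = fit_gap(matrix, weights, combo(["SIZE0001"]), seed=0)
        assert model.mu == pytest.approx(200.0)
        assert model.effects[("SIZE0001", 0)] == pytest.approx(-50.0)
        assert model.effects[("SIZE0001", 2)] == pytest.approx(50.0)

    def test_noiseless_additive_data_fit_almost_perfectly(self):
        matrix, weights, panel = additive_study(
            n=300, n_markers=10, effect=[10, -8, 12, 7, -9, 11, 8, -10, 9, 13],
            noise_sd=0.0, seed=3,
        )
        model = fit_gap(matrix, weights, combo([m.marker_id for m in panel]), seed=3)
        gpv = predict(model, matrix)
        r, _, _ = accuracy(gpv, weights)
        # marginal genotype-mean effects leave a little cross-marker noise in
        # each estimate, so self-consistency is near-perfect, not exact
        assert r > 0.95

    def test_null_phenotype_gives_near_zero_cv_accuracy(self):
        from applegap.pipeline import cross_validated_gpv

        matrix, weights, panel = additive_study(
            n=200, n_markers=10, effect=[0.0] * 10, noise_sd=25.0, seed=9,
        )
        gpv = cross_validated_gpv(matrix, weights, combo([m.marker_id for m in panel]),
                                  seed=9)
        r, _, _ = accuracy(gpv, weights)
        assert abs(r) < 0.25

    def test_empty_combination_rejected(self, tiny_matrix, tiny_phenotypes):
        with pytest.raises(DataError):
            fit_gap(tiny_matrix, tiny_phenotypes, combo([]), seed=0)

    def test_monomorphic_training_marker_contributes_constant(self):
        calls = np.zeros((10, 1), dtype=np.int8)
        ids = [f"i{k}" for k in range(10)]
        matrix = GenotypeMatrix(ids, default_panel(1), calls)
        weights = phen(np.linspace(150, 250, 10), ids)
        model = fit_gap(matrix, weights, combo(["SIZE0001"]), seed=0)
        assert list(model.effects) == [("SIZE0001", 0)]
        gpv = predict(model, matrix)
        assert np.allclose(gpv, gpv.iloc[0])

    def test_gamma_selected_from_grid(self):
        matrix, weights, panel = additive_study(
            n=200, n_markers=5, effect=[10, 10, 10, 10, 10], noise_sd=5.0, seed=1,
        )
        model = fit_gap(matrix, weights, combo([m.marker_id for m in panel]),
                        gamma_grid=(0.2, 1.0), seed=1)
        assert model.gamma in (0.2, 1.0)
        assert model.gamma == 1.0  # strong signal: no shrinkage pays off


class TestPredict:
    def test_zero_effect_model_predicts_mu_plus_beta(self, tiny_matrix):
        model = GapModel(
            mu=200.0, effects={(m.marker_id, c): 0.0 for m in tiny_matrix.markers
                               for c in (0, 1, 2)},
            marker_ids=[m.marker_id for m in tiny_matrix.markers],
            fixed_markers=[], fixed_effects={}, gamma=1.0, alpha=0.0, beta=3.5,
        )
        gpv = predict(model, tiny_matrix)
        assert np.allclose(gpv, 203.5)

    def test_training_repredictions_are_deterministic(self):
        matrix, weights, panel = additive_study(
            n=100, n_markers=5, effect=[10, 0, 5, 0, -5], noise_sd=10.0, seed=2,
        )
        model = fit_gap(matrix, weights, combo([m.marker_id for m in panel]), seed=2)
        assert predict(model, matrix).equals(predict(model, matrix))

    def test_phenotype_shift_shifts_gpv_by_same_constant(self):
        matrix, weights, panel = additive_study(
            n=120, n_markers=5, effect=[10, -5, 8, 0, 4], noise_sd=10.0, seed=4,
        )
        c = 37.0
        ids = combo([m.marker_id for m in panel])
        base = predict(fit_gap(matrix, weights, ids, seed=4), matrix)
        shifted = predict(fit_gap(matrix, weights + c, ids, seed=4), matrix)
        assert np.allclose(shifted - base, c)

    def test_all_missing_individual_flagged(self):
        calls = np.array([[0], [2], [-1]], dtype=np.int8)
        ids = ["a", "b", "c"]
        matrix = GenotypeMatrix(ids, default_panel(1), calls)
        train_calls = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
        train_ids = [f"t{k}" for k in range(10)]
        train = GenotypeMatrix(train_ids, default_panel(1), train_calls)
        model = fit_gap(train, phen([150] * 5 + [250] * 5, train_ids),
                        combo(["SIZE0001"]), seed=0)
        frame = predict(model, matrix, with_flags=True)
        assert bool(frame.loc["c", "all_missing"])
        assert frame.loc["c", "gpv"] == pytest.approx(model.mu + model.beta)


class TestAccuracy:
    def test_identity_and_antisymmetry(self):
        ids = [f"i{k}" for k in range(10)]
        opv = phen(np.linspace(100, 300, 10), ids)
        assert accuracy(opv.rename("gpv"), opv)[0] == pytest.approx(1.0)
        assert accuracy((-opv).rename("gpv"), opv)[0] == pytest.approx(-1.0)

    def test_constant_gpv_reported_as_na(self):
        ids = [f"i{k}" for k in range(10)]
        gpv = phen([200.0] * 10, ids)
        opv = phen(np.linspace(100, 300, 10), ids)
        r, p, n_used = accuracy(gpv, opv)
        assert np.isnan(r) and np.isnan(p)
        assert n_used == 10

    def test_too_few_pairs_is_na(self):
        r, p, n_used = accuracy(phen([1, 2], ["a", "b"]), phen([2, 1], ["a", "b"]))
        assert np.isnan(r) and n_used == 2

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        ids = [f"i{k}" for k in range(50)]
        gpv = phen(rng.normal(200, 20, 50), ids)
        opv = phen(rng.normal(200, 20, 50), ids)
        r0 = accuracy(gpv, opv)[0]
        r1 = accuracy(gpv * 3.2 + 17.0, opv)[0]
        assert r1 == pytest.approx(r0, abs=1e-12)

    @pytest.mark.parametrize(
        "p,stars", [(0.2, ""), (0.04, "*"), (0.004, "**"), (0.0004, "***"),
                    (float("nan"), "")],
    )
    def test_stars(self, p, stars):
        assert significance_stars(p) == stars


class TestHeritabilityRecovery:
    @pytest.mark.parametrize("h2", [0.25, 0.5, 0.9])
    def test_validation_r_approaches_sqrt_h2(self, h2):
        """With additive effects and noise tuned to h², out-of-sample r ≈ √h²."""
        n_markers, a, n = 10, 10.0, 500
        genetic_var = n_markers * 0.5 * a * a  # 1:2:1 dosage variance is 1/2
        noise_sd = float(np.sqrt(genetic_var * (1 - h2) / h2))
        effect = [a] * n_markers
        train_m, train_w, panel = additive_study(n, n_markers, effect, noise_sd,
                                                 seed=100 + int(h2 * 100))
        val_m, val_w, _ = additive_study(n, n_markers, effect, noise_sd,
                                         seed=200 + int(h2 * 100))
        model = fit_gap(train_m, train_w, combo([m.marker_id for m in panel]),
                        seed=0)
        r, _, _ = accuracy(predict(model, val_m), val_w)
        assert r == pytest.approx(np.sqrt(h2), abs=0.1)
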