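"""Genome-assisted prediction (GAP) of fruit weight from a marker combination.

The genomic prediction value of an individual is

    GPV = α·Fx + γ·Σ_{i=1..k} GnE_i + μ + β

where μ is the training-population phenotypic mean, GnE_i the genotype
effect of the i-th non-fixed marker (estimated here as the mean phenotype
of training individuals carrying that genotype, expressed as a deviation
from μ), Fx the summed effect of any declared fixed-effect markers with α
its regression coefficient, γ a shrinkage coefficient chosen by k-fold
cross-validation, and β a residual (intercept) parameter. Prediction
accuracy is the Pearson correlation r between GPV and the observed
phenotypic value (OPV), with a two-sided p-value from the t distribution
on n − 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CALL_MISSING, DataError, GenotypeMatrix
from .screening import MarkerCombination

DEFAULT_GAMMA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


@dataclass
class GapModel:
    mu: float
    effects: dict[tuple[str, int], float]  # (marker_id, call code) -> grams
    marker_ids: list[str]  # non-fixed markers of the combination
    fixed_markers: list[str]
    fixed_effects: dict[tuple[str, int], float]
    gamma: float
    alpha: float
    beta: float

    @property
    def k(self) -> int:
        return len(self.marker_ids)


@dataclass
class PredictionResult:
    gpv: pd.Series
    r: float
    r_p: float
    n_used: int


def _genotype_effects(
    calls: np.ndarray,
    marker_ids: Sequence[str],
    col_index: Mapping[str, int],
    weights: np.ndarray,
    mu: float,
) -> dict[tuple[str, int], float]:
    """Per (marker, genotype) mean phenotype deviation from mu."""
    effects: dict[tuple[str, int], float] = {}
    for mid in marker_ids:
        col = calls[:, col_index[mid]]
        for code in (0, 1, 2):
            mask = col == code
            if mask.any():
                effects[(mid, code)] = float(weights[mask].mean() - mu)
    return effects


def _score_sum(
    calls: np.ndarray,
    marker_ids: Sequence[str],
    col_index: Mapping[str, int],
    effects: Mapping[tuple[str, int], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Summed genotype effects per individual, plus imputed-term tally.

    A missing genotype, or a genotype unseen in training, contributes 0
    and increments the tally.
    """
    n = calls.shape[0]
    total = np.zeros(n)
    imputed = np.zeros(n, dtype=int)
    for mid in marker_ids:
        col = calls[:, col_index[mid]]
        for i, code in enumerate(col):
            eff = effects.get((mid, int(code)))
            if code == CALL_MISSING or eff is None:
                imputed[i] += 1
            else:
                total[i] += eff
    return total, imputed


def fit_gap(
    train_genotypes: GenotypeMatrix,
    train_phenotypes: pd.Series,
    combination: MarkerCombination,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    fixed_markers: Sequence[str] = (),
) -> GapModel:
    """Fit a GAP model on a training population.

    μ is the training phenotypic mean; genotype effects are per-genotype
    mean deviations from μ. γ is picked from ``gamma_grid`` by minimising
    the ``n_folds``-fold cross-validated squared error of the raw score
    μ + γ·ΣGnE, with effects re-estimated inside each training fold
    (folds shuffled under ``seed``). With fixed-effect markers declared, α
    is the least-squares coefficient of the summed fixed effects; otherwise
    α is recorded as 0. β is the least-squares intercept of the final
    score (slope held at 1), i.e. the mean training residual.
    A combination marker that is monomorphic in training simply collapses
    to a single effect entry and contributes a constant.
    """
    if combination.size == 0:
        raise DataError("cannot fit a GAP model on an empty marker combination")
    weights = train_phenotypes.reindex(train_genotypes.individual_ids)
    if weights.isna().any():
        missing = [
            i for i, w in zip(train_genotypes.individual_ids, weights) if pd.isna(w)
        ]
        raise DataError(f"no phenotype for training individual(s): {missing[:5]}")
    y = weights.to_numpy(dtype=float)
    col_index = {m.marker_id: j for j, m in enumerate(train_genotypes.markers)}
    for mid in combination.marker_ids:
        if mid not in col_index:
            raise DataError(f"combination marker {mid} absent from genotype matrix")
    fixed = [mid for mid in fixed_markers if mid in combination.marker_ids]
    free = [mid for mid in combination.marker_ids if mid not in fixed]
    mu = float(y.mean())
    calls = train_genotypes.calls

    effects = _genotype_effects(calls, free, col_index, y, mu)
    fixed_effects = _genotype_effects(calls, fixed, col_index, y, mu)

    gamma = _select_gamma(calls, y, free, col_index, mu, gamma_grid, n_folds, seed)

    free_sum, _ = _score_sum(calls, free, col_index, effects)
    if fixed:
        fixed_sum, _ = _score_sum(calls, fixed, col_index, fixed_effects)
        design = np.column_stack([fixed_sum, np.ones_like(fixed_sum)])
        target = y - (mu + gamma * free_sum)
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        alpha, beta = float(coef[0]), float(coef[1])
    else:
        alpha = 0.0
        beta = float(np.mean(y - (mu + gamma * free_sum)))
    return GapModel(
        mu=mu,
        effects=effects,
        marker_ids=free,
        fixed_markers=fixed,
        fixed_effects=fixed_effects,
        gamma=gamma,
        alpha=alpha,
        beta=beta,
    )


def _select_gamma(
    calls: np.ndarray,
    y: np.ndarray,
    marker_ids: Sequence[str],
    col_index: Mapping[str, int],
    mu: float,
    gamma_grid: Sequence[float],
    n_folds: int,
    seed: int,
) -> float:
    n = y.size
    if not marker_ids or len(gamma_grid) == 1 or n < 2 * n_folds:
        return float(gamma_grid[-1]) if gamma_grid else 1.0
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    sse = np.zeros(len(gamma_grid))
    for held_out in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[held_out] = False
        mu_fold = float(y[train_mask].mean())
        fold_effects = _genotype_effects(
            calls[train_mask], marker_ids, col_index, y[train_mask], mu_fold
        )
        held_sum, _ = _score_sum(calls[held_out], marker_ids, col_index, fold_effects)
        for g, gamma in enumerate(gamma_grid):
            pred = mu_fold + gamma * held_sum
            sse[g] += float(((y[held_out] - pred) ** 2).sum())
    return float(gamma_grid[int(np.argmin(sse))])


def predict(
    model: GapModel,
    genotypes: GenotypeMatrix,
    with_flags: bool = False,
) -> pd.Series | pd.DataFrame:
    """GPVs for every individual in the matrix.

    With ``with_flags=True`` returns a DataFrame with the GPV, the number
    of imputed (missing or unseen-genotype) marker terms per individual,
    and a flag for individuals whose combination genotypes were all
    missing (their GPV degenerates to α·0 + μ + β).
    """
    col_index = {m.marker_id: j for j, m in enumerate(genotypes.markers)}
    for mid in model.marker_ids + model.fixed_markers:
        if mid not in col_index:
            raise DataError(f"model marker {mid} absent from genotype matrix")
    free_sum, imputed = _score_sum(
        genotypes.calls, model.marker_ids, col_index, model.effects
    )
    fixed_sum, fixed_imputed = _score_sum(
        genotypes.calls, model.fixed_markers, col_index, model.fixed_effects
    )
    gpv = model.alpha * fixed_sum + model.gamma * free_sum + model.mu + model.beta
    index = pd.Index(genotypes.individual_ids, name="individual_id")
    series = pd.Series(gpv, index=index, name="gpv")
    if not with_flags:
        return series
    n_terms = len(model.marker_ids) + len(model.fixed_markers)
    total_imputed = imputed + fixed_imputed
    return pd.DataFrame(
        {
            "gpv": series,
            "n_imputed_terms": total_imputed,
            "all_missing": total_imputed == n_terms,
        },
        index=index,
    )


def accuracy(gpv: pd.Series, phenotypes: pd.Series) -> tuple[float, float, int]:
    """Pearson correlation between GPV and OPV over paired individuals.

    Returns (r, two-sided p, n_used). When fewer than 3 pairs remain or
    either series is constant (e.g. an empty-effect model), r is undefined
    and (nan, nan, n_used) is reported — rendered as NA in reports.
    """
    paired = pd.concat([gpv.rename("gpv"), phenotypes.rename("opv")], axis=1).dropna()
    n_used = len(paired)
    if n_used < 3:
        return float("nan"), float("nan"), n_used
    g = paired["gpv"].to_numpy()
    o = paired["opv"].to_numpy()
    if np.ptp(g) == 0 or np.ptp(o) == 0:
        return float("nan"), float("nan"), n_used
    res = stats.pearsonr(g, o)
    return float(res.statistic), float(res.pvalue), n_used


def significance_stars(p: float) -> str:
    """Report stars: * p<0.05, ** p<0.01, *** p<0.001; '' otherwise or NA."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
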