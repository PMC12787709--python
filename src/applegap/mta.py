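"""Marker-trait association testing with assumption-gated test selection.

Individuals are grouped by genotype at each eligible marker. Within-group
normality (Shapiro–Wilk) and variance homogeneity (Levene) decide the test:
ANOVA (≥ 3 groups) or t-test (2 groups) when both assumptions hold,
otherwise Kruskal–Wallis or Mann–Whitney U. Significant ANOVAs are followed
by Tukey HSD, significant Kruskal–Wallis tests by Dunn's test with
Bonferroni adjustment. Raw p-values are corrected across all tested markers
of one population with the Benjamini–Hochberg step-up procedure;
association is declared at raw p < 0.05 and q < 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataError, GenotypeMatrix, MarkerDef

ANOVA = "anova"
T_TEST = "t_test"
KRUSKAL_WALLIS = "kruskal_wallis"
MANN_WHITNEY = "mann_whitney"


class InsufficientGroupsError(ValueError):
    """Fewer than two genotype groups survive the minimum-size filter."""


@dataclass
class GenotypeGroups:
    marker_id: str
    groups: dict[str, np.ndarray]  # genotype label -> phenotype values

    @property
    def group_ns(self) -> dict[str, int]:
        return {label: len(v) for label, v in self.groups.items()}

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class PosthocComparison:
    pair: str  # e.g. "AA-CA"
    adjusted_p: float
    significant: bool


@dataclass
class MTARecord:
    marker_id: str
    test_used: str
    n_groups: int
    statistic: float
    raw_p: float
    q_value: float = float("nan")
    posthoc: list[PosthocComparison] = field(default_factory=list)
    significant: bool = False


def group_by_genotype(
    calls: np.ndarray,
    marker: MarkerDef,
    phenotypes: pd.Series,
    individual_ids: Sequence[str],
    min_group_n: int = 3,
) -> GenotypeGroups:
    """Phenotype values grouped by genotype at one marker.

    Individuals with a missing genotype or missing phenotype are dropped;
    groups smaller than ``min_group_n`` are dropped. Raises
    :class:`InsufficientGroupsError` when fewer than two groups survive
    (such a marker is recorded as untested).
    """
    weights = phenotypes.reindex(individual_ids).to_numpy(dtype=float)
    return _group_from_array(np.asarray(calls), marker, weights, min_group_n)


def _group_from_array(
    calls: np.ndarray,
    marker: MarkerDef,
    weights: np.ndarray,
    min_group_n: int,
) -> GenotypeGroups:
    present = ~np.isnan(weights)
    groups: dict[str, np.ndarray] = {}
    for code in (0, 1, 2):
        mask = (calls == code) & present
        if mask.sum() >= min_group_n:
            groups[marker.genotype_label(code)] = weights[mask]
    if len(groups) < 2:
        raise InsufficientGroupsError(
            f"{marker.marker_id}: {len(groups)} group(s) with n >= {min_group_n}"
        )
    return GenotypeGroups(marker_id=marker.marker_id, groups=groups)


def choose_test(
    groups: GenotypeGroups,
    alpha_assumption: float = 0.05,
    levene_center: str = "mean",
) -> str:
    """Select the association test from the assumption checks.

    Parametric (ANOVA / t-test) only when every group passes Shapiro–Wilk
    and Levene's test passes, both at ``alpha_assumption``; otherwise the
    rank-based analogue. ``levene_center="median"`` gives the
    Brown–Forsythe variant.
    """
    values = list(groups.groups.values())
    normal = all(stats.shapiro(v).pvalue > alpha_assumption for v in values)
    if normal:
        homoscedastic = (
            stats.levene(*values, center=levene_center).pvalue > alpha_assumption
        )
    else:
        homoscedastic = False  # short-circuit: already routed non-parametric
    if normal and homoscedastic:
        return ANOVA if groups.n_groups >= 3 else T_TEST
    return KRUSKAL_WALLIS if groups.n_groups >= 3 else MANN_WHITNEY


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q(i) = min over j >= i of p(j)·m/j after sorting ascending, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def tukey_posthoc(groups: GenotypeGroups, alpha: float = 0.05) -> list[PosthocComparison]:
    """Tukey HSD pairwise comparisons after a significant ANOVA."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = []
    values = []
    for label, v in groups.groups.items():
        labels.extend([label] * len(v))
        values.extend(v.tolist())
    res = pairwise_tukeyhsd(np.asarray(values), np.asarray(labels), alpha=alpha)
    out = []
    for (g1, g2), p_adj, reject in zip(
        itertools.combinations(res.groupsunique, 2), res.pvalues, res.reject
    ):
        out.append(PosthocComparison(pair=f"{g1}-{g2}", adjusted_p=float(p_adj),
                                     significant=bool(reject)))
    return out


def dunn_bonferroni(groups: GenotypeGroups, alpha: float = 0.05) -> list[PosthocComparison]:
    """Dunn's rank-based pairwise test with Bonferroni adjustment.

    Pooled midranks with tie correction; for groups i, j the statistic is
    z = (R̄_i − R̄_j) / sqrt(S²(1/n_i + 1/n_j)) with
    S² = N(N+1)/12 − Σ(t³ − t)/(12(N − 1)), compared to a standard normal;
    two-sided p-values are multiplied by the number of pairs and capped at 1.
    """
    labels = list(groups.groups)
    pooled = np.concatenate([groups.groups[label] for label in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction over pooled values
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    s2 = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for label in labels:
        n_i = groups.groups[label].size
        mean_ranks[label] = ranks[start : start + n_i].mean()
        start += n_i
    pairs = list(itertools.combinations(labels, 2))
    out = []
    for g1, g2 in pairs:
        n1, n2 = groups.groups[g1].size, groups.groups[g2].size
        z = (mean_ranks[g1] - mean_ranks[g2]) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        p_adj = min(1.0, 2.0 * stats.norm.sf(abs(z)) * len(pairs))
        out.append(PosthocComparison(pair=f"{g1}-{g2}", adjusted_p=p_adj,
                                     significant=p_adj < alpha))
    return out


def test_marker(
    groups: GenotypeGroups,
    alpha: float = 0.05,
    alpha_assumption: float = 0.05,
    levene_center: str = "mean",
    posthoc: bool = True,
) -> MTARecord:
    """Run the assumption-gated association test for one marker.

    ``posthoc=False`` skips the pairwise follow-up (used in large
    simulation studies where only the omnibus p-values matter).
    """
    test = choose_test(groups, alpha_assumption, levene_center)
    values = list(groups.groups.values())
    if test == ANOVA:
        res = stats.f_oneway(*values)
    elif test == T_TEST:
        res = stats.ttest_ind(*values)
    elif test == KRUSKAL_WALLIS:
        res = stats.kruskal(*values)
    else:
        res = stats.mannwhitneyu(*values, alternative="two-sided")
    record = MTARecord(
        marker_id=groups.marker_id,
        test_used=test,
        n_groups=groups.n_groups,
        statistic=float(res.statistic),
        raw_p=float(res.pvalue),
    )
    if posthoc and record.raw_p < alpha:
        if test == ANOVA:
            record.posthoc = tukey_posthoc(groups, alpha=alpha)
        elif test == KRUSKAL_WALLIS:
            record.posthoc = dunn_bonferroni(groups, alpha=alpha)
    return record


def run_mta(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    eligible_markers: Sequence[str],
    alpha: float = 0.05,
    q_max: float = 0.05,
    alpha_assumption: float = 0.05,
    min_group_n: int = 3,
    levene_center: str = "mean",
    posthoc: bool = True,
) -> list[MTARecord]:
    """Association records for the eligible markers of one population.

    BH correction is applied across all markers actually tested within the
    population; a marker is flagged significant when raw p < ``alpha`` and
    q < ``q_max``. Markers with fewer than two sufficiently large genotype
    groups are skipped (untested). An empty eligible set yields an empty
    list.
    """
    weights = phenotypes.reindex(matrix.individual_ids).to_numpy(dtype=float)
    records: list[MTARecord] = []
    for marker_id in eligible_markers:
        j = matrix.marker_index(marker_id)
        try:
            groups = _group_from_array(
                matrix.calls[:, j], matrix.markers[j], weights, min_group_n
            )
        except InsufficientGroupsError:
            continue
        records.append(
            test_marker(groups, alpha, alpha_assumption, levene_center, posthoc)
        )
    if records:
        q_values = bh_adjust([r.raw_p for r in records])
        for record, q in zip(records, q_values):
            record.q_value = float(q)
            record.significant = record.raw_p < alpha and q < q_max
    return records
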