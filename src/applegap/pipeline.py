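"""End-to-end per-population workflow.

Chains the stages for one biparental population: phenotype variation
summary, per-marker diversity table, marker-trait association on the
moderate-PIC / HWE-conforming tier, construction of the three marker
combinations (full panel, PIC+HWE subset, MTA subset), and GAP accuracy
for each combination. Because an external training population is not part
of the inputs, accuracy is estimated by within-population k-fold
cross-validation: each individual's GPV comes from a model fitted without
it, and the reported r correlates these out-of-fold GPVs with the
observed weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gap as gap_mod
from . import screening
from .data_io import CrossMetadata, GenotypeMatrix
from .diversity import DiversityRecord, diversity_table
from .gap import accuracy, fit_gap, predict, significance_stars
from .mta import MTARecord, run_mta
from .popstats import VariationSummary, summarize_variation
from .screening import MarkerCombination, build_combinations


@dataclass
class RunConfig:
    """Thresholds and knobs of the screening and testing pipeline."""

    pic_min: float = 0.25
    strict_pic: bool = False
    hwe_alpha: float = 0.001
    mta_alpha: float = 0.05
    q_max: float = 0.05
    assumption_alpha: float = 0.05
    min_group_n: int = 3
    gamma_grid: tuple[float, ...] = gap_mod.DEFAULT_GAMMA_GRID
    n_folds: int = 5
    seed: int = 0
    mta_all_polymorphic: bool = False  # test all polymorphic loci, not just pic_hwe

    def __post_init__(self) -> None:
        for name in ("hwe_alpha", "mta_alpha", "q_max", "assumption_alpha"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")


@dataclass
class AccuracyCell:
    population: str
    combination: str
    size: int
    r: float
    p: float
    stars: str
    n_used: int

    @property
    def display_r(self) -> str:
        return "NA" if np.isnan(self.r) else f"{self.r:.4f}{self.stars}"


@dataclass
class PopulationReport:
    population: str
    variation: VariationSummary
    diversity: list[DiversityRecord]
    mta: list[MTARecord]
    combinations: dict[str, MarkerCombination]
    accuracy: list[AccuracyCell]


def cross_validated_gpv(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    combination: MarkerCombination,
    gamma_grid=gap_mod.DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold GPV per individual under k-fold cross-validation."""
    n = matrix.n_individuals
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    gpv = pd.Series(np.nan, index=pd.Index(matrix.individual_ids, name="individual_id"),
                    name="gpv")
    ids = np.asarray(matrix.individual_ids)
    for held_out in folds:
        if held_out.size == 0:
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[held_out] = False
        train = GenotypeMatrix(
            individual_ids=list(ids[train_mask]),
            markers=matrix.markers,
            calls=matrix.calls[train_mask],
        )
        model = fit_gap(
            train,
            phenotypes,
            combination,
            gamma_grid=gamma_grid,
            n_folds=n_folds,
            seed=seed,
        )
        test = GenotypeMatrix(
            individual_ids=list(ids[held_out]),
            markers=matrix.markers,
            calls=matrix.calls[held_out],
        )
        gpv.loc[ids[held_out]] = predict(model, test).to_numpy()
    return gpv


def evaluate_combinations(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    combinations: dict[str, MarkerCombination],
    config: RunConfig,
) -> list[AccuracyCell]:
    """Cross-validated GAP accuracy for each marker combination.

    An empty combination (no markers survived screening) is reported as NA,
    matching how an accuracy that cannot be computed is displayed.
    """
    cells = []
    for name in (screening.FULL, screening.PIC_HWE, screening.MTA):
        combo = combinations[name]
        if combo.size == 0:
            cells.append(
                AccuracyCell(
                    population=combo.population,
                    combination=name,
                    size=0,
                    r=float("nan"),
                    p=float("nan"),
                    stars="",
                    n_used=0,
                )
            )
            continue
        gpv = cross_validated_gpv(
            matrix,
            phenotypes,
            combo,
            gamma_grid=config.gamma_grid,
            n_folds=config.n_folds,
            seed=config.seed,
        )
        r, p, n_used = accuracy(gpv, phenotypes)
        cells.append(
            AccuracyCell(
                population=combo.population,
                combination=name,
                size=combo.size,
                r=r,
                p=p,
                stars=significance_stars(p),
                n_used=n_used,
            )
        )
    return cells


def analyze_population(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    metadata: CrossMetadata,
    config: RunConfig | None = None,
) -> PopulationReport:
    """Run the full workflow for one population."""
    config = config or RunConfig()
    weights = phenotypes.reindex(matrix.individual_ids).dropna()
    variation = summarize_variation(weights.to_numpy(), metadata)
    div = diversity_table(matrix, hwe_alpha=config.hwe_alpha)
    if config.mta_all_polymorphic:
        eligible = [rec.marker_id for rec in div if rec.pic > 0]
    else:
        pic_ok = (lambda v: v > config.pic_min) if config.strict_pic else (
            lambda v: v >= config.pic_min
        )
        eligible = [
            rec.marker_id
            for rec in div
            if pic_ok(rec.pic) and rec.hwe_p > config.hwe_alpha
        ]
    mta_records = run_mta(
        matrix,
        phenotypes,
        eligible,
        alpha=config.mta_alpha,
        q_max=config.q_max,
        alpha_assumption=config.assumption_alpha,
        min_group_n=config.min_group_n,
    )
    combos = build_combinations(
        div,
        mta_records,
        matrix.markers,
        population=metadata.cross_name,
        pic_min=config.pic_min,
        hwe_alpha=config.hwe_alpha,
        strict_pic=config.strict_pic,
    )
    cells = evaluate_combinations(matrix, phenotypes, combos, config)
    return PopulationReport(
        population=metadata.cross_name,
        variation=variation,
        diversity=div,
        mta=mta_records,
        combinations=combos,
        accuracy=cells,
    )


def accuracy_matrix(reports: list[PopulationReport]) -> pd.DataFrame:
    """Study-level accuracy table: population x combination -> size, r, stars."""
    rows = []
    for report in reports:
        for cell in report.accuracy:
            rows.append(
                {
                    "population": cell.population,
                    "combination": cell.combination,
                    "n_markers": cell.size,
                    "r": round(cell.r, 4) if not np.isnan(cell.r) else float("nan"),
                    "p": round(cell.p, 6) if not np.isnan(cell.p) else float("nan"),
                    "stars": cell.stars,
                    "display": cell.display_r,
                }
            )
    return pd.DataFrame(rows)
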