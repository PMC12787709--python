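"""Synthetic six-population F1 study generator.

Emulates the structure of a multi-family apple fruit-weight validation
study: six biparental F1 populations (80, 75, 137, 113, 80 and 88
offspring; 573 in total) genotyped on a panel of 70 biallelic SNP markers
spread over the 17 apple chromosomes. Offspring genotypes follow Mendelian
segregation from the parental genotypes independently across markers (no
linkage map is imposed), so a marker segregates 1:2:1, 1:1 or not at all
depending on the parents — giving the population-specific monomorphism
seen in real panels. Phenotypes are additive:

    weight (g) = base_mean + Σ_m dosage_m · effect_m + Normal(0, noise_sd)

clipped below at 1 g, where dosage is the alt-allele count. Defaults plant
10 causal markers with effects of 7–15 g on a 180 g baseline and a 25 g
environmental SD, i.e. a broad-sense heritability near 0.45 — a realistic
regime for fruit weight in segregating apple families, whose phenotypic
CVs run around 20–45%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    CALL_MISSING,
    CrossMetadata,
    DataError,
    GenotypeMatrix,
    MarkerDef,
    write_genotypes,
    write_panel,
    write_phenotypes,
)

STUDY_POPULATIONS = (  # (label, n_offspring), 573 individuals in total
    ("RJxRY", 80),
    ("RJxY", 75),
    ("YxH", 137),
    ("RJxH", 113),
    ("RXxA", 80),
    ("QxRX", 88),
)

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("A", "T"), ("C", "G"))

DEFAULT_N_MARKERS = 70
DEFAULT_BASE_MEAN = 180.0
DEFAULT_NOISE_SD = 25.0
DEFAULT_MISSING_RATE = 0.02
# every 7th marker is causal; grams per alt allele
DEFAULT_EFFECTS = (12.0, -10.0, 8.0, 15.0, -9.0, 7.0, 11.0, -8.0, 10.0, 9.0)


@dataclass
class PopulationSpec:
    name: str
    n_offspring: int
    female_genotypes: np.ndarray  # call codes 0/1/2, one per panel marker
    male_genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise DataError("n_offspring must be >= 1")


@dataclass
class SimConfig:
    populations: list[PopulationSpec]
    panel: list[MarkerDef]
    effect_map: dict[str, float]
    base_mean: float = DEFAULT_BASE_MEAN
    noise_sd: float = DEFAULT_NOISE_SD
    missing_rate: float = DEFAULT_MISSING_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must lie in [0, 1)")
        panel_ids = {m.marker_id for m in self.panel}
        stray = set(self.effect_map) - panel_ids
        if stray:
            raise DataError(f"effect markers not on panel: {sorted(stray)}")
        for spec in self.populations:
            for parent in (spec.female_genotypes, spec.male_genotypes):
                arr = np.asarray(parent)
                if arr.shape != (len(self.panel),):
                    raise DataError(f"{spec.name}: parent genotype length mismatch")
                if not np.isin(arr, (0, 1, 2)).all():
                    raise DataError(f"{spec.name}: parent genotypes must be 0/1/2")


@dataclass
class StudyPopulation:
    spec: PopulationSpec
    genotypes: GenotypeMatrix
    phenotypes: pd.Series
    metadata: CrossMetadata


def default_panel(n_markers: int = DEFAULT_N_MARKERS) -> list[MarkerDef]:
    """A deterministic panel of biallelic SNPs across the 17 apple chromosomes."""
    panel = []
    for i in range(n_markers):
        chrom = f"Chr{(i % 17) + 1:02d}"
        ref, alt = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        panel.append(
            MarkerDef(
                marker_id=f"SIZE{i + 1:04d}",
                chromosome=chrom,
                position=1_000_000 + 731_017 * (i // 17 + 1) + 13 * i,
                ref_allele=ref,
                alt_allele=alt,
            )
        )
    return panel


def default_effect_map(panel: list[MarkerDef]) -> dict[str, float]:
    """Ten causal markers (every 7th panel position) with fixed additive effects."""
    causal = [panel[7 * i].marker_id for i in range(len(DEFAULT_EFFECTS))]
    return dict(zip(causal, DEFAULT_EFFECTS))


def _draw_parent(
    rng: np.random.Generator,
    major_code: np.ndarray,
    fixed: np.ndarray,
    p_het: float,
    p_minor: float,
) -> np.ndarray:
    """One parent: homozygous for the panel-wide major allele with excess
    probability, heterozygous or homozygous-minor otherwise; markers flagged
    ``fixed`` are homozygous-major in every parent."""
    n = major_code.size
    minor_code = (2 - major_code).astype(np.int8)
    draw = rng.random(n)
    codes = major_code.copy()
    codes[draw < p_het + p_minor] = np.int8(1)
    codes[draw < p_minor] = minor_code[draw < p_minor]
    codes[fixed] = major_code[fixed]
    return codes.astype(np.int8)


def default_config(seed: int = 0) -> SimConfig:
    """The default six-population study configuration.

    Parental genotypes are drawn per population (deterministically from
    ``seed``). About 30% of markers are fixed for their major allele in
    every parent — emulating panel markers ascertained in unrelated
    mapping populations that do not segregate in these families — and the
    remaining markers carry a strong homozygote excess in the five
    cultivar × cultivar crosses, with a more heterozygous wild × cultivar
    cross (QxRX). Each cross is therefore monomorphic at a
    population-specific subset of the panel, and roughly 12–27 markers per
    population are moderately polymorphic, as in real multi-family panels.
    """
    panel = default_panel()
    parent_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n_markers = len(panel)
    major_is_ref = parent_rng.random(n_markers) < 0.5
    major_code = np.where(major_is_ref, 0, 2).astype(np.int8)
    fixed = parent_rng.random(n_markers) < 0.30
    populations = []
    for name, n in STUDY_POPULATIONS:
        p_het, p_minor = (0.22, 0.12) if name == "QxRX" else (0.10, 0.05)
        populations.append(
            PopulationSpec(
                name=name,
                n_offspring=n,
                female_genotypes=_draw_parent(parent_rng, major_code, fixed, p_het, p_minor),
                male_genotypes=_draw_parent(parent_rng, major_code, fixed, p_het, p_minor),
            )
        )
    return SimConfig(
        populations=populations,
        panel=panel,
        effect_map=default_effect_map(panel),
        seed=seed,
    )


def simulate_cross(
    female: np.ndarray,
    male: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    panel: list[MarkerDef] | None = None,
    name_prefix: str = "ind",
) -> GenotypeMatrix:
    """Mendelian F1 offspring of two genotyped parents.

    Each offspring receives one uniformly random allele from each parent,
    independently across markers (unlinked loci). Deterministic under a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    female = np.asarray(female, dtype=float)
    male = np.asarray(male, dtype=float)
    if female.shape != male.shape:
        raise DataError("parents must be genotyped on the same panel")
    n_markers = female.size
    # a parent with code c transmits the alt allele with probability c/2
    gam_f = rng.random((n, n_markers)) < female / 2.0
    gam_m = rng.random((n, n_markers)) < male / 2.0
    calls = (gam_f.astype(np.int8) + gam_m.astype(np.int8))
    if panel is None:
        panel = default_panel(n_markers)
    if len(panel) != n_markers:
        raise DataError("panel length does not match parent genotype length")
    ids = [f"{name_prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(individual_ids=ids, markers=panel, calls=calls)


def genetic_values(matrix: GenotypeMatrix, config: SimConfig) -> np.ndarray:
    """Additive genetic value (deviation excluded) per individual, in grams."""
    col_index = {m.marker_id: j for j, m in enumerate(matrix.markers)}
    value = np.full(matrix.n_individuals, config.base_mean)
    for marker_id, effect in config.effect_map.items():
        dosage = matrix.calls[:, col_index[marker_id]].astype(float)
        dosage[dosage == CALL_MISSING] = 0.0
        value += dosage * effect
    return value


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    config: SimConfig,
    seed: int | np.random.Generator,
) -> pd.Series:
    """Fruit weights: base mean + additive marker effects + Gaussian noise.

    Weights are clipped below at 1 g (a fruit cannot weigh nothing).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    value = genetic_values(matrix, config)
    weight = value + rng.normal(0.0, config.noise_sd, size=matrix.n_individuals)
    weight = np.clip(weight, 1.0, None)
    return pd.Series(
        weight,
        index=pd.Index(matrix.individual_ids, name="individual_id"),
        name="fruit_weight",
    )


def _parent_mean(codes: np.ndarray, config: SimConfig) -> float:
    """A parent's additive genetic value, used as its phenotype mean."""
    col_index = {m.marker_id: j for j, m in enumerate(config.panel)}
    value = config.base_mean
    for marker_id, effect in config.effect_map.items():
        value += float(codes[col_index[marker_id]]) * effect
    return max(value, 1.0)


def simulate_population(
    spec: PopulationSpec, config: SimConfig, seed_sequence: np.random.SeedSequence
) -> StudyPopulation:
    rng = np.random.default_rng(seed_sequence)
    matrix = simulate_cross(
        spec.female_genotypes,
        spec.male_genotypes,
        spec.n_offspring,
        rng,
        panel=config.panel,
        name_prefix=f"{spec.name}_",
    )
    phenotypes = simulate_phenotypes(matrix, config, rng)
    if config.missing_rate > 0:
        mask = rng.random(matrix.calls.shape) < config.missing_rate
        matrix.calls[mask] = CALL_MISSING
    meta = CrossMetadata(
        cross_name=spec.name,
        female_parent_mean=_parent_mean(spec.female_genotypes, config),
        male_parent_mean=_parent_mean(spec.male_genotypes, config),
        n_individuals=spec.n_offspring,
    )
    return StudyPopulation(spec=spec, genotypes=matrix, phenotypes=phenotypes, metadata=meta)


def make_study(
    config: SimConfig, outdir: str | Path | None = None
) -> dict[str, StudyPopulation]:
    """Simulate every population of the study; optionally write TSVs.

    When ``outdir`` is given, writes ``panel.tsv``, ``metadata.tsv`` and,
    per population, ``<name>_genotypes.tsv`` and ``<name>_phenotypes.tsv``.
    Identical configs (including seed) produce byte-identical files.
    """
    children = np.random.SeedSequence(config.seed).spawn(len(config.populations))
    study = {
        spec.name: simulate_population(spec, config, child)
        for spec, child in zip(config.populations, children)
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_panel(config.panel, outdir / "panel.tsv")
        meta_rows = []
        for name, pop in study.items():
            write_genotypes(pop.genotypes, outdir / f"{name}_genotypes.tsv")
            write_phenotypes(pop.phenotypes, outdir / f"{name}_phenotypes.tsv")
            meta_rows.append(
                {
                    "cross_name": name,
                    "female_parent_mean": round(pop.metadata.female_parent_mean, 4),
                    "male_parent_mean": round(pop.metadata.male_parent_mean, 4),
                    "n_individuals": pop.metadata.n_individuals,
                }
            )
        pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return study
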