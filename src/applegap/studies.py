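"""Reference analyses: published-cross arithmetic and simulation studies.

Three self-contained study drivers built on the library:

* variation arithmetic for the six published apple crosses, recomputed
  from their printed parental and F1 means;
* a global-null simulation measuring the raw type-I error of the
  marker-trait association stage and the false-positive count surviving
  FDR control;
* a screening-benefit simulation measuring validation accuracy of the
  MTA-screened marker combination against the full panel when only a
  subset of markers carries real effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CrossMetadata
from .diversity import diversity_table
from .gap import accuracy, fit_gap, predict
from .mta import run_mta
from .popstats import summarize_variation
from .screening import FULL, MTA, PIC_HWE, build_combinations
from .simdata import SimConfig, default_panel, simulate_cross, simulate_phenotypes

# Published per-cross summaries (parental means, F1 mean, all in grams) for
# six apple F1 populations; inputs to the variation arithmetic. The YxH cross
# is marked arithmetically inconsistent: its published mid-parent value does
# not equal the mean of its published parent means, so recomputed Ta/H cannot
# be compared against the published ones.
PUBLISHED_CROSSES = (
    # label, female mean, male mean, F1 mean, n, consistent
    ("RJxRY", 126.76, 265.34, 165.04, 80, True),
    ("RJxY", 126.76, 215.80, 158.82, 75, True),
    ("YxH", 215.80, 319.21, 229.18, 137, False),
    ("RJxH", 126.76, 319.21, 183.97, 113, True),
    ("RXxA", 271.16, 38.00, 223.76, 80, True),
    ("QxRX", 30.75, 271.16, 39.72, 88, True),
)


@dataclass
class CrossArithmetic:
    label: str
    mid_parent: float
    ta_percent: float
    heterosis_percent: float
    consistent: bool


def published_cross_arithmetic() -> list[CrossArithmetic]:
    """Mid-parent, Ta and H recomputed from the published cross means.

    Each cross's printed F1 mean is realised as a symmetric sample with
    that exact mean and pushed through the variation summary, so the
    returned numbers are produced by the same code path as any real
    analysis.
    """
    out = []
    for label, female, male, f1_mean, n, consistent in PUBLISHED_CROSSES:
        offsets = np.linspace(-1.0, 1.0, n)
        weights = f1_mean + offsets - offsets.mean()
        summary = summarize_variation(
            weights, CrossMetadata(label, female, male, n)
        )
        out.append(
            CrossArithmetic(
                label=label,
                mid_parent=summary.mid_parent,
                ta_percent=summary.ta_percent,
                heterosis_percent=summary.heterosis_percent,
                consistent=consistent,
            )
        )
    return out


@dataclass
class NullStudyResult:
    raw_rate: float          # fraction of tested markers with raw p < alpha
    mean_fdr_hits: float     # mean FDR-significant markers per replicate
    n_tests: int
    n_replicates: int


def null_type1_study(
    n_replicates: int = 2000,
    n_individuals: int = 100,
    n_markers: int = 70,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullStudyResult:
    """Type-I error of the MTA stage under a global null.

    Each replicate simulates a fully segregating F1 cross (both parents
    heterozygous at every marker) and pure-noise phenotypes, runs the
    assumption-gated association tests across all markers, and counts raw
    p < ``alpha`` along with FDR-significant calls.
    """
    panel = default_panel(n_markers)
    het = np.ones(n_markers, dtype=np.int8)
    rng = np.random.default_rng(seed)
    raw_hits = 0
    n_tests = 0
    fdr_hits = 0
    marker_ids = [m.marker_id for m in panel]
    for _ in range(n_replicates):
        matrix = simulate_cross(het, het, n_individuals, rng, panel=panel)
        weights = pd.Series(
            rng.normal(180.0, 25.0, n_individuals), index=matrix.individual_ids
        )
        records = run_mta(matrix, weights, marker_ids, alpha=alpha, posthoc=False)
        n_tests += len(records)
        raw_hits += sum(r.raw_p < alpha for r in records)
        fdr_hits += sum(r.significant for r in records)
    return NullStudyResult(
        raw_rate=raw_hits / n_tests,
        mean_fdr_hits=fdr_hits / n_replicates,
        n_tests=n_tests,
        n_replicates=n_replicates,
    )


@dataclass
class ScreeningBenefitResult:
    mean_r: dict[str, float]           # combination name -> mean validation r
    mean_combination_size: dict[str, float]
    n_replicates: int


def screening_benefit_study(
    n_replicates: int = 50,
    h2: float = 0.9,
    n_train: int = 500,
    n_val: int = 500,
    n_markers: int = 70,
    n_causal: int = 10,
    effect: float = 10.0,
    seed: int = 0,
) -> ScreeningBenefitResult:
    """Validation accuracy of screened vs full marker combinations.

    Each replicate simulates a training and a validation cross sharing
    the same parents, with ``n_causal`` causal markers of additive effect
    ``effect`` g per alt allele and environmental noise sized so that the
    broad-sense heritability is ``h2``. Causal markers and half of the
    non-causal markers segregate 1:2:1 (both parents heterozygous); the
    other half of the non-causal markers segregate 1:1 backcross-style,
    which deviates sharply from Hardy–Weinberg proportions at these sample
    sizes and is therefore removed by the PIC+HWE screen — giving the
    three combinations genuinely different content, as in real panels.
    The screening pipeline (diversity, MTA, combination building) runs on
    the training population only; GAP models are fitted on training and
    evaluated on validation.
    """
    panel = default_panel(n_markers)
    female = np.ones(n_markers, dtype=np.int8)
    male = np.ones(n_markers, dtype=np.int8)
    n_noise = n_markers - n_causal
    # backcross-type noise markers: female parent homozygous reference
    female[n_causal + n_noise // 2 :] = 0
    causal = [panel[i].marker_id for i in range(n_causal)]
    genetic_var = n_causal * 0.5 * effect * effect
    noise_sd = float(np.sqrt(genetic_var * (1.0 - h2) / h2))
    config = SimConfig(
        populations=[], panel=panel,
        effect_map={mid: effect for mid in causal},
        base_mean=200.0, noise_sd=noise_sd, missing_rate=0.0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    sums = {name: 0.0 for name in (FULL, PIC_HWE, MTA)}
    sizes = {name: 0.0 for name in (FULL, PIC_HWE, MTA)}
    used = {name: 0 for name in (FULL, PIC_HWE, MTA)}
    for _ in range(n_replicates):
        train = simulate_cross(female, male, n_train, rng, panel=panel)
        train_w = simulate_phenotypes(train, config, rng)
        val = simulate_cross(female, male, n_val, rng, panel=panel)
        val_w = simulate_phenotypes(val, config, rng)
        div = diversity_table(train)
        eligible = [r.marker_id for r in div if r.pic >= 0.25 and r.hwe_p > 0.001]
        records = run_mta(train, train_w, eligible, posthoc=False)
        combos = build_combinations(div, records, panel, population="sim")
        fit_seed = int(rng.integers(2**31))
        for name, combo in combos.items():
            sizes[name] += combo.size
            if combo.size == 0:
                continue
            model = fit_gap(train, train_w, combo, seed=fit_seed)
            r, _, _ = accuracy(predict(model, val), val_w)
            if not np.isnan(r):
                sums[name] += r
                used[name] += 1
    return ScreeningBenefitResult(
        mean_r={name: (sums[name] / used[name] if used[name] else float("nan"))
                for name in sums},
        mean_combination_size={name: sizes[name] / n_replicates for name in sizes},
        n_replicates=n_replicates,
    )


@dataclass
class MendelianConformance:
    p_1_2_1: float
    p_1_1: float
    n: int


def mendelian_conformance(n: int = 10_000, seed: int = 0) -> MendelianConformance:
    """Chi-square conformance of simulated segregation to Mendelian ratios."""
    panel = default_panel(1)
    matrix = simulate_cross(np.array([1]), np.array([1]), n, seed, panel=panel)
    counts = [(matrix.calls[:, 0] == c).sum() for c in (0, 1, 2)]
    p_121 = float(stats.chisquare(counts, f_exp=[n / 4, n / 2, n / 4]).pvalue)
    matrix = simulate_cross(np.array([0]), np.array([1]), n, seed + 1, panel=panel)
    counts = [(matrix.calls[:, 0] == c).sum() for c in (0, 1)]
    p_11 = float(stats.chisquare(counts, f_exp=[n / 2, n / 2]).pvalue)
    return MendelianConformance(p_1_2_1=p_121, p_1_1=p_11, n=n)
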