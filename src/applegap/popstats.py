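"""Per-population phenotype variation statistics for biparental F1 crosses.

For a population of n F1 fruit-weight values with mean X̄ and sample
standard deviation S, and parental means defining the mid-parent value MP:

    CV (%) = S / X̄ × 100            coefficient of variation
    Ta (%) = X̄ / MP × 100           genetic transmitting ability
    H  (%) = (X̄ − MP) / MP × 100    heterosis rate (so Ta − H = 100)
    RH (%) = hp / n × 100            share strictly above the high parent
    RL (%) = lp / n × 100            share strictly below the low parent

Normality of the F1 distribution is assessed with a one-sample
Kolmogorov–Smirnov test against a normal with sample-estimated mean and SD
(the classic SPSS-style one-sample KS); a Lilliefors-corrected p-value is
available because the plain KS with estimated parameters is
anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import CrossMetadata, DataError


@dataclass
class VariationSummary:
    cross_name: str
    n: int
    mean: float
    sd: float
    cv_percent: float
    range_min: float
    range_max: float
    mid_parent: float
    ta_percent: float
    heterosis_percent: float
    rh_percent: float
    rl_percent: float
    ks_statistic: float
    ks_p: float


def mid_parent(female_mean: float, male_mean: float) -> float:
    """Mid-parent value: the arithmetic mean of the two parental means."""
    if female_mean <= 0 or male_mean <= 0:
        raise DataError("parent means must be positive")
    return (female_mean + male_mean) / 2.0


def ks_normality(weights, lilliefors: bool = False) -> tuple[float, float]:
    """One-sample KS test of normality with parameters estimated from the data.

    Returns (statistic, two-sided p). ``lilliefors=True`` switches to the
    Lilliefors-corrected p-value (statsmodels), which accounts for the
    parameter estimation.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 5:
        raise DataError("KS normality test needs at least 5 observations")
    mean = w.mean()
    sd = w.std(ddof=1)
    if sd == 0:
        raise DataError("KS normality test undefined for a constant sample")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(w, dist="norm", pvalmethod="table")
        return float(stat), float(p)
    stat, p = stats.kstest(w, "norm", args=(mean, sd))
    return float(stat), float(p)


def summarize_variation(weights, meta: CrossMetadata) -> VariationSummary:
    """Variation summary of one F1 population against its parental means.

    RH counts individuals strictly above the higher parental mean, RL
    strictly below the lower one; ties count as neither. SD uses the n−1
    denominator.
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    if n < 2:
        raise DataError("variation summary needs at least 2 individuals")
    mean = float(w.mean())
    if mean == 0:
        raise DataError("zero phenotype mean")
    sd = float(w.std(ddof=1))
    mp = mid_parent(meta.female_parent_mean, meta.male_parent_mean)
    high = max(meta.female_parent_mean, meta.male_parent_mean)
    low = min(meta.female_parent_mean, meta.male_parent_mean)
    hp = int((w > high).sum())
    lp = int((w < low).sum())
    ks_stat, ks_p = ks_normality(w) if n >= 5 and sd > 0 else (float("nan"), float("nan"))
    return VariationSummary(
        cross_name=meta.cross_name,
        n=n,
        mean=mean,
        sd=sd,
        cv_percent=sd / mean * 100.0,
        range_min=float(w.min()),
        range_max=float(w.max()),
        mid_parent=mp,
        ta_percent=mean / mp * 100.0,
        heterosis_percent=(mean - mp) / mp * 100.0,
        rh_percent=hp / n * 100.0,
        rl_percent=lp / n * 100.0,
        ks_statistic=ks_stat,
        ks_p=ks_p,
    )
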