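"""Per-marker genetic diversity statistics and Hardy–Weinberg testing.

For a biallelic SNP with allele frequencies p (reference) and q = 1 − p
estimated from the non-missing genotype calls:

    PIC = 1 − (p² + q²) − 2 p² q²      polymorphism information content
    Ne  = 1 / (p² + q²)                effective number of alleles
    Ho  = n_het / n_called             observed heterozygosity
    He  = 1 − (p² + q²)                expected heterozygosity

Hardy–Weinberg conformance is tested with the plain chi-square
χ² = Σ (O − E)² / E over the three genotype classes against expected
counts N·(p², 2pq, q²), df = 1 (no continuity correction by default; a
Yates-corrected variant is available). Markers are classed by PIC:
low (< 0.25), moderate (0.25 ≤ PIC < 0.5), high (≥ 0.5 — unreachable for
a biallelic locus, whose maximum is 0.375 at p = 0.5, but kept for
generality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import (
    CALL_HET,
    CALL_HOMALT,
    CALL_HOMREF,
    DataError,
    GenotypeMatrix,
)


class MonomorphicMarkerError(ValueError):
    """HWE is undefined for a monomorphic marker (expected het count is 0)."""


@dataclass(frozen=True)
class AlleleFrequencies:
    p_ref: float
    p_alt: float
    n_called: int
    genotype_counts: tuple[int, int, int]  # (hom-ref, het, hom-alt)

    def __post_init__(self) -> None:
        if abs(self.p_ref + self.p_alt - 1.0) > 1e-12:
            raise DataError("allele frequencies must sum to 1")
        if sum(self.genotype_counts) != self.n_called:
            raise DataError("genotype counts do not sum to n_called")


@dataclass
class DiversityRecord:
    marker_id: str
    p_ref: float
    n_called: int
    n_homref: int
    n_het: int
    n_homalt: int
    pic: float
    ne: float
    ho: float
    he: float
    hwe_chi2: float  # NaN when HWE undefined (monomorphic)
    hwe_p: float
    polymorphism_class: str
    hwe_conforming: bool


def allele_frequencies(calls: np.ndarray) -> AlleleFrequencies:
    """Allele frequencies from one marker's calls; missing calls excluded."""
    calls = np.asarray(calls)
    n_homref = int((calls == CALL_HOMREF).sum())
    n_het = int((calls == CALL_HET).sum())
    n_homalt = int((calls == CALL_HOMALT).sum())
    n_called = n_homref + n_het + n_homalt
    if n_called == 0:
        raise DataError("all calls missing for this marker")
    p_ref = (2 * n_homref + n_het) / (2 * n_called)
    return AlleleFrequencies(
        p_ref=p_ref,
        p_alt=1.0 - p_ref,
        n_called=n_called,
        genotype_counts=(n_homref, n_het, n_homalt),
    )


def pic(freqs: AlleleFrequencies | float) -> float:
    """Polymorphism information content, 1 − Σp² − ΣΣ 2p²q² over allele pairs."""
    p = freqs.p_ref if isinstance(freqs, AlleleFrequencies) else float(freqs)
    q = 1.0 - p
    # clamp: analytically >= 0, but cancellation near p in {0, 1} can give -eps
    return max(1.0 - (p * p + q * q) - 2.0 * p * p * q * q, 0.0)


def ne_ho_he(freqs: AlleleFrequencies) -> tuple[float, float, float]:
    """Effective allele number, observed and expected heterozygosity."""
    p, q = freqs.p_ref, freqs.p_alt
    sum_p2 = p * p + q * q
    ne = 1.0 / sum_p2
    ho = freqs.genotype_counts[1] / freqs.n_called
    he = 1.0 - sum_p2
    return ne, ho, he


def hwe_test(
    counts: tuple[int, int, int], yates: bool = False
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of genotype counts to Hardy–Weinberg.

    ``counts`` are (hom-ref, het, hom-alt); the allele frequency is
    estimated from the same counts. Returns (chi2, p) with df = 1.
    Raises :class:`MonomorphicMarkerError` for a monomorphic marker.
    """
    n_homref, n_het, n_homalt = (int(c) for c in counts)
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise DataError("no called genotypes")
    p = (2 * n_homref + n_het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise MonomorphicMarkerError("HWE chi-square undefined for a monomorphic marker")
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([n_homref, n_het, n_homalt], dtype=float)
    dev = np.abs(observed - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return chi2, p_value


def classify_polymorphism(pic_value: float) -> str:
    """PIC class: low (< 0.25), moderate (0.25 ≤ PIC < 0.5), high (≥ 0.5)."""
    if not 0.0 <= pic_value <= 1.0:
        raise DataError(f"PIC must lie in [0, 1], got {pic_value}")
    if pic_value < 0.25:
        return "low"
    if pic_value < 0.5:
        return "moderate"
    return "high"


def diversity_table(
    matrix: GenotypeMatrix, hwe_alpha: float = 0.001, yates: bool = False
) -> list[DiversityRecord]:
    """One diversity record per panel marker.

    A marker conforms to HWE when its chi-square p-value exceeds
    ``hwe_alpha`` (severe-deviation screen, default 0.001). Monomorphic
    markers get PIC = 0, class low, and NaN HWE fields with
    ``hwe_conforming=False`` so that "no information" is distinct from
    "conforming".
    """
    records = []
    for j, marker in enumerate(matrix.markers):
        freqs = allele_frequencies(matrix.calls[:, j])
        pic_value = pic(freqs)
        ne, ho, he = ne_ho_he(freqs)
        try:
            chi2, p_value = hwe_test(freqs.genotype_counts, yates=yates)
            conforming = p_value > hwe_alpha
        except MonomorphicMarkerError:
            chi2, p_value = float("nan"), float("nan")
            conforming = False
        records.append(
            DiversityRecord(
                marker_id=marker.marker_id,
                p_ref=freqs.p_ref,
                n_called=freqs.n_called,
                n_homref=freqs.genotype_counts[0],
                n_het=freqs.genotype_counts[1],
                n_homalt=freqs.genotype_counts[2],
                pic=pic_value,
                ne=ne,
                ho=ho,
                he=he,
                hwe_chi2=chi2,
                hwe_p=p_value,
                polymorphism_class=classify_polymorphism(pic_value),
                hwe_conforming=conforming,
            )
        )
    return records
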