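"""Tabular input/output and the canonical in-memory data model.

The pipeline works on small biparental F1 populations genotyped on a fixed
panel of biallelic SNP markers. Genotypes are held as an individuals x
markers matrix of integer call codes (0 = homozygous reference, 1 =
heterozygous, 2 = homozygous alternate, -1 = missing); on disk they are
two-letter allele strings ("AA", "CA", "CC") in TSV, or optionally the
numeric dosage dialect (0/1/2). Phenotypes are fruit weights in grams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CALL_HOMREF = 0
CALL_HET = 1
CALL_HOMALT = 2
CALL_MISSING = -1

DEFAULT_MISSING_CODE = "NA"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class MarkerDef:
    """One biallelic SNP marker on the panel.

    Positions are 1-based physical coordinates; alleles are single IUPAC
    bases as genotyped (no strand handling).
    """

    marker_id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DataError(f"{self.marker_id}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"{self.marker_id}: ref and alt alleles are equal")

    def genotype_label(self, code: int) -> str:
        """Two-letter genotype string for a call code ('CA' style for hets)."""
        if code == CALL_HOMREF:
            return self.ref_allele * 2
        if code == CALL_HET:
            return self.ref_allele + self.alt_allele
        if code == CALL_HOMALT:
            return self.alt_allele * 2
        raise ValueError(f"no genotype label for call code {code}")

    def parse_cell(self, cell: str) -> int:
        """Decode a two-letter allele cell; heterozygotes are order-insensitive."""
        if len(cell) != 2:
            raise DataError(f"{self.marker_id}: malformed genotype cell {cell!r}")
        a, b = cell[0], cell[1]
        valid = {self.ref_allele, self.alt_allele}
        if a not in valid or b not in valid:
            raise DataError(
                f"{self.marker_id}: allele in cell {cell!r} not in declared pair "
                f"{self.ref_allele}/{self.alt_allele}"
            )
        if a != b:
            return CALL_HET
        return CALL_HOMREF if a == self.ref_allele else CALL_HOMALT


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of biallelic SNP calls."""

    individual_ids: list[str]
    markers: list[MarkerDef]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.markers)):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise DataError("duplicate individual ids")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate marker ids in panel")
        bad = ~np.isin(self.calls, (CALL_MISSING, CALL_HOMREF, CALL_HET, CALL_HOMALT))
        if bad.any():
            raise DataError("call codes must be -1, 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(marker_id)

    def marker(self, marker_id: str) -> MarkerDef:
        return self.markers[self.marker_index(marker_id)]

    def calls_for(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.marker_index(mid) for mid in marker_ids]
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            markers=[self.markers[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )

    def to_frame(self, missing_code: str = DEFAULT_MISSING_CODE) -> pd.DataFrame:
        """Allele-string DataFrame (individuals as index, marker ids as columns)."""
        cols = {}
        for j, m in enumerate(self.markers):
            col = np.empty(self.n_individuals, dtype=object)
            for i, code in enumerate(self.calls[:, j]):
                col[i] = missing_code if code == CALL_MISSING else m.genotype_label(code)
            cols[m.marker_id] = col
        frame = pd.DataFrame(cols, index=pd.Index(self.individual_ids, name="individual_id"))
        return frame


@dataclass(frozen=True)
class CrossMetadata:
    """One biparental cross: population label and parental phenotype means."""

    cross_name: str
    female_parent_mean: float
    male_parent_mean: float
    n_individuals: int

    def __post_init__(self) -> None:
        if self.female_parent_mean <= 0 or self.male_parent_mean <= 0:
            raise DataError("parent means must be positive")
        if self.n_individuals < 1:
            raise DataError("n_individuals must be >= 1")


# ---------------------------------------------------------------------------
# readers


def read_panel(path: str | Path) -> list[MarkerDef]:
    """Read a marker panel TSV (marker_id, chromosome, position, ref, alt)."""
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"marker_id", "chromosome", "position", "ref_allele", "alt_allele"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"panel file missing columns: {sorted(missing)}")
    panel = [
        MarkerDef(
            marker_id=str(row.marker_id),
            chromosome=str(row.chromosome),
            position=int(row.position),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
        )
        for row in frame.itertuples()
    ]
    ids = [m.marker_id for m in panel]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate marker_id in panel file")
    return panel


def read_genotypes(
    path: str | Path,
    panel: Sequence[MarkerDef],
    missing_code: str = DEFAULT_MISSING_CODE,
    numeric: bool = False,
) -> GenotypeMatrix:
    """Read a genotype TSV (first column individual id, one column per marker).

    Cells are two-letter allele pairs ("CA" and "AC" are the same
    heterozygote) or, with ``numeric=True``, alt-allele dosages 0/1/2.
    Cells equal to ``missing_code`` become missing calls. Alleles outside a
    marker's declared pair, duplicate individuals, and markers absent from
    the panel are errors.
    """
    # na_filter off: genotype cells (including a literal "NA" missing code)
    # must reach the parser as strings
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise DataError(f"duplicate individual id(s): {dupes}")
    by_id = {m.marker_id: m for m in panel}
    unknown = [c for c in frame.columns if c not in by_id]
    if unknown:
        raise DataError(f"marker(s) in file absent from panel: {unknown}")
    markers = [by_id[c] for c in frame.columns]
    calls = np.full(frame.shape, CALL_MISSING, dtype=np.int8)
    for j, m in enumerate(markers):
        col = frame.iloc[:, j]
        for i, cell in enumerate(col):
            cell = str(cell).strip()
            if cell == missing_code:
                continue
            if numeric:
                if cell not in ("0", "1", "2"):
                    raise DataError(f"{m.marker_id}: numeric dosage cell {cell!r} not in 0/1/2")
                calls[i, j] = int(cell)
            else:
                calls[i, j] = m.parse_cell(cell)
    return GenotypeMatrix(
        individual_ids=[str(i) for i in frame.index],
        markers=markers,
        calls=calls,
    )


def read_phenotypes(path: str | Path) -> pd.Series:
    """Read a two-column phenotype TSV (individual id, fruit weight in grams).

    Returns a float Series indexed by individual id. Weights must be finite
    and strictly positive; duplicate ids and empty files are errors.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise DataError("phenotype file needs two columns (id, weight)")
    if len(frame) == 0:
        raise DataError("no records in phenotype file")
    ids = frame.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DataError(f"duplicate individual id(s): {ids[ids.duplicated()].tolist()}")
    try:
        weights = pd.to_numeric(frame.iloc[:, 1], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-numeric fruit weight: {exc}") from exc
    if not np.all(np.isfinite(weights)) or (weights <= 0).any():
        raise DataError("fruit weights must be finite and positive")
    out = pd.Series(weights.to_numpy(), index=pd.Index(ids, name="individual_id"),
                    name="fruit_weight")
    return out


def read_vcf(path: str | Path) -> tuple[list[MarkerDef], GenotypeMatrix]:
    """Read biallelic SNP records with GT fields from a VCF.

    GT 0/0 -> homozygous reference, 0/1 or 1/0 -> heterozygous,
    1/1 -> homozygous alternate, ./. -> missing. Multiallelic records
    are rejected.
    """
    from cyvcf2 import VCF  # deferred: only needed on the VCF path

    reader = VCF(str(path))
    individual_ids = list(reader.samples)
    markers: list[MarkerDef] = []
    rows: list[np.ndarray] = []
    for rec in reader:
        if len(rec.ALT) != 1:
            raise DataError(
                f"multiallelic record at {rec.CHROM}:{rec.POS} (ALT={','.join(rec.ALT)})"
            )
        marker_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        markers.append(
            MarkerDef(
                marker_id=marker_id,
                chromosome=rec.CHROM,
                position=rec.POS,
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        codes = np.empty(len(individual_ids), dtype=np.int8)
        for i, gt in enumerate(rec.gt_types):
            if gt == 0:
                codes[i] = CALL_HOMREF
            elif gt == 1:
                codes[i] = CALL_HET
            elif gt == 3:
                codes[i] = CALL_HOMALT
            else:
                codes[i] = CALL_MISSING
        rows.append(codes)
    reader.close()
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(individual_ids), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(individual_ids=individual_ids, markers=markers, calls=calls)
    return markers, matrix


# ---------------------------------------------------------------------------
# writers


def write_genotypes(
    matrix: GenotypeMatrix,
    path: str | Path,
    missing_code: str = DEFAULT_MISSING_CODE,
) -> None:
    matrix.to_frame(missing_code=missing_code).to_csv(path, sep="\t")


def write_phenotypes(weights: pd.Series, path: str | Path) -> None:
    frame = weights.rename("fruit_weight").to_frame()
    frame.index.name = "individual_id"
    frame.to_csv(path, sep="\t", float_format="%.4f")


def write_panel(panel: Sequence[MarkerDef], path: str | Path) -> None:
    frame = pd.DataFrame([dataclasses.asdict(m) for m in panel])
    frame.to_csv(path, sep="\t", index=False)


def write_table(records: Iterable, path: str | Path, record_type: type | None = None) -> None:
    """Write result records (dataclasses or mappings) as TSV.

    Floats get at least four decimal places. An empty record list produces a
    header-only file when ``record_type`` (a dataclass) is given.
    """
    rows = list(records)
    if rows and dataclasses.is_dataclass(rows[0]):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    elif not rows and record_type is not None and dataclasses.is_dataclass(record_type):
        frame = pd.DataFrame(columns=[f.name for f in dataclasses.fields(record_type)])
    else:
        frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
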