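#!/usr/bin/env python
"""Per-marker genetic diversity of every population.

Computes allele frequencies, PIC, Ne, Ho, He and the Hardy–Weinberg
chi-square for each of the 70 panel markers in each population, writes
one diversity TSV per population, and prints the marker count trail
(total -> polymorphic -> moderate PIC -> HWE-conforming) that drives the
downstream screening.
"""

from pathlib import Path

from applegap.data_io import read_genotypes, read_panel, write_table
from applegap.diversity import diversity_table

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "simdata"


def main() -> None:
    panel = read_panel(DATA / "panel.tsv")
    names = [p.name.replace("_genotypes.tsv", "")
             for p in sorted(DATA.glob("*_genotypes.tsv"))]
    for name in names:
        matrix = read_genotypes(DATA / f"{name}_genotypes.tsv", panel)
        records = diversity_table(matrix)
        write_table(records, ROOT / "results" / f"{name}_diversity.tsv")
        poly = sum(1 for r in records if r.pic > 0)
        moderate = [r for r in records if r.polymorphism_class == "moderate"]
        conforming = sum(1 for r in moderate if r.hwe_conforming)
        print(
            f"{name}: 70 markers -> {poly} polymorphic -> "
            f"{len(moderate)} moderate PIC -> {conforming} HWE-conforming"
        )


if __name__ == "__main__":
    main()
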