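#!/usr/bin/env python
"""Generate the synthetic six-population F1 study.

Writes the panel, per-population genotype and phenotype TSVs, and the
cross metadata to results/simdata/. The study mirrors a multi-family
apple fruit-weight validation design: six biparental crosses of 80, 75,
137, 113, 80 and 88 offspring (573 in total) genotyped at 70 biallelic
SNPs, with population-specific monomorphism and ten causal markers.
"""

from pathlib import Path

from applegap.simdata import default_config, make_study

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simdata"


def main() -> None:
    study = make_study(default_config(SEED), OUT)
    print(f"wrote {len(study)} populations to {OUT}")
    for name, pop in study.items():
        n_poly = sum(
            len(set(col[col >= 0])) > 1 for col in pop.genotypes.calls.T
        )
        print(
            f"  {name}: n={pop.metadata.n_individuals}, "
            f"{n_poly}/70 markers polymorphic, "
            f"parents {pop.metadata.female_parent_mean:.1f} g x "
            f"{pop.metadata.male_parent_mean:.1f} g"
        )


if __name__ == "__main__":
    main()
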