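"""Three-tier marker pre-screening: full panel, PIC + HWE subset, MTA subset.

The screening pipeline retains markers with moderate polymorphism
(PIC ≥ 0.25 by default) that conform to Hardy–Weinberg equilibrium
(p > 0.001, i.e. no severe deviation), then narrows further to markers
with a significant marker-trait association. Combination sizes are
population-specific and entirely data-driven.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_io import MarkerDef
from .diversity import DiversityRecord
from .mta import MTARecord

FULL = "full"
PIC_HWE = "pic_hwe"
MTA = "mta"


@dataclass
class MarkerCombination:
    name: str
    population: str
    marker_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.marker_ids)


def build_combinations(
    diversity: Sequence[DiversityRecord],
    mta: Sequence[MTARecord],
    panel: Sequence[MarkerDef],
    population: str = "",
    pic_min: float = 0.25,
    hwe_alpha: float = 0.001,
    strict_pic: bool = False,
) -> dict[str, MarkerCombination]:
    """The three marker combinations for one population.

    full: the whole panel in panel order. pic_hwe: markers with
    PIC ≥ ``pic_min`` (strict > with ``strict_pic``) whose HWE p-value
    exceeds ``hwe_alpha``. mta: markers flagged significant after FDR
    control (may be empty — downstream prediction then reports NA).
    With defaults and MTA eligibility restricted to the pic_hwe tier,
    mta ⊆ pic_hwe ⊆ full.
    """
    panel_ids = [m.marker_id for m in panel]
    order = {mid: i for i, mid in enumerate(panel_ids)}

    def in_panel_order(ids):
        return sorted(ids, key=order.__getitem__)

    pic_ok = (
        (lambda rec: rec.pic > pic_min) if strict_pic else (lambda rec: rec.pic >= pic_min)
    )
    # NaN hwe_p (monomorphic) fails the comparison, as intended
    pic_hwe_ids = [
        rec.marker_id for rec in diversity if pic_ok(rec) and rec.hwe_p > hwe_alpha
    ]
    mta_ids = [rec.marker_id for rec in mta if rec.significant]
    return {
        FULL: MarkerCombination(FULL, population, list(panel_ids)),
        PIC_HWE: MarkerCombination(PIC_HWE, population, in_panel_order(pic_hwe_ids)),
        MTA: MarkerCombination(MTA, population, in_panel_order(mta_ids)),
    }
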