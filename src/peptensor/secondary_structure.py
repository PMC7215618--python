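"""Ramachandran-region classification and secondary-structure shift trends.

Three regular secondary structures dominate glycyl sites in short
peptides: the β-sheet, the polyproline II (PP II) helix and the
right-handed α-helix.  A {φ, ψ} pair is classified by its periodic
distance to circular regions around canonical centers.

Three empirical trends link the ¹³Cα and ¹⁵N amide tensors to these
classes and together give an unambiguous secondary-structure readout:

    1. ¹³Cα isotropic shifts are lower in α-helices than in β-sheets
       and PP II helices;
    2. the ¹³Cα span is largest in PP II, then α-helix, then β-sheet;
    3. the ¹⁵N amide deviation from axial symmetry is largest in
       β-sheets, then PP II, then α-helix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .tensor_core import ShiftParameters

__all__ = [
    "RamachandranRegion",
    "TrendReport",
    "MissingGroupError",
    "DEFAULT_REGIONS",
    "CAPTION_ALPHA_REGION",
    "classify",
    "trend_report",
]


class MissingGroupError(ValueError):
    """A secondary-structure group needed for a trend has no sites."""


@dataclass(frozen=True)
class RamachandranRegion:
    label: str
    center: tuple[float, float]  # (φ, ψ) degrees
    radius: float = 60.0         # degrees

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


# The α_R center (−90°, −30°) sits in the right-handed helical quadrant
# consistent with φ ≈ −55° helical peptide data; a left-handed variant
# (+90°, −30°) is provided separately for users who need it.
DEFAULT_REGIONS: tuple[RamachandranRegion, ...] = (
    RamachandranRegion("beta_sheet", (-150.0, 150.0)),
    RamachandranRegion("pp2_helix", (-75.0, 145.0)),
    RamachandranRegion("alpha_r_helix", (-90.0, -30.0)),
)
CAPTION_ALPHA_REGION = RamachandranRegion("alpha_r_helix", (90.0, -30.0))


def _wrap(x: float) -> float:
    return (x + 180.0) % 360.0 - 180.0


def classify(phi: float, psi: float,
             regions: Sequence[RamachandranRegion] = DEFAULT_REGIONS) -> str:
    """Label of the nearest region under periodic Euclidean distance.

    Returns "other" if no region center lies within its radius; ties are
    broken by region list order.
    """
    best_label, best_d = "other", np.inf
    for region in regions:
        d = float(np.hypot(_wrap(phi - region.center[0]),
                           _wrap(psi - region.center[1])))
        if d <= region.radius and d < best_d:
            best_label, best_d = region.label, d
    return best_label


class TrendReport(NamedTuple):
    iso_lower_in_alpha: bool     # trend 1, ¹³Cα iso
    span_order_pp2_alpha_beta: bool  # trend 2, ¹³Cα span
    dev_order_beta_pp2_alpha: bool   # trend 3, ¹⁵N dev


def trend_report(
    sites: Sequence[tuple[str, ShiftParameters, ShiftParameters]],
) -> TrendReport:
    """Evaluate the three secondary-structure trends on labelled sites.

    ``sites`` holds (label, ¹³Cα parameters, ¹⁵N parameters) triples with
    labels among beta_sheet / pp2_helix / alpha_r_helix.  Trend 1 is the
    strict separation max(α iso) < min(β ∪ PP II iso); trends 2 and 3
    compare group means.
    """
    groups: dict[str, list[tuple[ShiftParameters, ShiftParameters]]] = {
        "beta_sheet": [], "pp2_helix": [], "alpha_r_helix": []}
    for label, c13, n15 in sites:
        if label in groups:
            groups[label].append((c13, n15))
    for label, members in groups.items():
        if not members:
            raise MissingGroupError(f"no sites labelled {label!r}")

    def c13_iso(label): return [c.iso for c, _ in groups[label]]
    def c13_span(label): return float(np.mean([c.span for c, _ in groups[label]]))
    def n15_dev(label): return float(np.mean([n.dev for _, n in groups[label]]))

    t1 = max(c13_iso("alpha_r_helix")) < min(c13_iso("beta_sheet")
                                             + c13_iso("pp2_helix"))
    t2 = c13_span("pp2_helix") > c13_span("alpha_r_helix") > c13_span("beta_sheet")
    t3 = n15_dev("beta_sheet") > n15_dev("pp2_helix") > n15_dev("alpha_r_helix")
    return TrendReport(bool(t1), bool(t2), bool(t3))
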