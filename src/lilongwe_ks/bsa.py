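"""Body-surface-area estimation for woody edema via the Wallace Rule of 9s.

The Rule of 9s, borrowed from burn medicine, partitions the body surface
into regions worth 9% (or multiples) of total BSA. The estimated percent
involved is the weight-fraction inner product over regions; it decides the
stage-3 substage (3A below 10% BSA, 3B at or above).
"""

from __future__ import annotations

from .patient_model import EdemaMap, Region

__all__ = ["WALLACE_WEIGHTS", "estimate_bsa_percent", "bsa_substage"]

#: Adult Wallace Rule-of-9s weights (percent of total BSA per region).
#: The classification names the Wallace rule without pediatric modification;
#: pass a different mapping (e.g. a pediatric chart) to override.
WALLACE_WEIGHTS: dict[Region, float] = {
    Region.HEAD_NECK: 9.0,
    Region.LEFT_ARM: 9.0,
    Region.RIGHT_ARM: 9.0,
    Region.LEFT_LEG: 18.0,
    Region.RIGHT_LEG: 18.0,
    Region.ANTERIOR_TRUNK: 18.0,
    Region.POSTERIOR_TRUNK: 18.0,
    Region.PERINEUM: 1.0,
}
assert sum(WALLACE_WEIGHTS.values()) == 100.0

#: BSA percent at and above which stage-3 edema is substage B. The stage
#: definitions ("less than 10%" vs "more than 10%") leave exactly 10%
#: unassigned; the boundary is placed with the more extensive-disease group.
SUBSTAGE_B_THRESHOLD_PERCENT: float = 10.0


def estimate_bsa_percent(
    edema: EdemaMap, weights: dict[Region, float] | None = None
) -> float:
    """Percent of total body surface area involved by woody edema.

    Computes ``sum(weight[region] * fraction[region])`` over the weighted
    regions. Linear and monotone in each fraction; 0 for no involvement and
    100 only when every region is fully involved.
    """
    table = WALLACE_WEIGHTS if weights is None else weights
    total = 0.0
    for region, frac in edema.fractions.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(
                f"edema fraction for {region.value} must lie in [0, 1], got {frac}"
            )
        total += table.get(region, 0.0) * frac
    return total


def bsa_substage(percent: float) -> str:
    """Map an edema BSA percent to stage-3 substage ``"A"`` or ``"B"``.

    ``"A"`` below 10% BSA, ``"B"`` at or above (exactly 10% is B; see
    :data:`SUBSTAGE_B_THRESHOLD_PERCENT`).
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"BSA percent must lie in [0, 100], got {percent}")
    return "B" if percent >= SUBSTAGE_B_THRESHOLD_PERCENT else "A"
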