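"""Incremental cost-effectiveness: deltas, ICERs, CE-plane quadrants.

Two approaches are supported: the primary *program-total* approach
(differences of arm totals) and the supplementary *per-participant*
approach (difference of median per-participant costs over difference of
mean effects). Ratios are reported at full precision; rounding for
display happens in the reporting layer.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


def quadrant(delta_effect: float, delta_cost: float) -> str:
    """CE-plane quadrant (effect on x, cost on y).

    NE: more effective, more costly (ICER meaningful).
    SE: more effective, cheaper (intervention dominant).
    NW: less effective, more costly (intervention dominated).
    SW: less effective, cheaper.
    Boundary values (zero deltas) fold into the adjacent quadrant with
    nonnegative effect and cost treated as NE.
    """
    if delta_effect >= 0:
        return "NE" if delta_cost >= 0 else "SE"
    return "NW" if delta_cost >= 0 else "SW"


@dataclass(frozen=True)
class CeaResult:
    delta_cost: float
    delta_effect: float
    icer: float | None
    effect_measure: str
    quadrant: str
    approach: str
    status: str = "ok"  # "ok" | "undefined" (zero incremental effect)

    @property
    def dominant(self) -> bool:
        """Intervention both cheaper and at least as effective."""
        return self.quadrant == "SE"

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer,
            "effect_measure": self.effect_measure,
            "quadrant": self.quadrant,
            "approach": self.approach,
            "status": self.status,
        }


def incremental(
    arm_totals: Mapping[str, tuple[float, float]],
    intervention: str,
    comparator: str,
) -> tuple[float, float]:
    """(delta_cost, delta_effect) as intervention minus comparator totals."""
    for arm in (intervention, comparator):
        if arm not in arm_totals:
            raise ValidationError(f"arm {arm!r} absent from totals")
    ci, ei = arm_totals[intervention]
    cc, ec = arm_totals[comparator]
    return ci - cc, ei - ec


def icer(
    delta_cost: float,
    delta_effect: float,
    effect_measure: str = "qaly",
    approach: str = "program-total",
) -> CeaResult:
    """Full-precision ratio of increments with quadrant labeling.

    A zero incremental effect yields an explicit undefined-ICER result
    (status "undefined", icer None) rather than an exception or infinity.
    The sign convention is native: an improvement measured as a negative
    change (e.g. PHQ decrease) gives a negative ICER.
    """
    q = quadrant(delta_effect, delta_cost)
    if delta_effect == 0:
        return CeaResult(delta_cost, delta_effect, None, effect_measure, q, approach, "undefined")
    return CeaResult(
        delta_cost, delta_effect, delta_cost / delta_effect, effect_measure, q, approach
    )


def per_participant_icer(
    costs_by_arm: Mapping[str, Sequence[float]],
    effects_by_arm: Mapping[str, Sequence[float]],
    intervention: str,
    comparator: str,
    effect_measure: str = "qaly",
) -> CeaResult:
    """Supplementary approach: median cost difference over mean effect difference."""
    for arm in (intervention, comparator):
        if arm not in costs_by_arm or arm not in effects_by_arm:
            raise ValidationError(f"arm {arm!r} absent from per-participant inputs")
    dc = float(np.median(costs_by_arm[intervention]) - np.median(costs_by_arm[comparator]))
    de = float(np.mean(effects_by_arm[intervention]) - np.mean(effects_by_arm[comparator]))
    result = icer(dc, de, effect_measure=effect_measure, approach="per-participant")
    return result
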