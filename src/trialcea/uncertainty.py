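"""Bootstrap uncertainty for incremental cost-effectiveness.

Nonparametric paired bootstrap: participants are resampled with
replacement within each arm, keeping every participant's (cost, effect)
pair intact; each of the B replicates yields a (delta cost, delta
effect, ICER) triple. Percentile intervals, willingness-to-pay threshold
fractions, and the cost-effectiveness acceptability curve derive from
the replicate set. Threshold comparisons use net monetary benefit
(lambda * dE - dC > 0), which is well defined in every CE-plane quadrant
and coincides with "ICER below lambda" when dE > 0.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QuadrantStraddleError, ValidationError


@dataclass(frozen=True)
class ThresholdConfig:
    """Willingness-to-pay thresholds anchored at per-capita GDP."""

    gdp_per_capita: float = 4009.0
    multipliers: tuple[float, ...] = (1.0, 3.0)
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 20000.0, 201)
    )

    def __post_init__(self):
        if self.gdp_per_capita <= 0:
            raise ConfigurationError("gdp_per_capita must be positive")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if (np.diff(grid) < 0).any():
            raise ConfigurationError("lambda_grid must be sorted ascending")
        object.__setattr__(self, "lambda_grid", grid)

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(m * self.gdp_per_capita for m in self.multipliers)


@dataclass(frozen=True)
class BootstrapSet:
    """B replicate (delta cost, delta effect, ICER) triples plus provenance."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    icer: np.ndarray  # NaN where the replicate delta effect is exactly 0
    n_per_arm: dict[str, int]
    seed: int
    point_delta_cost: float
    point_delta_effect: float
    #: order-invariant digest of the input (cost, effect) pairs; carried so
    #: tests can verify resampling never re-pairs costs with effects
    pairing_checksum: float = 0.0

    @property
    def B(self) -> int:
        return int(self.delta_cost.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(self.B),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
                "icer": self.icer,
            }
        )


def _pairing_checksum(costs: np.ndarray, effects: np.ndarray) -> float:
    """Symmetric function of the multiset of (cost, effect) pairs."""
    return float(np.sum(np.sin(costs * 0.001) * np.cos(effects * 3.0)))


def bootstrap(
    costs_by_arm: dict[str, Sequence[float]],
    effects_by_arm: dict[str, Sequence[float]],
    intervention: str,
    comparator: str,
    B: int = 1000,
    seed: int = 0,
) -> BootstrapSet:
    """Within-arm paired resampling of per-participant (cost, effect) pairs.

    Replicate r consumes its own child RNG stream, so increasing B
    extends the replicate list without changing earlier replicates.
    Deltas are program-total scale (sums over the resampled arm at its
    original size): intervention minus comparator.
    """
    arrs = {}
    for arm in (comparator, intervention):
        c = np.asarray(costs_by_arm[arm], dtype=float)
        e = np.asarray(effects_by_arm[arm], dtype=float)
        if c.size == 0:
            raise ValidationError(f"arm {arm!r} is empty")
        if c.size != e.size:
            raise ValidationError(f"arm {arm!r}: cost and effect lengths differ")
        if np.isnan(c).any() or np.isnan(e).any():
            raise ValidationError(f"arm {arm!r}: bootstrap inputs contain missing values")
        arrs[arm] = (c, e)

    seeds = np.random.SeedSequence(seed).spawn(B)
    dc = np.empty(B)
    de = np.empty(B)
    for r in range(B):
        rng = np.random.default_rng(seeds[r])
        totals = {}
        for arm in (comparator, intervention):  # fixed draw order
            c, e = arrs[arm]
            idx = rng.integers(0, c.size, size=c.size)
            totals[arm] = (c[idx].sum(), e[idx].sum())
        dc[r] = totals[intervention][0] - totals[comparator][0]
        de[r] = totals[intervention][1] - totals[comparator][1]

    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(de != 0, dc / de, np.nan)
    point_dc = arrs[intervention][0].sum() - arrs[comparator][0].sum()
    point_de = arrs[intervention][1].sum() - arrs[comparator][1].sum()
    checksum = sum(_pairing_checksum(c, e) for c, e in arrs.values())
    return BootstrapSet(
        delta_cost=dc,
        delta_effect=de,
        icer=icers,
        n_per_arm={arm: int(arrs[arm][0].size) for arm in arrs},
        seed=seed,
        point_delta_cost=float(point_dc),
        point_delta_effect=float(point_de),
        pairing_checksum=checksum,
    )


def percentile_ci(bs: BootstrapSet, level: float = 95.0) -> tuple[float, float]:
    """Middle ``level`` percent of the replicate ICERs, linear interpolation.

    Only meaningful when every replicate's incremental effect has the
    same sign; otherwise ratio order statistics mix CE-plane quadrants
    and :class:`QuadrantStraddleError` is raised (use :func:`ceac`).
    """
    if not 0 < level < 100:
        raise ConfigurationError("confidence level must be in (0, 100)")
    de = bs.delta_effect
    if (de > 0).any() and (de <= 0).any():
        raise QuadrantStraddleError(
            "bootstrap replicates straddle delta_effect = 0; percentile ICER "
            "interval is not order-meaningful — use the acceptability curve"
        )
    tail = (100.0 - level) / 2.0
    lo, hi = np.percentile(bs.icer, [tail, 100.0 - tail], method="linear")
    return float(lo), float(hi)


def net_monetary_benefit(bs: BootstrapSet, lam: float) -> np.ndarray:
    return lam * bs.delta_effect - bs.delta_cost


def threshold_fraction(bs: BootstrapSet, thresholds: ThresholdConfig) -> dict[float, float]:
    """Fraction of replicates cost-effective at each configured threshold.

    Cost-effective means positive net monetary benefit, equivalent to
    ICER < lambda whenever delta_effect > 0.
    """
    return {
        lam: float((net_monetary_benefit(bs, lam) > 0).mean())
        for lam in thresholds.thresholds
    }


def ceac(bs: BootstrapSet, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """P(cost-effective) over a willingness-to-pay grid.

    Columns: ``lambda``, ``probability``. Evaluating the curve at a
    threshold value reproduces :func:`threshold_fraction` exactly (same
    NMB rule on the same replicates).
    """
    grid = np.asarray(lambda_grid, dtype=float)
    probs = [(net_monetary_benefit(bs, lam) > 0).mean() for lam in grid]
    return pd.DataFrame({"lambda": grid, "probability": probs})
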