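"""Instrument scoring and QALY estimation.

PHQ-9 totals (0-27, depression cutoff at 10), a linear mapping from
WHODAS-12 items plus sociodemographic covariates to a disability index
in [0, 1], health status as one minus disability, and per-participant
QALYs as the trapezoidal area under the health-status trajectory over
the 12-month horizon.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError

PHQ_ITEMS = 9
PHQ_ITEM_MAX = 3
PHQ_TOTAL_MAX = PHQ_ITEMS * PHQ_ITEM_MAX
PHQ_DEPRESSION_CUTOFF = 10

WHODAS_ITEMS = 12
WHODAS_ITEM_MAX = 4
MAPPED_ITEM_COUNT = 8


@dataclass(frozen=True)
class MappingCoefficients:
    """Linear map from WHODAS items + covariates to a disability index.

    Exactly eight of the twelve WHODAS items carry weight. Coefficient
    values are configuration data, not code: pass the published set for
    the target population via YAML; the package default is a documented
    uniform placeholder.
    """

    intercept: float
    whodas_item_weights: Mapping[int, float]
    sociodemographic_weights: Mapping[str, float] = field(default_factory=dict)
    population_tag: str = "unspecified"

    def __post_init__(self):
        if len(self.whodas_item_weights) != MAPPED_ITEM_COUNT:
            raise ConfigurationError(
                f"mapping must reference exactly {MAPPED_ITEM_COUNT} WHODAS items, "
                f"got {len(self.whodas_item_weights)}"
            )
        for item in self.whodas_item_weights:
            if not 1 <= int(item) <= WHODAS_ITEMS:
                raise ConfigurationError(f"WHODAS item id {item} outside 1..{WHODAS_ITEMS}")

    @classmethod
    def from_yaml(cls, path) -> "MappingCoefficients":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            intercept=float(raw["intercept"]),
            whodas_item_weights={int(k): float(v) for k, v in raw["whodas_item_weights"].items()},
            sociodemographic_weights={str(k): float(v) for k, v in raw.get("sociodemographic_weights", {}).items()},
            population_tag=str(raw.get("population_tag", "unspecified")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "population_tag": self.population_tag,
                    "intercept": self.intercept,
                    "whodas_item_weights": {int(k): float(v) for k, v in self.whodas_item_weights.items()},
                    "sociodemographic_weights": dict(self.sociodemographic_weights),
                },
                fh,
            )


#: Placeholder coefficient set: uniform weight on items 1-8, no covariate
#: terms. Linear predictor stays in [0.05, 0.85] for any item values, so
#: it never clamps. Replace with a published population-specific set in
#: production use.
DEFAULT_MAPPING = MappingCoefficients(
    intercept=0.05,
    whodas_item_weights={i: 0.025 for i in range(1, 9)},
    population_tag="placeholder-uniform",
)


@dataclass
class ClampLog:
    """Counts how often the linear disability predictor left [0, 1]."""

    low: int = 0
    high: int = 0

    @property
    def total(self) -> int:
        return self.low + self.high


def score_phq9(items: Sequence[int]) -> tuple[int, bool]:
    """Sum the nine PHQ-9 items; flag depression at the >= 10 cutoff.

    Raises :class:`ValidationError` on missing or out-of-range items —
    imputation happens upstream, never silently here.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (PHQ_ITEMS,):
        raise ValidationError(f"expected {PHQ_ITEMS} PHQ-9 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise ValidationError("PHQ-9 items contain missing values")
    if ((arr < 0) | (arr > PHQ_ITEM_MAX) | (arr != np.round(arr))).any():
        raise ValidationError(f"PHQ-9 items must be integers in 0..{PHQ_ITEM_MAX}")
    total = int(arr.sum())
    return total, total >= PHQ_DEPRESSION_CUTOFF


def phq_change(baseline_total: float, followup_total: float) -> float:
    """Follow-up minus baseline; negative values indicate improvement."""
    for v in (baseline_total, followup_total):
        if not 0 <= v <= PHQ_TOTAL_MAX:
            raise ValidationError(f"PHQ total {v} outside [0, {PHQ_TOTAL_MAX}]")
    return followup_total - baseline_total


def map_disability(
    items: Mapping[int, float],
    covariates: Mapping[str, float],
    coeffs: MappingCoefficients,
    clamp_log: ClampLog | None = None,
) -> float:
    """Linear disability index from WHODAS items and covariates, clamped to [0, 1].

    Clamping events are recorded in ``clamp_log`` when one is supplied.
    A coefficient referencing an absent item or covariate is a
    configuration error, not a silent zero.
    """
    lp = coeffs.intercept
    for item_id, w in coeffs.whodas_item_weights.items():
        if item_id not in items:
            raise ConfigurationError(f"mapping references WHODAS item {item_id} absent from response")
        value = items[item_id]
        if not 0 <= value <= WHODAS_ITEM_MAX:
            raise ValidationError(f"WHODAS item {item_id} value {value} outside 0..{WHODAS_ITEM_MAX}")
        lp += w * value
    for name, w in coeffs.sociodemographic_weights.items():
        if name not in covariates:
            raise ConfigurationError(f"mapping references covariate {name!r} absent from roster")
        lp += w * covariates[name]
    if lp < 0.0:
        if clamp_log is not None:
            clamp_log.low += 1
        return 0.0
    if lp > 1.0:
        if clamp_log is not None:
            clamp_log.high += 1
        return 1.0
    return float(lp)


def health_status(disability: float) -> float:
    """One minus the disability index: 1 is full health, 0 is death."""
    if not 0.0 <= disability <= 1.0:
        raise ValidationError(f"disability index {disability} outside [0, 1]")
    return 1.0 - disability


def qaly_auc(
    times_months: Sequence[float],
    statuses: Sequence[float],
    horizon_months: float = 12.0,
) -> float:
    """QALYs over the horizon: trapezoidal AUC of health status, in years.

    With measurements at months 0, 3 and 12 the result lies in
    [0, horizon/12]; a constant status of 1 yields exactly one QALY.
    """
    t = np.asarray(times_months, dtype=float)
    s = np.asarray(statuses, dtype=float)
    if t.size < 2:
        raise ValidationError("QALY AUC needs at least two trajectory points")
    if t.size != s.size:
        raise ValidationError("times and statuses differ in length")
    if (np.diff(t) <= 0).any():
        raise ValidationError("trajectory times must be strictly increasing")
    if t[0] < 0 or t[-1] > horizon_months:
        raise ValidationError(f"trajectory times outside [0, {horizon_months}] months")
    if ((s < 0) | (s > 1)).any():
        raise ValidationError("health statuses must lie in [0, 1]")
    return float(np.trapezoid(s, t) / 12.0)


# ---------------------------------------------------------------------------
# Vectorised frame-level helpers used by the pipeline


def phq_totals_frame(phq_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot long PHQ item rows to one total per participant x timepoint.

    Timepoints where any item is missing yield NaN totals (scoring never
    imputes). Columns: participant_id, timepoint_months, phq_total.
    """
    wide = phq_long.pivot_table(
        index=["participant_id", "timepoint_months"],
        columns="item",
        values="value",
        aggfunc="first",
    )
    complete = wide.notna().sum(axis=1) == PHQ_ITEMS
    totals = wide.sum(axis=1).where(complete)
    out = totals.rename("phq_total").reset_index()
    return out


def disability_frame(
    whodas_long: pd.DataFrame,
    roster: pd.DataFrame,
    coeffs: MappingCoefficients,
    clamp_log: ClampLog | None = None,
) -> pd.DataFrame:
    """Disability index per participant x timepoint from long WHODAS rows.

    Returns columns participant_id, timepoint_months, disability,
    health_status. Incomplete item sets (any mapped item missing) give NaN.
    """
    wide = whodas_long.pivot_table(
        index=["participant_id", "timepoint_months"],
        columns="item",
        values="value",
        aggfunc="first",
    )
    item_ids = sorted(coeffs.whodas_item_weights)
    for item_id in item_ids:
        if item_id not in wide.columns:
            raise ConfigurationError(f"mapping references WHODAS item {item_id} absent from data")
    weights = np.array([coeffs.whodas_item_weights[i] for i in item_ids])
    lp = coeffs.intercept + wide[item_ids].to_numpy(dtype=float) @ weights

    if coeffs.sociodemographic_weights:
        cov = roster.set_index("participant_id")
        for name in coeffs.sociodemographic_weights:
            if name not in cov.columns:
                raise ConfigurationError(f"mapping references covariate {name!r} absent from roster")
        pid = wide.index.get_level_values("participant_id")
        for name, w in coeffs.sociodemographic_weights.items():
            lp = lp + w * cov[name].reindex(pid).to_numpy(dtype=float)

    if clamp_log is not None:
        finite = np.isfinite(lp)
        clamp_log.low += int((lp[finite] < 0).sum())
        clamp_log.high += int((lp[finite] > 1).sum())
    disability = np.clip(lp, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "participant_id": wide.index.get_level_values("participant_id"),
            "timepoint_months": wide.index.get_level_values("timepoint_months"),
            "disability": disability,
        }
    )
    out["health_status"] = 1.0 - out["disability"]
    return out


def qaly_frame(status_wide: pd.DataFrame, timepoints: Sequence[float] = (0, 3, 12)) -> pd.Series:
    """Per-participant QALYs from a wide health-status table.

    ``status_wide`` must have one ``hs_<t>`` column per timepoint and be
    fully observed (run after imputation).
    """
    cols = [f"hs_{int(t)}" for t in timepoints]
    missing = [c for c in cols if c not in status_wide.columns]
    if missing:
        raise ValidationError(f"status table lacks columns {missing}")
    values = status_wide[cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("health-status table has missing cells; impute first")
    t = np.asarray(timepoints, dtype=float)
    q = np.trapezoid(values, t, axis=1) / 12.0
    return pd.Series(q, index=status_wide.index, name="qalys")
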