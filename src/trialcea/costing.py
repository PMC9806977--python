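"""Costing: service delivery, amortized implementation, currency conversion.

All monetary outputs are 2020 international dollars from the societal
perspective: formal healthcare, informal care (traditional healers),
transport, and participant time at a configured wage. Implementation
(training and supervision) costs are amortized straight-line over a
five-year horizon across projected annual users.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, UnpricedCategoryError, ValidationError

COST_BLOCKS = ("implementation", "mental", "physical")


@dataclass(frozen=True)
class UnitCostTable:
    """Category -> (block, unit cost in Int$2020 per unit)."""

    entries: Mapping[str, tuple[str, float]]

    def __post_init__(self):
        for cat, (block, cost) in self.entries.items():
            if block not in ("mental", "physical"):
                raise ConfigurationError(f"category {cat!r}: unknown block {block!r}")
            if cost < 0:
                raise ConfigurationError(f"category {cat!r}: negative unit cost {cost}")

    def unit_cost(self, category: str) -> float:
        if category not in self.entries:
            raise UnpricedCategoryError(category)
        return self.entries[category][1]

    def block(self, category: str) -> str:
        if category not in self.entries:
            raise UnpricedCategoryError(category)
        return self.entries[category][0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "UnitCostTable":
        return cls({r.category: (r.block, float(r.unit_cost)) for r in df.itertuples()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "block": b, "unit_cost": u}
            for c, (b, u) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["category", "block", "unit_cost"])

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class LedgerItem:
    """One implementation activity with its allocation across arms."""

    activity: str
    total_cost: float
    currency_year: int = 2020
    arm_allocation: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_cost < 0:
            raise ConfigurationError(f"{self.activity}: negative total cost")
        for arm, share in self.arm_allocation.items():
            if not 0.0 <= share <= 1.0:
                raise ConfigurationError(f"{self.activity}: share for {arm!r} outside [0, 1]")


@dataclass(frozen=True)
class ImplementationCostLedger:
    items: tuple[LedgerItem, ...]
    horizon_years: float = 5.0
    users_per_year: Mapping[str, float] = field(default_factory=dict)
    #: annuitization interest rate; 0% (straight-line) unless configured
    discount_rate: float = 0.0

    def __post_init__(self):
        if self.horizon_years <= 0:
            raise ConfigurationError("amortization horizon must be positive")
        if self.discount_rate < 0:
            raise ConfigurationError("discount rate must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "ImplementationCostLedger":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        items = tuple(
            LedgerItem(
                activity=str(it["activity"]),
                total_cost=float(it["total_cost"]),
                currency_year=int(it.get("currency_year", 2020)),
                arm_allocation={str(k): float(v) for k, v in it.get("arm_allocation", {}).items()},
            )
            for it in raw.get("items", [])
        )
        return cls(
            items=items,
            horizon_years=float(raw.get("horizon_years", 5.0)),
            users_per_year={str(k): float(v) for k, v in raw.get("users_per_year", {}).items()},
            discount_rate=float(raw.get("discount_rate", 0.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "horizon_years": self.horizon_years,
                    "discount_rate": self.discount_rate,
                    "users_per_year": dict(self.users_per_year),
                    "items": [
                        {
                            "activity": it.activity,
                            "total_cost": it.total_cost,
                            "currency_year": it.currency_year,
                            "arm_allocation": dict(it.arm_allocation),
                        }
                        for it in self.items
                    ],
                },
                fh,
            )


@dataclass(frozen=True)
class CurrencyFactors:
    """Combined multiplier per source year onto Int$2020.

    Each factor already chains local-currency inflation and the PPP
    conversion; identity (1.0) leaves amounts unchanged.
    """

    factors: Mapping[int, float] = field(default_factory=lambda: {2020: 1.0})

    def factor(self, source_year: int) -> float:
        if source_year not in self.factors:
            raise ConfigurationError(f"no currency factor configured for year {source_year}")
        return self.factors[source_year]


def convert_currency(amount: float, source_year: int, factors: CurrencyFactors) -> float:
    """Convert an amount from its source currency-year to Int$2020."""
    return amount * factors.factor(source_year)


def combine_factors(*factors: float) -> float:
    """Chain multiplicative conversion steps (inflation, PPP) into one."""
    return float(np.prod(factors))


def amortize_implementation(
    ledger: ImplementationCostLedger,
    arm: str,
    factors: CurrencyFactors | None = None,
) -> float:
    """Per-user implementation cost for one arm, Int$2020.

    Each line item's cost (converted to Int$2020) times the arm's share is
    spread over horizon_years x users_per_year. With a nonzero discount
    rate the annual charge is the standard annuity payment instead of the
    straight-line fraction.
    """
    factors = factors or CurrencyFactors()
    users = ledger.users_per_year.get(arm, 0.0)
    total_allocated = 0.0
    for it in ledger.items:
        share = it.arm_allocation.get(arm, 0.0)
        if share > 0 and users <= 0:
            raise ConfigurationError(
                f"{it.activity}: nonzero allocation to {arm!r} but zero projected users"
            )
        total_allocated += convert_currency(it.total_cost, it.currency_year, factors) * share
    if total_allocated == 0.0:
        return 0.0
    r = ledger.discount_rate
    if r == 0.0:
        annual = total_allocated / ledger.horizon_years
    else:
        annual = total_allocated * r / (1.0 - (1.0 + r) ** -ledger.horizon_years)
    return annual / users


def service_cost(use: pd.DataFrame, table: UnitCostTable) -> pd.DataFrame:
    """Per-participant service-delivery cost by block and recall window.

    ``use`` is long: participant_id, window_end_months, category, quantity.
    Returns one row per participant with ``cost_<block>_<window>`` columns
    (mental/physical x each window present). Quantities must be priced:
    an unknown category raises :class:`UnpricedCategoryError` naming it.
    """
    if (use["quantity"] < 0).any():
        raise ValidationError("service-use quantities must be nonnegative")
    unknown = set(use["category"]) - set(table.entries)
    if unknown:
        raise UnpricedCategoryError(sorted(unknown)[0])
    df = use.copy()
    df["block"] = df["category"].map(lambda c: table.block(c))
    df["cost"] = df["quantity"] * df["category"].map(lambda c: table.unit_cost(c))
    pivot = df.pivot_table(
        index="participant_id",
        columns=["block", "window_end_months"],
        values="cost",
        aggfunc="sum",
        fill_value=0.0,
    )
    pivot.columns = [f"cost_{block}_{int(w)}" for block, w in pivot.columns]
    return pivot.reset_index()


@dataclass
class CostProfile:
    """Per-arm cost summary in the shape of a published cost table.

    ``summary`` rows: arm x block with median and mean per-user cost;
    ``totals`` rows: arm with program-total cost. Totals are the sum of
    per-participant totals (conservation) while medians are computed on
    per-participant values.
    """

    summary: pd.DataFrame
    totals: pd.DataFrame
    per_participant: pd.DataFrame


def cost_profile(per_participant: pd.DataFrame, arm_col: str = "arm") -> CostProfile:
    """Summarize per-participant block costs into the per-arm profile.

    ``per_participant`` needs columns arm plus ``cost_implementation``,
    ``cost_mental``, ``cost_physical`` (complete, post-imputation).
    """
    block_cols = [f"cost_{b}" for b in COST_BLOCKS]
    for c in block_cols:
        if c not in per_participant.columns:
            raise ValidationError(f"per-participant cost table lacks column {c!r}")
    df = per_participant.copy()
    df["cost_total"] = df[block_cols].sum(axis=1)
    long = df.melt(
        id_vars=[arm_col],
        value_vars=block_cols + ["cost_total"],
        var_name="block",
        value_name="cost",
    )
    long["block"] = long["block"].str.removeprefix("cost_")
    summary = (
        long.groupby([arm_col, "block"], sort=False)["cost"]
        .agg(median="median", mean="mean")
        .reset_index()
    )
    totals = df.groupby(arm_col)["cost_total"].agg(program_total="sum", n="count").reset_index()
    return CostProfile(summary=summary, totals=totals, per_participant=df)


def block_totals(
    delivery: pd.DataFrame,
    windows: Iterable[int] = (3, 12),
) -> pd.DataFrame:
    """Collapse per-window delivery costs to per-block totals per participant."""
    out = delivery[["participant_id"]].copy()
    for block in ("mental", "physical"):
        cols = [f"cost_{block}_{w}" for w in windows if f"cost_{block}_{w}" in delivery.columns]
        out[f"cost_{block}"] = delivery[cols].sum(axis=1) if cols else 0.0
    return out
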