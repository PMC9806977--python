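"""Synthetic two-arm trial generator with known ground truth.

Emulates the data structure the downstream analysis assumes: item-level
PHQ-9 and WHODAS-12 responses at months 0/3/12, right-skewed service-use
quantities, amortized implementation costs, and missing-at-random
monotone dropout. Every configured mean is matched exactly in
expectation, so incremental cost, QALY and PHQ-change effects have
closed analytic forms (:func:`ground_truth`) for parameter-recovery
testing.

Generative model
----------------
Each participant carries a latent severity rank ``u ~ Uniform(0, 1)``
shared across instruments and timepoints. Item propensities are Beta
quantiles of ``u`` at the configured per-arm, per-time mean (so item
totals have exactly the configured mean, with dispersion set by the Beta
concentration), and items are binomial draws given the propensity.
Service-use quantities are gamma draws scaled by a mean-preserving
log-normal factor in ``z = probit(u)`` — sicker participants are
costlier without shifting the configured mean.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .errors import ConfigurationError, ValidationError
from .outcomes import (
    DEFAULT_MAPPING,
    PHQ_ITEM_MAX,
    PHQ_ITEMS,
    PHQ_TOTAL_MAX,
    WHODAS_ITEM_MAX,
    WHODAS_ITEMS,
    MappingCoefficients,
)

TIMEPOINTS = (0, 3, 12)
FOLLOWUP_WINDOWS = (3, 12)


@dataclass(frozen=True)
class CategoryCostModel:
    """Gamma model for one service category's use quantities."""

    block: str  # "mental" | "physical"
    unit_cost: float
    #: arm -> {window_end_months -> mean quantity}
    mean_quantity: Mapping[str, Mapping[int, float]]
    shape: float = 2.0

    def __post_init__(self):
        if self.block not in ("mental", "physical"):
            raise ConfigurationError(f"unknown cost block {self.block!r}")
        if self.unit_cost < 0:
            raise ConfigurationError("unit cost must be nonnegative")
        if self.shape <= 0:
            raise ConfigurationError("gamma shape must be positive")
        for arm, by_window in self.mean_quantity.items():
            for w, m in by_window.items():
                if m < 0:
                    raise ConfigurationError(f"{arm}/{w}: negative mean quantity")


@dataclass(frozen=True)
class RosterModel:
    """Baseline sociodemographics (arm-independent by randomization)."""

    age_mean: float = 41.0
    age_sd: float = 13.0
    prob_female: float = 0.85
    prob_has_partner: float = 0.8
    prob_education_primary: float = 0.4

    def __post_init__(self):
        for p in (self.prob_female, self.prob_has_partner, self.prob_education_primary):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"roster probability {p} outside [0, 1]")

    def expectations(self) -> dict[str, float]:
        return {
            "age": self.age_mean,
            "female": self.prob_female,
            "has_partner": self.prob_has_partner,
            "education_primary": self.prob_education_primary,
        }


@dataclass(frozen=True)
class TrialConfig:
    """Everything the generator needs; one seed controls all randomness."""

    n_per_arm: int = 60
    arm_labels: tuple[str, str] = ("ST", "T+P")
    baseline_phq_mean: float = 15.0
    baseline_phq_sd: float = 5.0
    #: arm -> {month -> additive change in mean PHQ total vs baseline}
    phq_time_effect: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {"ST": {3: -4.0, 12: -5.5}, "T+P": {3: -7.0, 12: -9.5}}
    )
    #: arm -> {month -> mean WHODAS item value on the 0-4 scale}
    whodas_item_means: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            "ST": {0: 2.0, 3: 1.6, 12: 1.3},
            "T+P": {0: 2.0, 3: 1.2, 12: 0.8},
        }
    )
    whodas_concentration: float = 12.0
    cost_distributions: Mapping[str, CategoryCostModel] = field(
        default_factory=lambda: default_cost_distributions()
    )
    #: log-scale coupling of quantities to latent severity (mean-preserving)
    cost_severity_coupling: float = 0.3
    #: deterministic per-user implementation (training/supervision) cost
    implementation_cost_per_user: Mapping[str, float] = field(
        default_factory=lambda: {"ST": 329.0, "T+P": 617.0}
    )
    dropout_prob: Mapping[str, float] = field(default_factory=lambda: {"ST": 0.15, "T+P": 0.23})
    #: logit slope on standardized observed baseline PHQ (MAR mechanism)
    dropout_baseline_coef: float = 0.8
    #: among dropouts, fraction already missing at the 3-month visit
    dropout_early_fraction: float = 0.5
    roster: RosterModel = field(default_factory=RosterModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ConfigurationError("n_per_arm must be >= 1")
        if len(self.arm_labels) != 2 or len(set(self.arm_labels)) != 2:
            raise ConfigurationError("exactly two distinct arm labels required")
        for arm in self.arm_labels:
            for p_map, name in ((self.dropout_prob, "dropout_prob"),):
                if not 0.0 <= p_map.get(arm, 0.0) <= 1.0:
                    raise ConfigurationError(f"{name}[{arm}] outside [0, 1]")
            for t in TIMEPOINTS:
                mean = self.phq_mean(arm, t)
                if not 0.0 <= mean <= PHQ_TOTAL_MAX:
                    raise ConfigurationError(
                        f"PHQ mean {mean} for {arm}@{t}m outside [0, {PHQ_TOTAL_MAX}]"
                    )
                m = self.whodas_item_means[arm][t]
                if not 0.0 <= m <= WHODAS_ITEM_MAX:
                    raise ConfigurationError(
                        f"WHODAS item mean {m} for {arm}@{t}m outside [0, {WHODAS_ITEM_MAX}]"
                    )
        if self.baseline_phq_sd <= 0:
            raise ConfigurationError("baseline_phq_sd must be positive")
        if self.whodas_concentration <= 0:
            raise ConfigurationError("whodas_concentration must be positive")
        if not 0.0 <= self.dropout_early_fraction <= 1.0:
            raise ConfigurationError("dropout_early_fraction outside [0, 1]")
        # beta-binomial dispersion must be attainable for the baseline sd
        self.phq_concentration()

    def phq_mean(self, arm: str, t: int) -> float:
        effect = self.phq_time_effect.get(arm, {}).get(t, 0.0) if t != 0 else 0.0
        return self.baseline_phq_mean + effect

    def phq_concentration(self) -> float:
        """Beta concentration reproducing the configured baseline PHQ sd.

        For a total of 9 binomial(3, q) items with q ~ Beta at mean p and
        concentration k, Var(total) = p(1-p)(27k + 729)/(k + 1); invert
        for k given the target variance.
        """
        p = self.baseline_phq_mean / PHQ_TOTAL_MAX
        v = self.baseline_phq_sd**2
        lo = PHQ_TOTAL_MAX * p * (1 - p)  # pure binomial noise floor
        hi = PHQ_TOTAL_MAX**2 * p * (1 - p)  # fully dependent ceiling
        if not lo < v < hi:
            raise ConfigurationError(
                f"baseline_phq_sd^2 = {v:.2f} unattainable; needs ({lo:.2f}, {hi:.2f})"
            )
        return (hi - v) / (v - lo)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        def _cm(cm: CategoryCostModel) -> dict:
            return {
                "block": cm.block,
                "unit_cost": cm.unit_cost,
                "shape": cm.shape,
                "mean_quantity": {a: {int(w): q for w, q in d.items()} for a, d in cm.mean_quantity.items()},
            }

        return {
            "n_per_arm": self.n_per_arm,
            "arm_labels": list(self.arm_labels),
            "baseline_phq_mean": self.baseline_phq_mean,
            "baseline_phq_sd": self.baseline_phq_sd,
            "phq_time_effect": {a: {int(t): v for t, v in d.items()} for a, d in self.phq_time_effect.items()},
            "whodas_item_means": {a: {int(t): v for t, v in d.items()} for a, d in self.whodas_item_means.items()},
            "whodas_concentration": self.whodas_concentration,
            "cost_distributions": {c: _cm(cm) for c, cm in self.cost_distributions.items()},
            "cost_severity_coupling": self.cost_severity_coupling,
            "implementation_cost_per_user": dict(self.implementation_cost_per_user),
            "dropout_prob": dict(self.dropout_prob),
            "dropout_baseline_coef": self.dropout_baseline_coef,
            "dropout_early_fraction": self.dropout_early_fraction,
            "roster": dataclasses.asdict(self.roster),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, raw: Mapping) -> "TrialConfig":
        kwargs = dict(raw)
        if "arm_labels" in kwargs:
            kwargs["arm_labels"] = tuple(kwargs["arm_labels"])
        if "roster" in kwargs and isinstance(kwargs["roster"], Mapping):
            kwargs["roster"] = RosterModel(**kwargs["roster"])
        if "cost_distributions" in kwargs:
            kwargs["cost_distributions"] = {
                c: CategoryCostModel(
                    block=cm["block"],
                    unit_cost=cm["unit_cost"],
                    shape=cm.get("shape", 2.0),
                    mean_quantity={a: {int(w): q for w, q in d.items()} for a, d in cm["mean_quantity"].items()},
                )
                for c, cm in kwargs["cost_distributions"].items()
            }
        for key in ("phq_time_effect", "whodas_item_means"):
            if key in kwargs:
                kwargs[key] = {a: {int(t): v for t, v in d.items()} for a, d in kwargs[key].items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_cost_distributions() -> dict[str, CategoryCostModel]:
    """Plausible right-skewed service-use mix for a depression trial."""
    return {
        "outpatient_mental": CategoryCostModel(
            "mental", 3.5, {"ST": {3: 1.5, 12: 2.0}, "T+P": {3: 2.5, 12: 3.0}}
        ),
        "medication": CategoryCostModel(
            "mental", 0.05, {"ST": {3: 30.0, 12: 60.0}, "T+P": {3: 30.0, 12: 60.0}}
        ),
        "counseling_session": CategoryCostModel(
            "mental", 2.0, {"ST": {3: 0.0, 12: 0.0}, "T+P": {3: 3.0, 12: 1.0}}
        ),
        "participant_time_hours": CategoryCostModel(
            "mental", 0.6, {"ST": {3: 2.0, 12: 2.0}, "T+P": {3: 6.0, 12: 4.0}}
        ),
        "outpatient_physical": CategoryCostModel(
            "physical", 4.0, {"ST": {3: 1.0, 12: 1.5}, "T+P": {3: 1.0, 12: 1.5}}
        ),
        "traditional_healer": CategoryCostModel(
            "physical", 5.0, {"ST": {3: 0.8, 12: 0.8}, "T+P": {3: 0.3, 12: 0.3}}, shape=1.5
        ),
        "transport": CategoryCostModel(
            "physical", 1.0, {"ST": {3: 2.0, 12: 3.0}, "T+P": {3: 2.0, 12: 3.0}}
        ),
    }


@dataclass
class TrialData:
    """A generated (or loaded) trial dataset in the pipeline's schemas."""

    roster: pd.DataFrame  # participant_id, arm, age, female, has_partner, education_primary[, dropout_time]
    phq: pd.DataFrame  # participant_id, timepoint_months, item, value
    whodas: pd.DataFrame  # participant_id, timepoint_months, item, value
    service_use: pd.DataFrame  # participant_id, window_end_months, category, quantity
    unit_costs: pd.DataFrame  # category, block, unit_cost

    def copy(self) -> "TrialData":
        return TrialData(
            roster=self.roster.copy(),
            phq=self.phq.copy(),
            whodas=self.whodas.copy(),
            service_use=self.service_use.copy(),
            unit_costs=self.unit_costs.copy(),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic incremental quantities implied by a config (program-total scale)."""

    true_delta_cost: float
    true_delta_qaly: float
    true_delta_phq: float
    implied_icer: float | None
    detail: Mapping[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "true_delta_cost": self.true_delta_cost,
            "true_delta_qaly": self.true_delta_qaly,
            "true_delta_phq": self.true_delta_phq,
            "implied_icer": self.implied_icer,
            "detail": dict(self.detail),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            true_delta_cost=raw["true_delta_cost"],
            true_delta_qaly=raw["true_delta_qaly"],
            true_delta_phq=raw["true_delta_phq"],
            implied_icer=raw["implied_icer"],
            detail=raw.get("detail", {}),
        )


# ---------------------------------------------------------------------------
# generation


def _beta_quantile(u: np.ndarray, p: float, concentration: float) -> np.ndarray:
    """Propensity with mean exactly p, comonotone in the latent rank u."""
    if p <= 0.0:
        return np.zeros_like(u)
    if p >= 1.0:
        return np.ones_like(u)
    return stats.beta.ppf(u, p * concentration, (1.0 - p) * concentration)


def _item_long(
    rng: np.random.Generator,
    u: np.ndarray,
    pids: np.ndarray,
    mean_by_time: Mapping[int, float],
    item_max: int,
    n_items: int,
    concentration: float,
) -> pd.DataFrame:
    frames = []
    for t in TIMEPOINTS:
        p = mean_by_time[t] / item_max
        q = _beta_quantile(u, p, concentration)
        values = rng.binomial(item_max, q[:, None], size=(u.size, n_items))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, n_items),
                    "timepoint_months": t,
                    "item": np.tile(np.arange(1, n_items + 1), u.size),
                    "value": values.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_trial(config: TrialConfig) -> TrialData:
    """Draw a complete trial (no missingness yet) from the config.

    Deterministic under the config seed: the same config yields a
    byte-identical dataset.
    """
    n = config.n_per_arm
    arms = np.repeat(list(config.arm_labels), n)
    total = 2 * n
    pids = np.array([f"P{i:05d}" for i in range(total)])

    ss = np.random.SeedSequence(config.seed)
    s_roster, s_latent, s_phq, s_whodas, s_cost, _ = ss.spawn(6)
    rng_roster = np.random.default_rng(s_roster)
    rng_latent = np.random.default_rng(s_latent)
    rng_phq = np.random.default_rng(s_phq)
    rng_whodas = np.random.default_rng(s_whodas)
    rng_cost = np.random.default_rng(s_cost)

    r = config.roster
    roster = pd.DataFrame(
        {
            "participant_id": pids,
            "arm": arms,
            "age": np.clip(rng_roster.normal(r.age_mean, r.age_sd, total), 16, 90).round(1),
            "female": (rng_roster.random(total) < r.prob_female).astype(int),
            "has_partner": (rng_roster.random(total) < r.prob_has_partner).astype(int),
            "education_primary": (rng_roster.random(total) < r.prob_education_primary).astype(int),
        }
    )

    u = rng_latent.uniform(size=total)
    # clip away exact 0/1 so probit and beta quantiles stay finite
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = special.ndtri(u)

    kappa_phq = config.phq_concentration()
    phq_frames, whodas_frames = [], []
    for arm in config.arm_labels:
        mask = arms == arm
        phq_frames.append(
            _item_long(
                rng_phq,
                u[mask],
                pids[mask],
                {t: config.phq_mean(arm, t) / PHQ_ITEMS for t in TIMEPOINTS},  # per-item mean
                PHQ_ITEM_MAX,
                PHQ_ITEMS,
                kappa_phq,
            )
        )
        whodas_frames.append(
            _item_long(
                rng_whodas,
                u[mask],
                pids[mask],
                dict(config.whodas_item_means[arm]),
                WHODAS_ITEM_MAX,
                WHODAS_ITEMS,
                config.whodas_concentration,
            )
        )
    phq = pd.concat(phq_frames, ignore_index=True)
    whodas = pd.concat(whodas_frames, ignore_index=True)

    c = config.cost_severity_coupling
    severity_factor = np.exp(c * z - 0.5 * c * c)  # mean-one multiplier
    use_rows = []
    for category in sorted(config.cost_distributions):
        cm = config.cost_distributions[category]
        for arm in config.arm_labels:
            mask = arms == arm
            for w in FOLLOWUP_WINDOWS:
                mean_q = cm.mean_quantity[arm][w]
                if mean_q <= 0:
                    qty = np.zeros(mask.sum())
                else:
                    qty = rng_cost.gamma(cm.shape, mean_q / cm.shape, size=mask.sum())
                    qty = qty * severity_factor[mask]
                use_rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pids[mask],
                            "window_end_months": w,
                            "category": category,
                            "quantity": qty,
                        }
                    )
                )
    service_use = pd.concat(use_rows, ignore_index=True)

    unit_costs = pd.DataFrame(
        [
            {"category": cat, "block": cm.block, "unit_cost": cm.unit_cost}
            for cat, cm in sorted(config.cost_distributions.items())
        ]
    )
    return TrialData(roster=roster, phq=phq, whodas=whodas, service_use=service_use, unit_costs=unit_costs)


# ---------------------------------------------------------------------------
# missingness


def _calibrated_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) == target on this sample."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    f = lambda a: special.expit(a + lp).mean() - target
    return optimize.brentq(f, -40.0, 40.0)


def apply_missingness(data: TrialData, config: TrialConfig) -> TrialData:
    """Impose monotone MAR dropout on a complete dataset.

    Dropout probability is logistic in arm and the standardized observed
    baseline PHQ total (per-arm intercepts calibrated so the expected
    dropout proportion equals the configured one exactly). A dropout time
    of 3 removes both follow-up visits; 12 removes only the last.
    Baseline is never missing.
    """
    out = data.copy()
    baseline = (
        data.phq[data.phq["timepoint_months"] == 0]
        .groupby("participant_id")["value"]
        .sum()
        .reindex(out.roster["participant_id"])
        .to_numpy(dtype=float)
    )
    sd = baseline.std()
    z_obs = (baseline - baseline.mean()) / sd if sd > 0 else np.zeros_like(baseline)
    lp = config.dropout_baseline_coef * z_obs

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    arms = out.roster["arm"].to_numpy()
    prob = np.zeros(len(out.roster))
    for arm in config.arm_labels:
        mask = arms == arm
        target = config.dropout_prob.get(arm, 0.0)
        alpha = _calibrated_intercept(lp[mask], target)
        prob[mask] = special.expit(alpha + lp[mask]) if np.isfinite(alpha) else float(target > 0)
        if target <= 0.0:
            prob[mask] = 0.0
        elif target >= 1.0:
            prob[mask] = 1.0
    dropped = rng.random(len(prob)) < prob
    early = rng.random(len(prob)) < config.dropout_early_fraction
    dropout_time = np.where(dropped, np.where(early, 3.0, 12.0), np.nan)
    out.roster["dropout_time"] = dropout_time

    cutoff = pd.Series(dropout_time, index=out.roster["participant_id"])
    for attr, time_col in (("phq", "timepoint_months"), ("whodas", "timepoint_months"), ("service_use", "window_end_months")):
        df = getattr(out, attr)
        limit = cutoff.reindex(df["participant_id"]).to_numpy()
        keep = ~(df[time_col].to_numpy() >= limit)  # NaN limit -> keep
        setattr(out, attr, df[keep].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# analytic ground truth


def ground_truth(config: TrialConfig, coeffs: MappingCoefficients = DEFAULT_MAPPING) -> GroundTruth:
    """Expected incremental cost/QALY/PHQ implied by the config, analytically.

    Uses the linearity of every generator stage in its configured means;
    no simulation. Assumes the mapping's linear predictor stays inside
    [0, 1] at the configured means (true for the default coefficient set),
    so clamping never distorts the expectation.
    """
    comparator, intervention = config.arm_labels
    cov_exp = config.roster.expectations()
    socio_term = sum(w * cov_exp.get(name, 0.0) for name, w in coeffs.sociodemographic_weights.items())
    item_weight_sum = sum(coeffs.whodas_item_weights.values())

    def expected_qaly(arm: str) -> float:
        statuses = []
        for t in TIMEPOINTS:
            mean_item = config.whodas_item_means[arm][t]
            d = coeffs.intercept + item_weight_sum * mean_item + socio_term
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(
                    f"expected disability {d:.3f} for {arm}@{t}m outside [0, 1]; "
                    "analytic ground truth invalid under clamping"
                )
            statuses.append(1.0 - d)
        return float(np.trapezoid(statuses, TIMEPOINTS) / 12.0)

    def expected_phq_change(arm: str) -> float:
        return config.phq_mean(arm, 12) - config.phq_mean(arm, 0)

    def expected_cost(arm: str) -> float:
        delivery = sum(
            cm.unit_cost * cm.mean_quantity[arm][w]
            for cm in config.cost_distributions.values()
            for w in FOLLOWUP_WINDOWS
        )
        return delivery + config.implementation_cost_per_user.get(arm, 0.0)

    n = config.n_per_arm
    dq = n * (expected_qaly(intervention) - expected_qaly(comparator))
    dp = n * (expected_phq_change(intervention) - expected_phq_change(comparator))
    dc = n * (expected_cost(intervention) - expected_cost(comparator))
    icer = dc / dq if dq != 0 else None
    detail = {
        f"expected_qaly_per_participant[{a}]": expected_qaly(a) for a in config.arm_labels
    }
    detail.update({f"expected_phq_change[{a}]": expected_phq_change(a) for a in config.arm_labels})
    detail.update({f"expected_cost_per_participant[{a}]": expected_cost(a) for a in config.arm_labels})
    return GroundTruth(
        true_delta_cost=dc, true_delta_qaly=dq, true_delta_phq=dp, implied_icer=icer, detail=detail
    )


# ---------------------------------------------------------------------------
# CSV bundle IO


BUNDLE_FILES = {
    "roster": "roster.csv",
    "phq": "phq_long.csv",
    "whodas": "whodas_long.csv",
    "service_use": "service_use.csv",
    "unit_costs": "unit_costs.csv",
}


def write_bundle(data: TrialData, outdir) -> dict[str, Path]:
    """Write the dataset as the pipeline's CSV input schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in BUNDLE_FILES.items():
        path = outdir / fname
        getattr(data, attr).to_csv(path, index=False)
        paths[attr] = path
    return paths


def read_bundle(indir) -> TrialData:
    indir = Path(indir)
    frames = {}
    for attr, fname in BUNDLE_FILES.items():
        path = indir / fname
        if not path.exists():
            raise ValidationError(f"bundle file missing: {path}")
        frames[attr] = pd.read_csv(path)
    return TrialData(**frames)
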