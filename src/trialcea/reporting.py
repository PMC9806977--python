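"""Pipeline orchestration and paper-shaped outputs.

Sequences simulate -> score/map -> impute -> cost -> CEA -> bootstrap ->
render, and writes: a per-arm cost profile table, an incremental
cost-effectiveness table, health-trajectory plots, the CE plane with
willingness-to-pay rays, and the acceptability curve, plus a JSON run
manifest from which every output can be regenerated.

Tables carry both full-precision and display-rounded values (costs to
whole Int$, QALYs to 2 dp, ICERs to whole Int$ per QALY / 2 dp per PHQ
point); ratios are always computed before rounding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

plt.rcParams["svg.fonttype"] = "none"  # keep axis/legend labels as text
import numpy as np
import pandas as pd

from . import cea as cea_mod
from . import costing, imputation, outcomes, synthetic_data, uncertainty
from .errors import ValidationError

TIMEPOINTS = synthetic_data.TIMEPOINTS
WINDOWS = synthetic_data.FOLLOWUP_WINDOWS


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of stage configs; one top-level seed drives every stage."""

    trial: synthetic_data.TrialConfig = field(default_factory=synthetic_data.TrialConfig)
    mapping: outcomes.MappingCoefficients = outcomes.DEFAULT_MAPPING
    ledger: costing.ImplementationCostLedger | None = None
    imputation: imputation.ImputationSpec = field(default_factory=imputation.ImputationSpec)
    thresholds: uncertainty.ThresholdConfig = field(default_factory=uncertainty.ThresholdConfig)
    n_bootstrap: int = 1000
    #: bootstrap the ensemble-averaged per-participant values (default) or
    #: resample within each completed dataset and pool the replicates
    bootstrap_per_imputation: bool = False
    seed: int = 0

    def resolved_ledger(self) -> costing.ImplementationCostLedger:
        if self.ledger is not None:
            return self.ledger
        return ledger_for_per_user_costs(dict(self.trial.implementation_cost_per_user))


def ledger_for_per_user_costs(
    per_user: dict[str, float],
    users_per_year: float = 100.0,
    horizon_years: float = 5.0,
) -> costing.ImplementationCostLedger:
    """Build a ledger whose amortization reproduces given per-user costs.

    The arms' common floor (the minimum per-user cost) becomes one shared
    line item split equally; each arm's excess becomes an arm-specific
    item. Useful for synthetic runs and round-trip fixtures where only
    the per-user totals are known.
    """
    arms = sorted(per_user)
    common = min(per_user.values())
    items = []
    if common > 0:
        items.append(
            costing.LedgerItem(
                activity="training_supervision_common",
                total_cost=common * horizon_years * users_per_year * len(arms),
                arm_allocation={a: 1.0 / len(arms) for a in arms},
            )
        )
    for arm in arms:
        excess = per_user[arm] - common
        if excess > 0:
            items.append(
                costing.LedgerItem(
                    activity=f"specific_{arm}",
                    total_cost=excess * horizon_years * users_per_year,
                    arm_allocation={arm: 1.0},
                )
            )
    return costing.ImplementationCostLedger(
        items=tuple(items),
        horizon_years=horizon_years,
        users_per_year={a: users_per_year for a in arms},
    )


# ---------------------------------------------------------------------------
# assembly


def assemble_analysis_table(
    data: synthetic_data.TrialData,
    coeffs: outcomes.MappingCoefficients,
    clamp_log: outcomes.ClampLog | None = None,
) -> pd.DataFrame:
    """Wide analysis-variable table, one row per participant.

    Columns: roster covariates, phq_<t>, hs_<t> per timepoint, and
    cost_<block>_<w> per delivery block and recall window. Cells a
    participant never reported (dropout) are NaN — this is the table the
    chained-equation imputation operates on.
    """
    roster = data.roster.copy()
    ids = roster[["participant_id", "arm"]]

    phq_tot = outcomes.phq_totals_frame(data.phq)
    phq_wide = phq_tot.pivot(index="participant_id", columns="timepoint_months", values="phq_total")
    phq_wide.columns = [f"phq_{int(t)}" for t in phq_wide.columns]

    dis = outcomes.disability_frame(data.whodas, roster, coeffs, clamp_log=clamp_log)
    hs_wide = dis.pivot(index="participant_id", columns="timepoint_months", values="health_status")
    hs_wide.columns = [f"hs_{int(t)}" for t in hs_wide.columns]

    table = costing.UnitCostTable.from_frame(data.unit_costs)
    delivery = costing.service_cost(data.service_use, table).set_index("participant_id")
    cost_cols = [f"cost_{b}_{w}" for b in ("mental", "physical") for w in WINDOWS]
    for c in cost_cols:
        if c not in delivery.columns:
            delivery[c] = 0.0
    delivery = delivery[cost_cols]

    out = ids.set_index("participant_id")
    for part in (phq_wide, hs_wide, delivery):
        out = out.join(part)
    # windows lost to dropout are missing, not zero
    if "dropout_time" in roster.columns:
        cutoff = roster.set_index("participant_id")["dropout_time"]
        for w in WINDOWS:
            gone = cutoff >= 0  # non-NaN
            mask = gone & (w >= cutoff)
            for b in ("mental", "physical"):
                out.loc[mask, f"cost_{b}_{w}"] = np.nan
    for cov in ("age", "female", "has_partner", "education_primary"):
        if cov in roster.columns:
            out[cov] = roster.set_index("participant_id")[cov]
    expected = [f"phq_{int(t)}" for t in TIMEPOINTS] + [f"hs_{int(t)}" for t in TIMEPOINTS]
    for c in expected:
        if c not in out.columns:
            out[c] = np.nan
    return out.reset_index()


def per_participant_results(
    completed: pd.DataFrame,
    ledger: costing.ImplementationCostLedger,
) -> pd.DataFrame:
    """QALYs, PHQ change and block costs per participant from a completed table."""
    df = completed.copy()
    df["qalys"] = outcomes.qaly_frame(df, TIMEPOINTS).to_numpy()
    df["phq_change"] = df["phq_12"] - df["phq_0"]
    delivery = costing.block_totals(
        df.rename(columns=lambda c: c)[["participant_id"] + [c for c in df.columns if c.startswith("cost_")]]
    )
    df["cost_mental"] = delivery["cost_mental"].to_numpy()
    df["cost_physical"] = delivery["cost_physical"].to_numpy()
    impl = {arm: costing.amortize_implementation(ledger, arm) for arm in df["arm"].unique()}
    df["cost_implementation"] = df["arm"].map(impl)
    df["cost_total"] = df[["cost_implementation", "cost_mental", "cost_physical"]].sum(axis=1)
    keep = [
        "participant_id",
        "arm",
        "qalys",
        "phq_change",
        "cost_implementation",
        "cost_mental",
        "cost_physical",
        "cost_total",
    ]
    return df[keep]


def arm_totals_frame(per_participant: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-arm totals (cost, qalys, phq change) for pooling."""
    rows = []
    for arm, grp in per_participant.groupby("arm", sort=False):
        for quantity, col in (("cost", "cost_total"), ("qalys", "qalys"), ("phq_change", "phq_change")):
            values = grp[col].to_numpy()
            rows.append(
                {
                    "arm": arm,
                    "quantity": quantity,
                    "value": float(values.sum()),
                    # variance of a total: n * sample variance of the mean's summands
                    "within_var": float(len(values) * values.var(ddof=1)) if len(values) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    timestamp: str
    outputs: dict[str, str]
    digests: dict[str, str]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


@dataclass
class PipelineResult:
    manifest: RunManifest
    analysis_table: pd.DataFrame
    per_participant: pd.DataFrame
    cost_profile: costing.CostProfile
    cea_results: dict[str, cea_mod.CeaResult]
    bootstrap_sets: dict[str, uncertainty.BootstrapSet]
    intervals: dict[str, tuple[float, float] | None]
    threshold_fractions: dict[float, float]
    ceac_curve: pd.DataFrame
    pooled_totals: pd.DataFrame
    ground_truth: synthetic_data.GroundTruth | None = None


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "trial": config.trial.to_dict(),
        "mapping": {
            "intercept": config.mapping.intercept,
            "whodas_item_weights": {int(k): v for k, v in config.mapping.whodas_item_weights.items()},
            "sociodemographic_weights": dict(config.mapping.sociodemographic_weights),
            "population_tag": config.mapping.population_tag,
        },
        "imputation": dataclasses.asdict(config.imputation),
        "thresholds": {
            "gdp_per_capita": config.thresholds.gdp_per_capita,
            "multipliers": list(config.thresholds.multipliers),
            "lambda_grid": np.asarray(config.thresholds.lambda_grid).tolist(),
        },
        "n_bootstrap": config.n_bootstrap,
        "bootstrap_per_imputation": config.bootstrap_per_imputation,
        "seed": config.seed,
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    data: synthetic_data.TrialData | None = None,
    simulate: bool = True,
    render: bool = True,
) -> PipelineResult:
    """Execute the full analysis and write all artifacts under ``outdir``.

    With ``simulate`` (and no ``data``), a synthetic trial is generated
    from ``config.trial`` with its configured dropout, and the ground
    truth is written alongside. Identical config and seed reproduce
    byte-identical CSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    truth = None
    try:
        if data is None:
            if not simulate:
                raise ValidationError("no input data and simulation disabled")
            trial_cfg = dataclasses.replace(config.trial, seed=config.seed)
            data = synthetic_data.generate_trial(trial_cfg)
            if any(p > 0 for p in trial_cfg.dropout_prob.values()):
                data = synthetic_data.apply_missingness(data, trial_cfg)
            synthetic_data.write_bundle(data, outdir / "data")
            truth = synthetic_data.ground_truth(trial_cfg, config.mapping)
            truth.to_json(outdir / "data" / "ground_truth.json")

        stage = "outcomes"
        clamp_log = outcomes.ClampLog()
        analysis = assemble_analysis_table(data, config.mapping, clamp_log=clamp_log)

        stage = "imputation"
        spec = dataclasses.replace(config.imputation, seed=config.seed)
        ensemble = imputation.impute_pmm(analysis, spec)

        stage = "costing"
        ledger = config.resolved_ledger()
        per_dataset = [per_participant_results(d, ledger) for d in ensemble.datasets]
        pooled_totals = imputation.pool_cea_inputs(
            ensemble, lambda d: arm_totals_frame(per_participant_results(d, ledger))
        )
        # ensemble-averaged per-participant values drive the point CEA and bootstrap
        per_participant = per_dataset[0][["participant_id", "arm"]].copy()
        value_cols = [c for c in per_dataset[0].columns if c not in ("participant_id", "arm")]
        stacked = np.stack([d[value_cols].to_numpy(dtype=float) for d in per_dataset])
        per_participant[value_cols] = stacked.mean(axis=0)

        stage = "cea"
        comparator, intervention = config.trial.arm_labels
        profile = costing.cost_profile(per_participant)
        totals = {
            arm: (
                float(grp["cost_total"].sum()),
                float(grp["qalys"].sum()),
                float(grp["phq_change"].sum()),
            )
            for arm, grp in per_participant.groupby("arm", sort=False)
        }
        dc, dq = cea_mod.incremental(
            {a: (t[0], t[1]) for a, t in totals.items()}, intervention, comparator
        )
        _, dp = cea_mod.incremental(
            {a: (t[0], t[2]) for a, t in totals.items()}, intervention, comparator
        )
        cea_results = {
            "qaly": cea_mod.icer(dc, dq, "qaly", "program-total"),
            "phq": cea_mod.icer(dc, dp, "phq", "program-total"),
            "qaly_per_participant": cea_mod.per_participant_icer(
                {a: g["cost_total"].to_numpy() for a, g in per_participant.groupby("arm")},
                {a: g["qalys"].to_numpy() for a, g in per_participant.groupby("arm")},
                intervention,
                comparator,
                "qaly",
            ),
        }

        stage = "uncertainty"
        boot_seeds = np.random.SeedSequence(config.seed).spawn(2)
        costs_by_arm = {a: g["cost_total"].to_numpy() for a, g in per_participant.groupby("arm")}
        bootstrap_sets = {}
        for (measure, col), sseq in zip((("qaly", "qalys"), ("phq", "phq_change")), boot_seeds):
            effects = {a: g[col].to_numpy() for a, g in per_participant.groupby("arm")}
            if config.bootstrap_per_imputation:
                parts = []
                child = sseq.spawn(len(per_dataset))
                for d, cs in zip(per_dataset, child):
                    bs_d = uncertainty.bootstrap(
                        {a: g["cost_total"].to_numpy() for a, g in d.groupby("arm")},
                        {a: g[col].to_numpy() for a, g in d.groupby("arm")},
                        intervention,
                        comparator,
                        B=config.n_bootstrap,
                        seed=int(cs.generate_state(1)[0] % (2**31)),
                    )
                    parts.append(bs_d)
                bootstrap_sets[measure] = uncertainty.BootstrapSet(
                    delta_cost=np.concatenate([b.delta_cost for b in parts]),
                    delta_effect=np.concatenate([b.delta_effect for b in parts]),
                    icer=np.concatenate([b.icer for b in parts]),
                    n_per_arm=parts[0].n_per_arm,
                    seed=config.seed,
                    point_delta_cost=float(np.mean([b.point_delta_cost for b in parts])),
                    point_delta_effect=float(np.mean([b.point_delta_effect for b in parts])),
                    pairing_checksum=parts[0].pairing_checksum,
                )
            else:
                bootstrap_sets[measure] = uncertainty.bootstrap(
                    costs_by_arm,
                    effects,
                    intervention,
                    comparator,
                    B=config.n_bootstrap,
                    seed=int(sseq.generate_state(1)[0] % (2**31)),
                )
        intervals: dict[str, tuple[float, float] | None] = {}
        for measure, bs in bootstrap_sets.items():
            try:
                intervals[measure] = uncertainty.percentile_ci(bs)
            except Exception:
                intervals[measure] = None
        fractions = uncertainty.threshold_fraction(bootstrap_sets["qaly"], config.thresholds)
        curve = uncertainty.ceac(bootstrap_sets["qaly"], config.thresholds.lambda_grid)

        stage = "render"
        outputs = _write_outputs(
            outdir,
            ensemble.averaged(),
            per_participant,
            profile,
            cea_results,
            bootstrap_sets,
            intervals,
            fractions,
            curve,
            pooled_totals,
            config,
            render=render,
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    digests = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in outputs.items()
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        package_version=_version(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs={k: str(v) for k, v in outputs.items()},
        digests=digests,
    )
    manifest.to_json(outdir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        analysis_table=analysis,
        per_participant=per_participant,
        cost_profile=profile,
        cea_results=cea_results,
        bootstrap_sets=bootstrap_sets,
        intervals=intervals,
        threshold_fractions=fractions,
        ceac_curve=curve,
        pooled_totals=pooled_totals,
        ground_truth=truth,
    )


def _version() -> str:
    from . import __version__

    return __version__


def _write_outputs(
    outdir: Path,
    analysis_avg: pd.DataFrame,
    per_participant: pd.DataFrame,
    profile: costing.CostProfile,
    cea_results: dict,
    bootstrap_sets: dict,
    intervals: dict,
    fractions: dict,
    curve: pd.DataFrame,
    pooled_totals: pd.DataFrame,
    config: PipelineConfig,
    render: bool = True,
) -> dict[str, Path]:
    outputs: dict[str, Path] = {}

    def save_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        outputs[name] = path

    save_csv("per_participant.csv", per_participant)
    save_csv("table2_cost_profile.csv", _table2(profile, per_participant))
    save_csv("table3_incremental.csv", _table3(per_participant, cea_results, intervals, pooled_totals))
    save_csv("bootstrap_replicates.csv", bootstrap_sets["qaly"].to_frame())
    save_csv("ceac.csv", curve)

    cea_json = {
        name: res.to_dict() | {"ci95": intervals.get(name.split("_")[0])}
        for name, res in cea_results.items()
    }
    cea_json["threshold_fractions"] = {str(k): v for k, v in fractions.items()}
    path = outdir / "cea.json"
    path.write_text(json.dumps(cea_json, indent=2, sort_keys=True))
    outputs["cea.json"] = path

    if render:
        outputs["fig1_health_effects.svg"] = render_status_trajectories(
            analysis_avg, outdir / "fig1_health_effects.svg"
        )
        outputs["fig2_ce_plane.svg"] = render_ce_plane(
            bootstrap_sets["qaly"], config.thresholds, outdir / "fig2_ce_plane.svg"
        )
        outputs["fig_s3_ceac.svg"] = render_ceac(
            curve, config.thresholds, outdir / "fig_s3_ceac.svg"
        )
    return outputs


def _round_cost(x: float) -> float:
    return float(np.round(x))


def _table2(profile: costing.CostProfile, per_participant: pd.DataFrame) -> pd.DataFrame:
    t = profile.summary.copy()
    t["median_rounded"] = t["median"].round(1)
    t["mean_rounded"] = t["mean"].round(1)
    qaly = (
        per_participant.groupby("arm")["qalys"].agg(qaly_total="sum", qaly_mean="mean").reset_index()
    )
    return t.merge(qaly, on="arm", how="left")


def _table3(per_participant, cea_results, intervals, pooled_totals) -> pd.DataFrame:
    rows = []
    for arm, grp in per_participant.groupby("arm", sort=False):
        rows.append(
            {
                "row": f"total[{arm}]",
                "cost": grp["cost_total"].sum(),
                "qalys": grp["qalys"].sum(),
                "phq_change": grp["phq_change"].sum(),
            }
        )
    for measure in ("qaly", "phq"):
        res = cea_results[measure]
        ci = intervals.get(measure)
        rows.append(
            {
                "row": f"incremental[{measure}]",
                "cost": res.delta_cost,
                "qalys": res.delta_effect if measure == "qaly" else np.nan,
                "phq_change": res.delta_effect if measure == "phq" else np.nan,
                "icer": res.icer,
                "icer_rounded": (
                    _round_cost(res.icer)
                    if measure == "qaly" and res.icer is not None
                    else (round(res.icer, 2) if res.icer is not None else None)
                ),
                "ci_low": ci[0] if ci else np.nan,
                "ci_high": ci[1] if ci else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    # imputation-pooled variance alongside, labeled
    if not pooled_totals.empty:
        piv = pooled_totals.pivot(index="arm", columns="quantity", values="between_var")
        for arm in piv.index:
            table.loc[table["row"] == f"total[{arm}]", "between_imputation_var_cost"] = piv.loc[
                arm
            ].get("cost", np.nan)
    return table


# ---------------------------------------------------------------------------
# figures


def render_status_trajectories(
    analysis_averaged: pd.DataFrame, path, timepoints=TIMEPOINTS
) -> Path:
    """Health status and PHQ totals by arm at months 0/3/12 (trajectory shape)."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    t = list(timepoints)
    for arm, grp in analysis_averaged.groupby("arm", sort=False):
        hs = [grp[f"hs_{int(x)}"].mean() for x in t]
        phq = [grp[f"phq_{int(x)}"].mean() for x in t]
        axes[0].plot(t, hs, marker="o", label=arm)
        axes[1].plot(t, phq, marker="s", label=arm)
    axes[0].set_ylabel("mean health status")
    axes[1].set_ylabel("mean PHQ-9 total")
    for ax in axes:
        ax.set_xlabel("months")
        ax.set_xticks(t)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_ce_plane(
    bs: uncertainty.BootstrapSet, thresholds: uncertainty.ThresholdConfig, path
) -> Path:
    """Replicate scatter on the CE plane with threshold rays through the origin."""
    if bs.B == 0:
        raise ValidationError("empty bootstrap set: nothing to plot")
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.scatter(bs.delta_effect, bs.delta_cost, s=6, alpha=0.4)
    xmax = max(float(np.max(np.abs(bs.delta_effect))), 1e-9)
    xs = np.array([0.0, 1.1 * xmax])
    for lam, mult in zip(thresholds.thresholds, thresholds.multipliers):
        ax.plot(xs, lam * xs, lw=1, label=f"{mult:g}x GDP ({lam:.0f})")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("incremental effect (QALYs)")
    ax.set_ylabel("incremental cost (Int$2020)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def render_ceac(curve: pd.DataFrame, thresholds: uncertainty.ThresholdConfig, path) -> Path:
    if curve.empty:
        raise ValidationError("empty CEAC curve: nothing to plot")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["lambda"], curve["probability"])
    for lam, mult in zip(thresholds.thresholds, thresholds.multipliers):
        ax.axvline(lam, ls="--", lw=0.8, label=f"{mult:g}x GDP")
    ax.set_xlabel("willingness to pay (Int$ per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
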