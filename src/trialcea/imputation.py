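"""Multiple imputation by chained equations with predictive mean matching.

Missing analysis variables (per-timepoint health status and PHQ totals,
per-block costs) are filled by cycling linear regressions over the
incomplete columns; each missing cell receives the observed value of a
donor whose predicted mean is among the closest. Imputed values are
therefore always members of the observed support, so bounded scores stay
bounded with no explicit truncation.

Implemented here rather than delegated so that the sweep order, donor
selection and seed handling are fully deterministic and testable at the
level of drawn donor indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class ImputationSpec:
    n_imputations: int = 20
    donor_pool_size: int = 5
    max_iterations: int = 10
    #: optional restriction: variable -> list of predictor columns.
    #: Default (empty) uses every other analysis column.
    predictor_matrix: Mapping[str, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_imputations < 2:
            raise ConfigurationError("n_imputations must be >= 2")
        if self.donor_pool_size < 1:
            raise ConfigurationError("donor_pool_size must be >= 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class ImputedEnsemble:
    """m completed copies of the analysis table plus diagnostics."""

    datasets: list[pd.DataFrame]
    missing_mask: pd.DataFrame
    diagnostics: dict

    @property
    def m(self) -> int:
        return len(self.datasets)

    def averaged(self) -> pd.DataFrame:
        """Cell-wise mean of the m completed datasets (numeric columns)."""
        numeric = self.datasets[0].select_dtypes("number").columns
        stacked = np.stack([d[numeric].to_numpy(dtype=float) for d in self.datasets])
        out = self.datasets[0].copy()
        out[numeric] = stacked.mean(axis=0)
        return out


def _draw_coefficients(
    rng: np.random.Generator, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """OLS fit with an approximate Bayesian parameter draw.

    beta* ~ N(beta_hat, sigma2_hat (X'X)^-1); the perturbation keeps
    between-imputation variability honest. Falls back to the point
    estimate when the residual variance degenerates.
    """
    XtX = X.T @ X
    # ridge jitter guards against exactly collinear predictors
    XtX_reg = XtX + 1e-8 * np.eye(XtX.shape[0]) * max(1.0, np.trace(XtX) / XtX.shape[0])
    beta_hat = np.linalg.solve(XtX_reg, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0:
        return beta_hat
    cov = sigma2 * np.linalg.inv(XtX_reg)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return beta_hat
    return beta_hat + chol @ rng.standard_normal(beta_hat.size)


def _pmm_fill(
    rng: np.random.Generator,
    yhat_obs: np.ndarray,
    yhat_mis: np.ndarray,
    y_obs: np.ndarray,
    donors: int,
) -> np.ndarray:
    """For each missing case, draw one of the `donors` nearest observed values."""
    k = min(donors, y_obs.size)
    dist = np.abs(yhat_mis[:, None] - yhat_obs[None, :])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = rng.integers(0, k, size=yhat_mis.size)
    return y_obs[nearest[np.arange(yhat_mis.size), pick]]


def _single_imputation(
    values: np.ndarray,
    mask: np.ndarray,
    columns: Sequence[str],
    predictor_idx: Mapping[int, np.ndarray],
    spec: ImputationSpec,
    seed: np.random.SeedSequence,
) -> tuple[np.ndarray, list[dict]]:
    rng = np.random.default_rng(seed)
    filled = values.copy()
    incomplete = [j for j in range(len(columns)) if mask[:, j].any()]

    # initialize missing cells with random draws from the observed values
    for j in incomplete:
        obs = values[~mask[:, j], j]
        filled[mask[:, j], j] = rng.choice(obs, size=mask[:, j].sum(), replace=True)

    trace = []
    for _ in range(spec.max_iterations):
        step = {}
        for j in incomplete:  # deterministic sweep order: column order
            miss = mask[:, j]
            X = np.column_stack([np.ones(len(filled)), filled[:, predictor_idx[j]]])
            beta = _draw_coefficients(rng, X[~miss], values[~miss, j])
            yhat = X @ beta
            filled[miss, j] = _pmm_fill(
                rng, yhat[~miss], yhat[miss], values[~miss, j], spec.donor_pool_size
            )
            step[columns[j]] = float(filled[miss, j].mean())
        trace.append(step)
    return filled, trace


def impute_pmm(
    data: pd.DataFrame,
    spec: ImputationSpec,
    id_cols: Sequence[str] = ("participant_id",),
    factor_cols: Sequence[str] = ("arm",),
) -> ImputedEnsemble:
    """Chained-equation PMM over the numeric analysis columns.

    ``factor_cols`` (e.g. the arm indicator) must be fully observed; they
    are dummy-coded and always included as predictors. Observed cells are
    returned untouched in every completed dataset, and every imputed cell
    equals some observed value of its variable.
    """
    data = data.reset_index(drop=True)
    for c in list(id_cols) + list(factor_cols):
        if c not in data.columns:
            raise ValidationError(f"column {c!r} absent from analysis table")
        if c in factor_cols and data[c].isna().any():
            raise ValidationError(f"factor column {c!r} has missing values")

    analysis_cols = [c for c in data.columns if c not in id_cols and c not in factor_cols]
    non_numeric = [c for c in analysis_cols if not pd.api.types.is_numeric_dtype(data[c])]
    if non_numeric:
        raise ValidationError(
            f"non-numeric analysis columns without declared handling: {non_numeric}"
        )
    fully_missing = [c for c in analysis_cols if data[c].isna().all()]
    if fully_missing:
        raise ValidationError(f"variables with no observed values: {fully_missing}")
    for c in analysis_cols:
        n_obs = data[c].notna().sum()
        if data[c].isna().any() and n_obs < spec.donor_pool_size:
            raise ValidationError(
                f"{c!r}: only {n_obs} observed values, fewer than donor pool {spec.donor_pool_size}"
            )

    dummies = pd.get_dummies(data[list(factor_cols)], drop_first=True, dtype=float)
    work = pd.concat([data[analysis_cols], dummies], axis=1)
    columns = list(work.columns)
    values = work.to_numpy(dtype=float)
    mask = np.isnan(values)

    # predictor index sets per incomplete column
    predictor_idx: dict[int, np.ndarray] = {}
    for j, col in enumerate(columns):
        if not mask[:, j].any():
            continue
        if col in spec.predictor_matrix:
            wanted = list(spec.predictor_matrix[col]) + list(dummies.columns)
            idx = [columns.index(c) for c in dict.fromkeys(wanted) if c != col]
        else:
            idx = [k for k in range(len(columns)) if k != j]
        predictor_idx[j] = np.asarray(idx, dtype=int)

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_imputations)
    datasets, traces = [], []
    for m in range(spec.n_imputations):
        filled, trace = _single_imputation(values, mask, columns, predictor_idx, spec, seeds[m])
        completed = data.copy()
        completed[analysis_cols] = filled[:, : len(analysis_cols)]
        datasets.append(completed)
        traces.append(trace)

    missing_mask = pd.DataFrame(mask[:, : len(analysis_cols)], columns=analysis_cols)
    n_missing = {c: int(missing_mask[c].sum()) for c in analysis_cols}
    return ImputedEnsemble(
        datasets=datasets,
        missing_mask=missing_mask,
        diagnostics={"n_missing": n_missing, "chain_means": traces, "seed": spec.seed},
    )


@dataclass(frozen=True)
class PooledStat:
    """Rubin-style pooled mean with its variance decomposition."""

    estimate: float
    between_var: float
    within_var: float

    @property
    def total_var(self) -> float:
        m_corr = 1.0  # caller supplies (1 + 1/m) scaling when needed
        return self.within_var + m_corr * self.between_var


def pool_scalar(values: Sequence[float], within_vars: Sequence[float] | None = None) -> PooledStat:
    """Pool one scalar across the m completed datasets."""
    arr = np.asarray(values, dtype=float)
    between = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    within = float(np.mean(within_vars)) if within_vars is not None else 0.0
    return PooledStat(estimate=float(arr.mean()), between_var=between, within_var=within)


def pool_cea_inputs(
    ensemble: ImputedEnsemble,
    per_dataset_fn,
) -> pd.DataFrame:
    """Pool per-arm analysis totals across the ensemble.

    ``per_dataset_fn`` maps a completed dataset to a tidy frame with
    columns (arm, quantity, value[, within_var]). Returns one row per
    (arm, quantity) with the pooled estimate and between/within variance.
    """
    rows = []
    for d in ensemble.datasets:
        rows.append(per_dataset_fn(d))
    stacked = pd.concat(rows, keys=range(ensemble.m), names=["imputation"]).reset_index(level=0)
    has_within = "within_var" in stacked.columns
    out = []
    for (arm, quantity), grp in stacked.groupby(["arm", "quantity"], sort=False):
        pooled = pool_scalar(
            grp["value"].to_numpy(),
            grp["within_var"].to_numpy() if has_within else None,
        )
        out.append(
            {
                "arm": arm,
                "quantity": quantity,
                "estimate": pooled.estimate,
                "between_var": pooled.between_var,
                "within_var": pooled.within_var,
            }
        )
    return pd.DataFrame(out)
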