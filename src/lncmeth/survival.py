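"""Hub-module prognostic analysis.

The expression of a sub-network's hub mRNAs (its *module*) is used to
fit a multivariate Cox proportional-hazards model.  Each patient's
prognostic index (risk score) is the linear predictor

    PI = beta_1 x_1 + beta_2 x_2 + ... + beta_p x_p

on z-scored expression; patients are split at the median PI into
high-risk (PI > median) and low-risk groups and compared with a
Kaplan-Meier / log-rank analysis.  A fitted model can also be
transferred: the coefficients learned on one cohort split an
independent cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "RiskModel",
    "fit_cox",
    "prognostic_index",
    "median_split",
    "kaplan_meier",
    "logrank",
    "module_survival",
]


@dataclass
class RiskModel:
    """A fitted prognostic module with its risk stratification."""

    genes: list[str]
    beta: pd.Series
    pi: pd.Series  # per-sample prognostic index
    risk_group: pd.Series  # "high" / "low"
    chi2: float
    p: float
    standardization: pd.DataFrame = field(repr=False, default=None)  # mean/std per gene


def _standardize(x: pd.DataFrame, stats: pd.DataFrame | None = None):
    """z-score columns; zero-spread columns are an error (no information)."""
    if stats is None:
        mean = x.mean(axis=0)
        std = x.std(axis=0, ddof=1)
        stats = pd.DataFrame({"mean": mean, "std": std})
    zero = stats["std"] <= 0
    if zero.any():
        raise ValueError(
            f"constant covariate(s): {list(stats.index[zero])} carry no information"
        )
    return (x - stats["mean"]) / stats["std"], stats


def fit_cox(expression: pd.DataFrame, clinical: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Multivariate Cox fit of survival on z-scored module-gene expression.

    ``expression`` is genes x samples; ``clinical`` has columns
    (sample, time, event).  Returns the coefficient vector and the
    per-gene standardization stats used (for transfer to an external
    cohort).  Raises on zero events, constant covariates or a
    non-converging partial likelihood.
    """
    clinical = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    common = [s for s in clinical.index if s in expression.columns]
    if not common:
        raise ValueError("no samples shared between expression and clinical data")
    clin = clinical.loc[common]
    if int(clin["event"].sum()) == 0:
        raise ValueError("no observed events: Cox model cannot be fitted")
    if clin["event"].sum() <= len(expression.index):
        import warnings
        warnings.warn(
            f"only {int(clin['event'].sum())} events for {len(expression.index)} "
            "covariates: estimates may be unstable", stacklevel=2,
        )
    x = expression.T.loc[common].astype(float)
    xz, stats_ = _standardize(x)
    df = xz.copy()
    df["time"] = clin["time"].to_numpy()
    df["event"] = clin["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox partial likelihood did not converge: {exc}") from exc
    beta = cph.params_.copy()
    beta.index.name = "gene"
    return beta, stats_


def prognostic_index(beta: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """PI = sum_g beta_g x_g per sample; ``covariates`` is samples x genes
    (already on the scale beta was fitted on)."""
    missing = [g for g in beta.index if g not in covariates.columns]
    if missing:
        raise ValueError(f"covariates missing genes: {missing}")
    pi = covariates[list(beta.index)].to_numpy(dtype=float) @ beta.to_numpy(dtype=float)
    return pd.Series(pi, index=covariates.index, name="pi")


def median_split(pi: pd.Series) -> pd.Series:
    """Split samples at the median PI: strictly above -> ``high``,
    at or below -> ``low``.  A split leaving either group empty is a
    degenerate stratification and raises."""
    med = float(np.median(pi.to_numpy(dtype=float)))
    group = pd.Series(np.where(pi > med, "high", "low"), index=pi.index, name="risk_group")
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError("degenerate median split: one risk group is empty")
    return group


def kaplan_meier(times, events) -> pd.DataFrame:
    """Kaplan-Meier survival estimate S(t) at each distinct event time.

    Censored-only times shrink the risk set without stepping S."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events == 1])
    s = kmf.survival_function_at_times(event_times)
    return pd.DataFrame({"time": event_times, "survival": s.to_numpy(dtype=float)})


def logrank(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (chi-square on 1 df and its p-value).

    Each frame needs ``time`` and ``event`` columns; empty groups raise."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


def module_survival(
    hub_genes,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    beta: pd.Series | None = None,
    standardization: pd.DataFrame | None = None,
) -> RiskModel:
    """Full prognostic analysis of a hub-gene module.

    Fits the Cox model (unless ``beta`` is supplied for transfer mode),
    computes the prognostic index on z-scored expression, splits at the
    median and runs the log-rank test between risk groups.  An empty
    hub set raises ``no hub mRNAs`` — sub-networks without hubs cannot
    be assessed for survival.
    """
    hub_genes = sorted(hub_genes)
    if not hub_genes:
        raise ValueError("no hub mRNAs: survival analysis not possible for this module")
    missing = [g for g in hub_genes if g not in expression.index]
    if missing:
        raise ValueError(f"expression matrix lacks module genes: {missing}")
    clin = clinical.set_index("sample") if "sample" in clinical.columns else clinical
    common = [s for s in clin.index if s in expression.columns]
    clin = clin.loc[common]
    expr = expression.loc[hub_genes, common]

    if beta is None:
        beta, standardization = fit_cox(expr, clin.reset_index(names="sample"))
    xz, _ = _standardize(expr.T, standardization)
    pi = prognostic_index(beta, xz)
    group = median_split(pi)
    chi2, p = logrank(
        clin.loc[group[group == "high"].index],
        clin.loc[group[group == "low"].index],
    )
    return RiskModel(genes=hub_genes, beta=beta, pi=pi, risk_group=group,
                     chi2=chi2, p=p, standardization=standardization)
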