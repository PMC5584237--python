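"""SAM-style two-class differential analysis with permutation q-values.

The statistic for feature *i* is the moderated t-like

    d_i = (mean_T - mean_N) / (s_i + s0)

with s_i the pooled standard error

    s_i = sqrt{ (1/n_T + 1/n_N) * [SS_T + SS_N] / (n_T + n_N - 2) }

and s0 an exchangeability constant (default: the median of the per-
feature s_i).  Significance comes from label permutations: for a
threshold t the estimated false discovery rate is

    FDR(t) = E_perm[ #{ |d*| >= t } ] / max(1, #{ |d| >= t })

and the q-value of a feature is the minimum FDR over all thresholds
that would call it (a running minimum down the |d| ordering), clipped
to [0, 1].  Features are then called as differentially methylated
lncRNAs (DML: q <= 0.05 and |delta beta| >= 0.1), differentially
expressed genes (DEG: q <= 0.05 and fold change >= 2 or <= 0.5) or
differentially expressed lncRNAs (DEL: q <= 0.05), and the DML/DEL
intersection is cross-classified into the four methylation x expression
groups (high-up, high-down, low-up, low-down).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "SamResult",
    "sam_d",
    "estimate_s0",
    "sam_qvalues",
    "call_dml",
    "call_deg",
    "call_del",
    "classify",
    "FOUR_GROUPS",
]

FOUR_GROUPS = ("high-up", "high-down", "low-up", "low-down")

#: pseudocount added to both group means before the fold change
FC_PSEUDOCOUNT = 0.01


@dataclass
class SamResult:
    """Per-feature SAM output for one data type."""

    table: pd.DataFrame  # columns: d, s, q, delta, fold_change
    s0: float
    n_permutations: int


def _group_stats(x: np.ndarray, t_mask: np.ndarray):
    """Mean difference and pooled scatter for each row of ``x`` (features
    x samples) under tumor mask ``t_mask``.  Vectorized over features."""
    n_t = int(t_mask.sum())
    n_n = int((~t_mask).sum())
    if n_t < 2 or n_n < 2:
        raise ValueError("each group needs at least 2 samples")
    xt = x[:, t_mask]
    xn = x[:, ~t_mask]
    mt = xt.mean(axis=1)
    mn = xn.mean(axis=1)
    ss = ((xt - mt[:, None]) ** 2).sum(axis=1) + ((xn - mn[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n_t + 1.0 / n_n) * ss / (n_t + n_n - 2))
    return mt - mn, s


def sam_d(tumor, normal, s0: float):
    """The SAM statistic ``(d, s)`` for one feature.

    ``d = (mean_T - mean_N) / (s + s0)``; antisymmetric under swapping
    the group labels.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size < 2 or normal.size < 2:
        raise ValueError("each group needs at least 2 values")
    x = np.concatenate([tumor, normal])[None, :]
    mask = np.zeros(x.shape[1], dtype=bool)
    mask[: tumor.size] = True
    diff, s = _group_stats(x, mask)
    return float(diff[0] / (s[0] + s0)), float(s[0])


def estimate_s0(s_values) -> float:
    """Exchangeability constant: the median of the per-feature pooled
    scatters (a deterministic simplification of SAM's percentile
    search)."""
    s_values = np.asarray(s_values, dtype=float)
    if s_values.size == 0:
        raise ValueError("cannot estimate s0 from an empty feature set")
    return float(np.median(s_values))


def _count_ge(sorted_abs: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """#{ values >= t } for each t, given values sorted ascending."""
    return sorted_abs.size - np.searchsorted(sorted_abs, thresholds, side="left")


def sam_qvalues(
    matrix: pd.DataFrame,
    groups: pd.Series,
    b: int | str = 1000,
    seed: int | None = 0,
    s0: float | None = None,
    center: str = "mean",
    log2_stat: bool = False,
) -> SamResult:
    """Permutation q-values for every feature of a features x samples matrix.

    Parameters
    ----------
    matrix : features x samples data frame.
    groups : per-sample labels, ``"tumor"`` / ``"normal"`` (index must
        cover the matrix columns).
    b : number of Monte-Carlo label permutations, or ``"exact"`` for
        full enumeration of all distinct tumor-label assignments
        (rejected above 20 000 assignments).
    seed : RNG seed for Monte-Carlo permutations.
    center : ``"mean"`` (expected number of false calls, the default) or
        ``"median"`` across permutations.
    log2_stat : compute d, s and delta on ``log2(x + 1)`` — the usual
        variance-stabilising choice for RNA-seq-scale expression — while
        the fold change stays on the linear scale.  Leave off for
        beta-value matrices, which are already bounded.
    """
    if center not in {"mean", "median"}:
        raise ValueError("center must be 'mean' or 'median'")
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        missing = list(matrix.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    t_mask = (groups == "tumor").to_numpy()
    x_linear = matrix.to_numpy(dtype=float)
    x = np.log2(x_linear + 1.0) if log2_stat else x_linear
    n = x.shape[1]
    n_t = int(t_mask.sum())

    diff, s = _group_stats(x, t_mask)
    if s0 is None:
        s0 = estimate_s0(s)
    d = diff / (s + s0)

    if b == "exact":
        n_assign = comb(n, n_t)
        if n_assign > 20000:
            raise ValueError(
                f"exact enumeration would need {n_assign} assignments; use Monte-Carlo b"
            )
        masks = np.zeros((n_assign, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_t)):
            masks[i, list(idx)] = True
    else:
        if not (isinstance(b, int) and b >= 1):
            raise ValueError("b must be a positive integer or 'exact'")
        rng = np.random.default_rng(seed)
        masks = np.zeros((b, n), dtype=bool)
        for i in range(b):
            masks[i, rng.choice(n, size=n_t, replace=False)] = True

    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="mergesort")  # ascending
    thresholds = abs_d[order]
    n_called = _count_ge(thresholds, thresholds)  # observed #{|d| >= t}

    counts = np.empty((masks.shape[0], thresholds.size))
    for i, mask in enumerate(masks):
        diff_p, s_p = _group_stats(x, mask)
        abs_dp = np.sort(np.abs(diff_p / (s_p + s0)))
        counts[i] = _count_ge(abs_dp, thresholds)
    expected_false = counts.mean(axis=0) if center == "mean" else np.median(counts, axis=0)

    fdr = expected_false / np.maximum(1, n_called)
    # q at threshold t = min FDR over all thresholds t' <= t (running
    # minimum up the ascending |d| ordering), clipped to [0, 1]
    q_sorted = np.minimum.accumulate(np.clip(fdr, 0.0, 1.0))
    # equal |d| values must share a q: take the value at the last tie
    q = np.empty_like(q_sorted)
    q[order] = q_sorted[np.searchsorted(thresholds, thresholds, side="right") - 1]

    mt = x[:, t_mask].mean(axis=1)
    mn = x[:, ~t_mask].mean(axis=1)
    mt_lin = x_linear[:, t_mask].mean(axis=1)
    mn_lin = x_linear[:, ~t_mask].mean(axis=1)
    table = pd.DataFrame(
        {
            "d": d,
            "s": s,
            "q": q,
            "delta": mt - mn,
            "fold_change": (mt_lin + FC_PSEUDOCOUNT) / (mn_lin + FC_PSEUDOCOUNT),
        },
        index=matrix.index,
    )
    return SamResult(table=table, s0=float(s0), n_permutations=masks.shape[0])


def call_dml(result: SamResult, q_threshold: float = 0.05, delta_threshold: float = 0.1) -> pd.DataFrame:
    """Differentially methylated lncRNAs: ``q <= 0.05`` and
    ``|delta beta| >= 0.1``; the sign of delta assigns ``high`` (tumor
    hypermethylated) vs ``low``."""
    t = result.table
    is_dml = (t["q"] <= q_threshold) & (t["delta"].abs() >= delta_threshold)
    call = np.where(~is_dml, "none", np.where(t["delta"] > 0, "high", "low"))
    out = t.copy()
    out["call"] = call
    return out


def call_deg(result: SamResult, q_threshold: float = 0.05, fc_up: float = 2.0, fc_down: float = 0.5) -> pd.DataFrame:
    """Differentially expressed genes: ``q <= 0.05`` and fold change
    ``>= 2`` (up) or ``<= 0.5`` (down)."""
    t = result.table
    sig = t["q"] <= q_threshold
    up = sig & (t["fold_change"] >= fc_up)
    down = sig & (t["fold_change"] <= fc_down)
    out = t.copy()
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def call_del(result: SamResult, q_threshold: float = 0.05) -> pd.DataFrame:
    """Differentially expressed lncRNAs: ``q <= 0.05`` only; direction
    from the sign of the tumor - normal mean difference."""
    t = result.table
    sig = t["q"] <= q_threshold
    out = t.copy()
    out["call"] = np.where(~sig, "none", np.where(t["delta"] > 0, "up", "down"))
    return out


def classify(dml_calls: pd.DataFrame, del_calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-classify the DML/DEL intersection into the four
    methylation x expression groups.

    ``high`` methylation defines an HMLnc, ``low`` an LMLnc; the group
    is the methylation call crossed with the expression direction
    (e.g. high methylation + down-regulated expression = ``high-down``).
    lncRNAs lacking either call are ``unclassified``.
    """
    ids = dml_calls.index.union(del_calls.index)
    meth = dml_calls["call"].reindex(ids, fill_value="none")
    expr = del_calls["call"].reindex(ids, fill_value="none")
    both = (meth != "none") & (expr != "none")
    group = pd.Series("unclassified", index=ids, name="group")
    group[both] = meth[both] + "-" + expr[both]
    out = pd.DataFrame({"methylation": meth, "expression": expr, "group": group})
    out.index.name = "lncrna_id"
    return out
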