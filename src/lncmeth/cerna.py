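"""Competing-endogenous-RNA (ceRNA) network construction.

A lncRNA and an mRNA form a candidate ceRNA pair when they are
positively co-expressed and share more microRNA partners than chance
predicts.  An edge of the background network must satisfy all four
criteria conjunctively:

* Pearson correlation ``pcc > 0`` across the expression profiles,
* two-sided correlation p-value ``pcc_p <= 0.01``,
* shared-miRNA count ``m >= min_shared`` (default 2: "more than one"),
* hypergeometric tail p of the overlap ``hyper_p <= 0.01``, where for a
  universe of N miRNAs, M partners of the lncRNA and n of the mRNA,

      P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N, n).

Sub-networks are mined by seeding the background with the four
methylation x expression lncRNA groups; mRNAs of degree >= 5 in a
sub-network are its hubs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "pearson_pvalue",
    "shared_mirna_test",
    "mirna_sets",
    "build_background",
    "extract_subnetwork",
    "degrees_and_hubs",
    "summarize",
    "NetworkSummary",
]


def pearson(x, y) -> float:
    """Pearson correlation coefficient between two equal-length vectors.

    Requires n >= 3 and nonzero variance in both (zero variance makes
    the coefficient undefined and raises)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def pearson_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient via the t transform
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on ``n - 2`` degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def shared_mirna_test(m: int, big_m: int, n: int, big_n: int) -> float:
    """Hypergeometric tail probability of observing >= m shared miRNAs.

    ``big_n`` is the miRNA universe size, ``big_m`` the lncRNA's partner
    count, ``n`` the mRNA's partner count, ``m`` the overlap.  Evaluated
    as the survival function of the hypergeometric distribution (exact,
    log-space internally)."""
    if not (0 <= m <= min(big_m, n) and big_m <= big_n and n <= big_n):
        raise ValueError(
            f"inconsistent counts: m={m}, M={big_m}, n={n}, N={big_n}"
        )
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, big_n, big_m, n))


def mirna_sets(interactions: pd.DataFrame) -> dict[str, set[str]]:
    """target -> set of miRNA partners, from a deduplicated table."""
    dedup = interactions.drop_duplicates()
    out: dict[str, set[str]] = {}
    for mirna, target in zip(dedup["mirna_id"], dedup["target_id"]):
        out.setdefault(target, set()).add(mirna)
    return out


@dataclass
class NetworkSummary:
    """Table-style summary of one (sub-)network."""

    n_lncrnas: int
    n_mirnas: int
    n_mrnas: int
    n_edges: int
    mean_lncrna_degree: float


def build_background(
    del_ids,
    deg_ids,
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    lnc_mirna: pd.DataFrame,
    mrna_mirna: pd.DataFrame,
    min_shared: int = 2,
    pcc_p: float = 0.01,
    hyper_p: float = 0.01,
) -> nx.Graph:
    """Background ceRNA network over all DEL x DEG pairs.

    Both expression matrices must share an identical sample column
    order (the correlation scope — tumor-only by default — is the
    caller's responsibility).  Pairs sharing no candidate miRNA are
    never tested; retained edges carry ``pcc``, ``pcc_p``, ``shared``
    and ``hyper_p`` attributes.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("expression matrices must share an identical sample order")
    lnc_sets = mirna_sets(lnc_mirna)
    mrna_sets_ = mirna_sets(mrna_mirna)
    universe = set(lnc_mirna["mirna_id"]) | set(mrna_mirna["mirna_id"])
    big_n = len(universe)
    if big_n == 0:
        warnings.warn("empty interaction tables: background network is empty", stacklevel=2)

    del_ids = [i for i in del_ids if i in lnc_expr.index and i in lnc_sets]
    deg_ids = [i for i in deg_ids if i in mrna_expr.index and i in mrna_sets_]

    g = nx.Graph()
    if not del_ids or not deg_ids:
        return g

    n_samples = lnc_expr.shape[1]
    lx = lnc_expr.loc[del_ids].to_numpy(dtype=float)
    mx = mrna_expr.loc[deg_ids].to_numpy(dtype=float)
    lv = lx.std(axis=1)
    mv = mx.std(axis=1)
    # standardize rows; zero-variance features are skipped (correlation undefined)
    with np.errstate(invalid="ignore", divide="ignore"):
        lz = (lx - lx.mean(axis=1, keepdims=True)) / np.where(lv > 0, lv, np.nan)[:, None]
        mz = (mx - mx.mean(axis=1, keepdims=True)) / np.where(mv > 0, mv, np.nan)[:, None]
    rho = lz @ mz.T / n_samples
    n_skipped = int((lv == 0).sum() + (mv == 0).sum())
    if n_skipped:
        logger.info("build_background: %d zero-variance features skipped", n_skipped)

    for i, lnc in enumerate(del_ids):
        lset = lnc_sets[lnc]
        big_m = len(lset)
        for j, mrna in enumerate(deg_ids):
            shared = lset & mrna_sets_[mrna]
            m = len(shared)
            if m < 1:
                continue
            r = rho[i, j]
            if not np.isfinite(r) or r <= 0:
                continue
            r = float(np.clip(r, -1.0, 1.0))
            p_r = pearson_pvalue(r, n_samples)
            if p_r > pcc_p or m < min_shared:
                continue
            p_h = shared_mirna_test(m, big_m, len(mrna_sets_[mrna]), big_n)
            if p_h > hyper_p:
                continue
            g.add_node(lnc, kind="lncrna")
            g.add_node(mrna, kind="mrna")
            g.add_edge(lnc, mrna, pcc=r, pcc_p=p_r, shared=m, hyper_p=p_h,
                       mirnas=tuple(sorted(shared)))
    return g


def extract_subnetwork(background: nx.Graph, seed_lncrnas) -> nx.Graph:
    """Induced subgraph on the seed lncRNAs plus their background
    neighbors; seeds without edges remain as isolated nodes."""
    seeds = [s for s in seed_lncrnas]
    nodes = set(seeds)
    for s in seeds:
        if s in background:
            nodes.update(background.neighbors(s))
    sub = nx.Graph()
    for s in seeds:
        sub.add_node(s, kind="lncrna")
    present = nodes & set(background.nodes)
    induced = background.subgraph(present)
    sub.add_nodes_from((n, background.nodes[n]) for n in present)
    sub.add_edges_from((u, v, d) for u, v, d in induced.edges(data=True))
    return sub


def degrees_and_hubs(network: nx.Graph, hub_threshold: int = 5):
    """Per-node degrees, hub mRNAs (degree >= 5) and the mean lncRNA
    degree (edge count / lncRNA count)."""
    degrees = dict(network.degree())
    hubs = sorted(
        n for n, d in degrees.items()
        if network.nodes[n].get("kind") == "mrna" and d >= hub_threshold
    )
    lncs = [n for n in network if network.nodes[n].get("kind") == "lncrna"]
    mean_deg = network.number_of_edges() / len(lncs) if lncs else 0.0
    return degrees, hubs, mean_deg


def summarize(network: nx.Graph) -> NetworkSummary:
    """Counts of lncRNAs, miRNAs (distinct miRNAs on edges), mRNAs and
    edges, in the style of a per-group interaction table."""
    lncs = [n for n in network if network.nodes[n].get("kind") == "lncrna"]
    mrnas = [n for n in network if network.nodes[n].get("kind") == "mrna"]
    mirnas: set[str] = set()
    for _, _, d in network.edges(data=True):
        mirnas.update(d.get("mirnas", ()))
    _, _, mean_deg = degrees_and_hubs(network)
    return NetworkSummary(
        n_lncrnas=len(lncs),
        n_mirnas=len(mirnas),
        n_mrnas=len(mrnas),
        n_edges=network.number_of_edges(),
        mean_lncrna_degree=mean_deg,
    )
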