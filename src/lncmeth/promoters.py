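"""Promoter definition, probe mapping and promoter-level methylation.

The promoter of a lncRNA is the 2 kb window immediately upstream of its
transcription start site (TSS), strand-aware: ``[TSS - w, TSS)`` on the
plus strand, ``[TSS, TSS + w)`` on the minus strand, clipped at
coordinate 0.  The methylation level of a lncRNA in a sample is the
unweighted mean beta value of the 450K-style probes falling inside its
promoter.  Tumor and normal promoter-level distributions are compared
with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Promoter",
    "compute_beta",
    "filter_and_impute",
    "define_promoters",
    "map_probes",
    "promoter_level",
    "ks_compare",
]


@dataclass
class Promoter:
    """A strand-aware promoter interval with its mapped probes."""

    lncrna_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    probe_ids: list[str] = field(default_factory=list)


def compute_beta(methy, unmethy):
    """Beta value of a probe: ``Methy / (Methy + Unmethy)``.

    0 is fully unmethylated, 1 fully methylated.  Where both intensities
    are zero the beta value is undefined and returned as NaN (missing),
    never as 0/0.  Accepts scalars or arrays.
    """
    methy = np.asarray(methy, dtype=float)
    unmethy = np.asarray(unmethy, dtype=float)
    if (methy < 0).any() or (unmethy < 0).any():
        raise ValueError("intensities must be nonnegative")
    total = methy + unmethy
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, methy / np.where(total > 0, total, 1.0), np.nan)
    return beta if beta.ndim else float(beta) if total > 0 else float("nan")


def filter_and_impute(betas: pd.DataFrame, max_missing_frac: float = 0.30) -> pd.DataFrame:
    """Drop probes missing in strictly more than ``max_missing_frac`` of
    samples; impute the remaining missing entries with the probe's mean
    over non-missing samples.  Idempotent; the result has no missing
    values.
    """
    if betas.empty:
        raise ValueError("empty beta matrix")
    frac = betas.isna().mean(axis=1)
    kept = betas.loc[frac <= max_missing_frac].copy()
    dropped = len(betas) - len(kept)
    if dropped:
        logger.info("filter_and_impute: dropped %d/%d probes", dropped, len(betas))
    means = kept.mean(axis=1)
    return kept.T.fillna(means).T


def define_promoters(annotation: list[AnnotationRecord], window: int = 2000) -> list[Promoter]:
    """Strand-aware promoter windows upstream of each TSS, clipped at 0."""
    promoters = []
    for rec in annotation:
        if rec.strand == "+":
            start, end = max(0, rec.tss - window), rec.tss
        else:
            start, end = rec.tss, rec.tss + window
        if start >= end:  # TSS at coordinate 0 on + strand
            continue
        promoters.append(Promoter(rec.feature_id, rec.chrom, start, end, rec.strand))
    return promoters


def map_probes(promoters: list[Promoter], manifest: pd.DataFrame) -> list[Promoter]:
    """Assign each probe to every promoter whose half-open interval
    contains its position; a probe may serve several lncRNAs.  Returns
    the same promoters with ``probe_ids`` filled (sorted by position).
    """
    by_chrom = {}
    for chrom, sub in manifest.groupby("chrom"):
        sub = sub.sort_values("pos", kind="mergesort")
        by_chrom[chrom] = (sub["pos"].to_numpy(), sub["probe_id"].to_numpy())
    for p in promoters:
        p.probe_ids = []
        if p.chrom not in by_chrom:
            continue
        pos, ids = by_chrom[p.chrom]
        lo = np.searchsorted(pos, p.start, side="left")
        hi = np.searchsorted(pos, p.end, side="left")
        p.probe_ids = list(ids[lo:hi])
    return promoters


def promoter_level(betas: pd.DataFrame, promoters: list[Promoter]) -> pd.DataFrame:
    """Per-lncRNA, per-sample promoter methylation level.

    The level is the unweighted mean over the promoter's probes present
    in the beta matrix; lncRNAs with no such probes are excluded (their
    count is logged).
    """
    rows, index, counts = [], [], []
    for p in promoters:
        probes = [q for q in p.probe_ids if q in betas.index]
        if not probes:
            continue
        rows.append(betas.loc[probes].mean(axis=0))
        index.append(p.lncrna_id)
        counts.append(len(probes))
    skipped = len(promoters) - len(index)
    if skipped:
        logger.info("promoter_level: %d/%d lncRNAs had no measured promoter probes",
                    skipped, len(promoters))
    prof = pd.DataFrame(rows, index=pd.Index(index, name="lncrna_id"))
    prof.attrs["probe_count"] = dict(zip(index, counts))
    return prof


def ks_compare(tumor_levels, normal_levels) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of per-lncRNA mean
    methylation levels, tumor vs normal (one value per lncRNA per
    group).  Returns ``(D, p)`` with the asymptotic p-value.
    """
    tumor_levels = np.asarray(tumor_levels, dtype=float)
    normal_levels = np.asarray(normal_levels, dtype=float)
    if tumor_levels.size == 0 or normal_levels.size == 0:
        raise ValueError("both level vectors must be nonempty")
    res = stats.ks_2samp(tumor_levels, normal_levels, method="asymp")
    return float(res.statistic), float(res.pvalue)
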