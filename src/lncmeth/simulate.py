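"""Seeded synthetic multi-omics study with planted ground truth.

Generates, on one synthetic chromosome, everything the pipeline
consumes: a lncRNA and a protein-coding gene annotation, a 450K-style
probe manifest, a promoter beta-value matrix, lncRNA/mRNA expression
matrices, miRNA interaction tables, ontology-style annotation tables
and a clinical survival table — together with a truth table recording
what was planted:

* a subset of lncRNAs belongs to each of the four methylation x
  expression classes: their promoter probes are shifted by
  ``+/- delta_beta`` in tumor samples and their expression by
  ``+/- expr_effect`` (log2);
* each planted lncRNA has true ceRNA partner mRNAs: the pair shares
  ``cerna_overlap`` injected miRNAs and a latent expression factor
  giving a positive tumor-sample correlation of about ``cerna_rho``.
  lncRNAs of the two down-classes share a class-level *module* of
  partner mRNAs (so those sub-networks contain hub mRNAs, the up
  classes do not);
* tumor survival times are exponential with log-hazard
  ``sum_g beta_g z_g`` over the high-down module genes (z-scored log2
  expression), with random censoring at rate ``censor_rate``.

Each data modality draws from its own child RNG stream of the master
seed, so changing e.g. the probe count never perturbs the expression
draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationRecord, write_matrix
from .promoters import define_promoters, map_probes

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SyntheticDataset",
    "simulate_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_interactions",
    "simulate_clinical",
    "simulate_ontology",
    "simulate_all",
    "write_dataset",
]

CLASSES = ("high-up", "high-down", "low-up", "low-down")
UP_CLASSES = ("high-up", "low-up")
DOWN_CLASSES = ("high-down", "low-down")

_CHROM = "chrS"
_SLOT = 20_000  # grid spacing per lncRNA
_BODY = 3_000
_PROMOTER = 2_000

# RNG stream ids, one per modality
_STREAMS = {"truth": 0, "annotation": 1, "methylation": 2, "expression": 3,
            "interactions": 4, "clinical": 5, "ontology": 6}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort."""

    seed: int = 42
    n_tumor: int = 40
    n_normal: int = 20
    n_lnc: int = 200
    n_gene: int = 300
    n_mirna: int = 100
    n_probe: int = 2000
    n_high_up: int = 20
    n_high_down: int = 20
    n_low_up: int = 20
    n_low_down: int = 20
    delta_beta: float = 0.25  # planted promoter shift, beta units
    expr_effect: float = 1.5  # planted expression shift, log2 units
    cerna_overlap: int = 3  # shared miRNAs injected per true pair
    cerna_rho: float = 0.6  # latent-factor correlation of true pairs
    pairs_per_lnc: int = 3  # exclusive partner mRNAs per up-class lncRNA
    module_size: int = 6  # shared module mRNAs per down class
    mirna_bg_degree: int = 3  # background miRNAs per lncRNA/mRNA
    frac_extra_deg: float = 0.2  # extra non-partner mRNAs made differential
    survival_beta: float = 0.5  # log-hazard per high-down module gene
    censor_rate: float = 0.3
    missing_rate: float = 0.02
    beta_concentration: float = 50.0  # Beta(a+b) of the probe noise model
    expr_noise_sd: float = 0.8  # log2 residual sd

    def __post_init__(self) -> None:
        counts = dict(n_tumor=self.n_tumor, n_normal=self.n_normal,
                      n_lnc=self.n_lnc, n_gene=self.n_gene, n_mirna=self.n_mirna)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")
        if self.n_probe < 0:
            raise ValueError("n_probe must be nonnegative")
        if self.n_planted > self.n_lnc:
            raise ValueError(
                f"planted lncRNAs ({self.n_planted}) exceed n_lnc ({self.n_lnc})"
            )
        if not 0 < self.delta_beta < 1:
            raise ValueError("delta_beta must lie in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 < self.cerna_rho < 1:
            raise ValueError("cerna_rho must lie in (0, 1)")
        needed = (self.n_high_up + self.n_low_up) * self.pairs_per_lnc + 2 * self.module_size
        if needed > self.n_gene:
            raise ValueError(
                f"partner mRNA demand ({needed}) exceeds n_gene ({self.n_gene})"
            )

    @property
    def n_planted(self) -> int:
        return self.n_high_up + self.n_high_down + self.n_low_up + self.n_low_down

    @property
    def planted_counts(self) -> dict[str, int]:
        return {"high-up": self.n_high_up, "high-down": self.n_high_down,
                "low-up": self.n_low_up, "low-down": self.n_low_down}

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def tumor_samples(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_tumor)]

    @property
    def normal_samples(self) -> list[str]:
        return [f"N{i + 1:03d}" for i in range(self.n_normal)]

    @property
    def sample_groups(self) -> pd.Series:
        s = pd.Series(
            ["tumor"] * self.n_tumor + ["normal"] * self.n_normal,
            index=self.tumor_samples + self.normal_samples,
            name="group",
        )
        s.index.name = "sample_id"
        return s


@dataclass
class TruthTable:
    """What was planted: class labels, true ceRNA pairs, survival betas."""

    classes: pd.Series  # lncRNA id -> class label or "null"
    pairs: list[tuple[str, str]]  # (lncRNA id, mRNA id)
    module_genes: dict[str, list[str]]  # down class -> module mRNA ids
    partner_genes: dict[str, list[str]]  # lncRNA id -> its partner mRNAs
    survival_beta: pd.Series  # mRNA id -> planted log-hazard coefficient
    class_mirnas: dict[str, list[str]] = field(default_factory=dict)

    def lncrnas_of(self, cls: str) -> list[str]:
        return sorted(self.classes.index[self.classes == cls])

    def to_frame(self) -> pd.DataFrame:
        pair_map: dict[str, list[str]] = {}
        for lnc, mrna in self.pairs:
            pair_map.setdefault(lnc, []).append(mrna)
        return pd.DataFrame(
            {
                "class": self.classes,
                "partners": [",".join(sorted(pair_map.get(i, []))) for i in self.classes.index],
            },
            index=self.classes.index,
        )


def _make_truth(config: SimulationConfig) -> TruthTable:
    rng = config.rng("truth")
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lnc)]
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_gene)]
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(config.n_mirna)]

    classes = pd.Series("null", index=pd.Index(lnc_ids, name="lncrna_id"), name="class")
    shuffled = list(rng.permutation(lnc_ids))
    pos = 0
    for cls in CLASSES:
        k = config.planted_counts[cls]
        classes[shuffled[pos:pos + k]] = cls
        pos += k

    free_genes = list(rng.permutation(gene_ids))
    partner_genes: dict[str, list[str]] = {}
    module_genes: dict[str, list[str]] = {}
    pairs: list[tuple[str, str]] = []
    for cls in UP_CLASSES:
        for lnc in sorted(classes.index[classes == cls]):
            mine = [free_genes.pop() for _ in range(config.pairs_per_lnc)]
            partner_genes[lnc] = mine
            pairs.extend((lnc, g) for g in mine)
    for cls in DOWN_CLASSES:
        module = sorted(free_genes.pop() for _ in range(config.module_size))
        module_genes[cls] = module
        for lnc in sorted(classes.index[classes == cls]):
            partner_genes[lnc] = list(module)
            pairs.extend((lnc, g) for g in module)

    class_mirnas = {
        cls: [mirna_ids[i] for i in rng.choice(config.n_mirna, size=config.cerna_overlap,
                                               replace=False)]
        for cls in DOWN_CLASSES
    }

    sb = pd.Series(0.0, index=pd.Index(gene_ids, name="gene"), name="beta")
    sb[module_genes["high-down"]] = config.survival_beta
    return TruthTable(classes=classes, pairs=pairs, module_genes=module_genes,
                      partner_genes=partner_genes, survival_beta=sb,
                      class_mirnas=class_mirnas)


def simulate_annotation(config: SimulationConfig):
    """lncRNA annotation, gene annotation and probe manifest on one
    synthetic chromosome.

    Features sit on a grid with jitter (unambiguous nearest-gene
    assignments); ~80% of probes are placed inside lncRNA promoters in
    round-robin order, the rest uniformly along the chromosome.
    """
    rng = config.rng("annotation")
    chrom_len = 2 * _SLOT + config.n_lnc * _SLOT

    lnc_records = []
    for i in range(config.n_lnc):
        tss = _SLOT + i * _SLOT + int(rng.integers(-2000, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        lid = f"LNC{i + 1:04d}"
        if strand == "+":
            start, end = tss, tss + _BODY
        else:
            start, end = tss - _BODY, tss
        lnc_records.append(AnnotationRecord(lid, lid, _CHROM, start, end, strand,
                                            biotype="lincRNA"))

    gene_records = []
    gene_step = config.n_lnc * _SLOT / config.n_gene
    for j in range(config.n_gene):
        tss = int(_SLOT + (j + 0.5) * gene_step) + int(rng.integers(-200, 201))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{j + 1:04d}"
        if strand == "+":
            start, end = tss, tss + 2000
        else:
            start, end = tss - 2000, tss
        gene_records.append(AnnotationRecord(gid, gid, _CHROM, start, end, strand,
                                             biotype="protein_coding"))

    promoters = define_promoters(lnc_records, window=_PROMOTER)
    positions = []
    n_prom = int(round(0.8 * config.n_probe))
    for k in range(n_prom):
        p = promoters[k % len(promoters)]
        positions.append(int(rng.integers(p.start, p.end)))
    for _ in range(config.n_probe - n_prom):
        positions.append(int(rng.integers(0, chrom_len)))
    order = np.argsort(positions, kind="mergesort")
    manifest = pd.DataFrame(
        {
            "probe_id": [f"cg{i + 1:06d}" for i in range(config.n_probe)],
            "chrom": _CHROM,
            "pos": [positions[i] for i in order],
        }
    )
    return lnc_records, gene_records, manifest


def simulate_methylation(config: SimulationConfig, annotation):
    """Beta-value matrix (probes x samples) plus the truth table.

    Per-probe baselines are Beta-distributed (method-of-moments
    parameters from a per-probe mean and a common concentration);
    probes inside planted promoters have their tumor mean shifted by
    ``+/- delta_beta`` (clipped into (0, 1)); a ``missing_rate``
    fraction of entries is set missing completely at random.
    """
    truth = _make_truth(config)
    rng = config.rng("methylation")
    lnc_records, _, manifest = annotation
    samples = config.tumor_samples + config.normal_samples
    n_t = config.n_tumor

    promoters = map_probes(define_promoters(lnc_records, window=_PROMOTER), manifest)
    probe_class: dict[str, str] = {}
    for p in promoters:
        cls = truth.classes.get(p.lncrna_id, "null")
        if cls in CLASSES:
            direction = "high" if cls.startswith("high") else "low"
            for q in p.probe_ids:
                # a probe shared by a high and a low promoter keeps the first
                probe_class.setdefault(q, direction)

    probe_ids = list(manifest["probe_id"])
    mu = np.empty(len(probe_ids))
    shift = np.zeros(len(probe_ids))
    for i, q in enumerate(probe_ids):
        direction = probe_class.get(q)
        if direction == "high":
            mu[i] = rng.uniform(0.20, 0.55)
            shift[i] = config.delta_beta
        elif direction == "low":
            mu[i] = rng.uniform(0.45, 0.80)
            shift[i] = -config.delta_beta
        else:
            mu[i] = rng.uniform(0.20, 0.80)

    mu_tumor = np.clip(mu + shift, 0.02, 0.98)
    if np.any((mu + shift != mu_tumor) & (shift != 0)):
        warnings.warn("delta_beta clipped at the beta-value bounds for some probes",
                      stacklevel=2)
    kappa = config.beta_concentration
    means = np.concatenate(
        [np.repeat(mu_tumor[:, None], n_t, axis=1),
         np.repeat(mu[:, None], config.n_normal, axis=1)], axis=1,
    )
    values = rng.beta(means * kappa, (1.0 - means) * kappa)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    betas = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                         columns=samples)
    return betas, truth


def simulate_expression(config: SimulationConfig, annotation, truth: TruthTable):
    """Linear-scale lncRNA and mRNA expression matrices.

    log2 expression = per-feature baseline + tumor shift + residual;
    true ceRNA pairs share a latent factor in tumor samples (loading
    ``sqrt(cerna_rho)``, giving a log-scale pair correlation of about
    ``cerna_rho``); the matrices are written as ``2**log2``.
    """
    rng = config.rng("expression")
    lnc_ids = list(truth.classes.index)
    gene_ids = list(truth.survival_beta.index)
    n_t, n_n = config.n_tumor, config.n_normal
    n_s = n_t + n_n
    sd = config.expr_noise_sd
    rho = config.cerna_rho

    lnc_base = rng.normal(5.0, 1.5, size=len(lnc_ids))
    gene_base = rng.normal(5.0, 1.5, size=len(gene_ids))
    lnc_log = lnc_base[:, None] + rng.normal(0.0, sd, size=(len(lnc_ids), n_s))
    gene_log = gene_base[:, None] + rng.normal(0.0, sd, size=(len(gene_ids), n_s))

    lnc_index = {l: i for i, l in enumerate(lnc_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # latent factors: one per up-class lncRNA, one per down class
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    factors: dict[str, np.ndarray] = {}
    for cls in DOWN_CLASSES:
        factors[f"class:{cls}"] = rng.normal(0.0, 1.0, size=n_t)
    for cls in UP_CLASSES:
        for lnc in truth.lncrnas_of(cls):
            factors[f"lnc:{lnc}"] = rng.normal(0.0, 1.0, size=n_t)

    # coupled tumor rows: baseline + sd * (sqrt(rho) z + sqrt(1-rho) eps)
    for cls in CLASSES:
        for lnc in truth.lncrnas_of(cls):
            key = f"class:{cls}" if cls in DOWN_CLASSES else f"lnc:{lnc}"
            z = factors[key]
            i = lnc_index[lnc]
            eps = rng.normal(0.0, 1.0, size=n_t)
            lnc_log[i, :n_t] = lnc_base[i] + sd * (a * z + b * eps)
        for g in sorted({g for l in truth.lncrnas_of(cls) for g in truth.partner_genes[l]}):
            key = f"class:{cls}" if cls in DOWN_CLASSES else None
            if key is None:  # exclusive partner: factor of its own lncRNA
                owner = next(l for l in truth.lncrnas_of(cls) if g in truth.partner_genes[l])
                key = f"lnc:{owner}"
            j = gene_index[g]
            eps_g = rng.normal(0.0, 1.0, size=n_t)
            gene_log[j, :n_t] = gene_base[j] + sd * (a * factors[key] + b * eps_g)

    # planted expression shifts in tumor samples
    for cls in CLASSES:
        sign = +1.0 if cls.endswith("up") else -1.0
        for lnc in truth.lncrnas_of(cls):
            lnc_log[lnc_index[lnc], :n_t] += sign * config.expr_effect
        for g in sorted({g for l in truth.lncrnas_of(cls) for g in truth.partner_genes[l]}):
            gene_log[gene_index[g], :n_t] += sign * config.expr_effect

    # extra differential mRNAs outside the planted partner set
    partner_all = {g for gs in truth.partner_genes.values() for g in gs}
    free = [g for g in gene_ids if g not in partner_all]
    n_extra = int(round(config.frac_extra_deg * len(free)))
    extra = list(rng.permutation(free))[:n_extra]
    for g in extra:
        sign = +1.0 if rng.random() < 0.5 else -1.0
        gene_log[gene_index[g], :n_t] += sign * config.expr_effect

    samples = config.tumor_samples + config.normal_samples
    lnc_expr = pd.DataFrame(2.0 ** lnc_log, index=pd.Index(lnc_ids, name="lncrna_id"),
                            columns=samples)
    mrna_expr = pd.DataFrame(2.0 ** gene_log, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples)
    return lnc_expr, mrna_expr


def simulate_interactions(config: SimulationConfig, truth: TruthTable):
    """miRNA-lncRNA and miRNA-mRNA tables (deduplicated).

    Every lncRNA/mRNA draws ``mirna_bg_degree`` background miRNAs; for
    each true ceRNA pair an injected set of ``cerna_overlap`` common
    miRNAs guarantees the planted shared-miRNA count.
    """
    rng = config.rng("interactions")
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(config.n_mirna)]
    lnc_rows: list[tuple[str, str]] = []
    mrna_rows: list[tuple[str, str]] = []

    lnc_extra: dict[str, list[str]] = {}
    for cls in UP_CLASSES:
        for lnc in truth.lncrnas_of(cls):
            chosen = [mirna_ids[i] for i in rng.choice(config.n_mirna,
                                                       size=config.cerna_overlap,
                                                       replace=False)]
            lnc_extra[lnc] = chosen
    for cls in DOWN_CLASSES:
        for lnc in truth.lncrnas_of(cls):
            lnc_extra[lnc] = list(truth.class_mirnas[cls])

    for lnc in truth.classes.index:
        bg = [mirna_ids[i] for i in rng.choice(config.n_mirna,
                                               size=min(config.mirna_bg_degree, config.n_mirna),
                                               replace=False)]
        for m in bg + lnc_extra.get(lnc, []):
            lnc_rows.append((m, lnc))

    mrna_extra: dict[str, list[str]] = {}
    for lnc, partners in truth.partner_genes.items():
        for g in partners:
            mrna_extra.setdefault(g, [])
            mrna_extra[g] = sorted(set(mrna_extra[g]) | set(lnc_extra[lnc]))
    for g in truth.survival_beta.index:
        bg = [mirna_ids[i] for i in rng.choice(config.n_mirna,
                                               size=min(config.mirna_bg_degree, config.n_mirna),
                                               replace=False)]
        for m in bg + mrna_extra.get(g, []):
            mrna_rows.append((m, g))

    lnc_table = pd.DataFrame(lnc_rows, columns=["mirna_id", "target_id"]).drop_duplicates()
    mrna_table = pd.DataFrame(mrna_rows, columns=["mirna_id", "target_id"]).drop_duplicates()
    return lnc_table.reset_index(drop=True), mrna_table.reset_index(drop=True)


def simulate_clinical(config: SimulationConfig, mrna_expr: pd.DataFrame,
                      truth: TruthTable) -> pd.DataFrame:
    """Tumor-sample survival table (sample, time, event).

    Times are exponential with log-hazard ``sum_g beta_g z_g`` over the
    planted module genes (z-scored log2 expression across tumor
    samples); censoring picks a ``censor_rate`` fraction of samples at
    random and replaces their time by a uniform draw below it.
    """
    rng = config.rng("clinical")
    tumor = config.tumor_samples
    active = truth.survival_beta[truth.survival_beta != 0.0]
    lp = np.zeros(len(tumor))
    if len(active):
        x = np.log2(mrna_expr.loc[active.index, tumor].to_numpy(dtype=float))
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        lp = active.to_numpy() @ z
    base_mean = 1000.0  # days
    times = rng.exponential(base_mean * np.exp(-lp))
    events = (rng.random(len(tumor)) >= config.censor_rate).astype(int)
    u = rng.uniform(0.0, 1.0, size=len(tumor))
    times = np.where(events == 1, times, np.maximum(times * u, 1e-6))
    return pd.DataFrame({"sample": tumor, "time": times, "event": events})


def simulate_ontology(config: SimulationConfig, truth: TruthTable,
                      lnc_mirna: pd.DataFrame | None = None,
                      n_terms: int = 30, n_diseases: int = 10):
    """Term->gene, GO ``is_a`` edge and disease->miRNA tables.

    One term per down class is planted to contain that class's module
    genes, and one disease is planted inside the high-down group's
    miRNA repertoire (so the group's miRNA-disease enrichment has a
    true positive), everything else is random background.  Passing the
    miRNA-lncRNA table lets the planted disease draw from the group's
    actual repertoire; without it only the injected class miRNAs are
    guaranteed members.
    """
    rng = config.rng("ontology")
    gene_ids = list(truth.survival_beta.index)
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(config.n_mirna)]

    term_rows = []
    term_ids = [f"GO:{7000000 + i}" for i in range(n_terms)]
    for i, tid in enumerate(term_ids):
        size = int(rng.integers(10, 31))
        members = {gene_ids[j] for j in rng.choice(len(gene_ids), size=size, replace=False)}
        if i == 0:
            members |= set(truth.module_genes["high-down"])
            name = "planted high-down module process"
        elif i == 1:
            members |= set(truth.module_genes["low-down"])
            name = "planted low-down module process"
        else:
            name = f"background process {i}"
        for g in sorted(members):
            term_rows.append((tid, name, g))
    term_table = pd.DataFrame(term_rows, columns=["term_id", "term_name", "gene"])

    isa_rows = []
    for i in range(1, n_terms):
        if rng.random() < 0.6:
            isa_rows.append((term_ids[i], term_ids[int(rng.integers(0, i))]))
    is_a = pd.DataFrame(isa_rows, columns=["child", "parent"])

    hd_lncs = set(truth.lncrnas_of("high-down"))
    if lnc_mirna is not None:
        repertoire = sorted(set(lnc_mirna.loc[lnc_mirna["target_id"].isin(hd_lncs),
                                              "mirna_id"]))
    else:
        repertoire = sorted(truth.class_mirnas["high-down"])
    disease_rows = []
    for d in range(n_diseases):
        if d == 0:
            name = "planted neoplasm"
            members = set(truth.class_mirnas["high-down"])
            pool = [m for m in repertoire if m not in members]
            k = min(12, len(pool))
            if k:
                members |= {pool[j] for j in rng.choice(len(pool), size=k, replace=False)}
        else:
            name = f"background disease {d}"
            members = {mirna_ids[j] for j in rng.choice(config.n_mirna, size=15,
                                                        replace=False)}
        for m in sorted(members):
            disease_rows.append((name, m))
    disease_table = pd.DataFrame(disease_rows, columns=["disease", "mirna_id"])
    return term_table, is_a, disease_table


@dataclass
class SyntheticDataset:
    """Everything one synthetic study comprises."""

    config: SimulationConfig
    lnc_annotation: list[AnnotationRecord]
    gene_annotation: list[AnnotationRecord]
    manifest: pd.DataFrame
    betas: pd.DataFrame
    lnc_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    lnc_mirna: pd.DataFrame
    mrna_mirna: pd.DataFrame
    clinical: pd.DataFrame
    term_table: pd.DataFrame
    is_a: pd.DataFrame
    disease_table: pd.DataFrame
    truth: TruthTable

    @property
    def sample_groups(self) -> pd.Series:
        return self.config.sample_groups


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage for one seeded study."""
    annotation = simulate_annotation(config)
    betas, truth = simulate_methylation(config, annotation)
    lnc_expr, mrna_expr = simulate_expression(config, annotation, truth)
    lnc_mirna, mrna_mirna = simulate_interactions(config, truth)
    clinical = simulate_clinical(config, mrna_expr, truth)
    term_table, is_a, disease_table = simulate_ontology(config, truth, lnc_mirna)
    return SyntheticDataset(
        config=config,
        lnc_annotation=annotation[0],
        gene_annotation=annotation[1],
        manifest=annotation[2],
        betas=betas,
        lnc_expr=lnc_expr,
        mrna_expr=mrna_expr,
        lnc_mirna=lnc_mirna,
        mrna_mirna=mrna_mirna,
        clinical=clinical,
        term_table=term_table,
        is_a=is_a,
        disease_table=disease_table,
        truth=truth,
    )


def _write_gtf(records: list[AnnotationRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            attrs = (f'gene_id "{r.feature_id}"; gene_name "{r.feature_name}"; '
                     f'gene_type "{r.biotype}";')
            fh.write(
                f"{r.chrom}\tsynthetic\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every modality as plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    _write_gtf(ds.lnc_annotation, outdir / "lncrna_annotation.gtf")
    paths["lncrna_annotation"] = "lncrna_annotation.gtf"
    _write_gtf(ds.gene_annotation, outdir / "gene_annotation.gtf")
    paths["gene_annotation"] = "gene_annotation.gtf"

    ds.manifest.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    paths["probes"] = "probes.tsv"
    write_matrix(ds.betas, outdir / "methylation_beta.tsv")
    paths["methylation"] = "methylation_beta.tsv"
    write_matrix(ds.lnc_expr, outdir / "lncrna_expression.tsv")
    paths["lncrna_expression"] = "lncrna_expression.tsv"
    write_matrix(ds.mrna_expr, outdir / "mrna_expression.tsv")
    paths["mrna_expression"] = "mrna_expression.tsv"
    ds.sample_groups.reset_index().to_csv(outdir / "samples.tsv", sep="\t", index=False)
    paths["samples"] = "samples.tsv"
    ds.lnc_mirna.to_csv(outdir / "mirna_lncrna.tsv", sep="\t", index=False)
    paths["mirna_lncrna"] = "mirna_lncrna.tsv"
    ds.mrna_mirna.to_csv(outdir / "mirna_mrna.tsv", sep="\t", index=False)
    paths["mirna_mrna"] = "mirna_mrna.tsv"
    ds.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    paths["clinical"] = "clinical.tsv"
    ds.term_table.to_csv(outdir / "term_gene.tsv", sep="\t", index=False)
    paths["term_gene"] = "term_gene.tsv"
    ds.is_a.to_csv(outdir / "go_isa.tsv", sep="\t", index=False)
    paths["go_isa"] = "go_isa.tsv"
    ds.disease_table.to_csv(outdir / "disease_mirna.tsv", sep="\t", index=False)
    paths["disease_mirna"] = "disease_mirna.tsv"
    ds.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t")
    paths["truth"] = "truth.tsv"
    return paths
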