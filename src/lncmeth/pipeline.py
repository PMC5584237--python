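"""End-to-end orchestration of the methylation -> network -> survival workflow.

``run_all`` executes: promoter methylation aggregation; SAM differential
calling of methylation (DML), lncRNA expression (DEL) and mRNA
expression (DEG); four-way classification; background ceRNA network
plus the four seeded sub-networks; cis/set/miRNA-disease enrichment;
and the hub-module survival analysis per sub-network.  Every stage
writes plain-text tables into the run directory and the run ends with
a machine-readable ``manifest.json`` of output checksums and the
stage-wise feature counts.  Outputs are a pure function of (inputs,
config, seed): re-running an identical configuration reproduces every
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna, differential, enrichment, promoters, survival
from . import io as io_formats

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_all"]

REQUIRED_INPUTS = (
    "lncrna_annotation", "gene_annotation", "probes", "methylation",
    "lncrna_expression", "mrna_expression", "samples", "mirna_lncrna",
    "mirna_mrna", "clinical", "term_gene", "go_isa", "disease_mirna",
)

_RANGES = {
    "q_threshold": (0.0, 1.0), "delta_threshold": (0.0, 1.0),
    "pcc_p": (0.0, 1.0), "hyper_p": (0.0, 1.0), "fdr": (0.0, 1.0),
    "disease_p": (0.0, 1.0), "max_missing_frac": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Paths to every input plus all stage thresholds."""

    inputs: dict[str, str]
    outdir: str = "lncmeth_run"
    q_threshold: float = 0.05
    delta_threshold: float = 0.1
    fc_up: float = 2.0
    fc_down: float = 0.5
    pcc_p: float = 0.01
    min_shared: int = 2
    hyper_p: float = 0.01
    hub_threshold: int = 5
    fdr: float = 0.05
    disease_p: float = 0.05
    b_permutations: int = 1000
    seed: int = 0
    promoter_window: int = 2000
    max_missing_frac: float = 0.30
    max_distance: int = 1_000_000
    sample_scope: str = "tumor"  # correlation scope: "tumor" or "all"

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_INPUTS if k not in self.inputs]
        if missing:
            raise ValueError(f"missing input path(s): {missing}")
        for key, (lo, hi) in _RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"{key}={v} outside [{lo}, {hi}]")
        if self.fc_up <= 1 or not 0 < self.fc_down < 1:
            raise ValueError("fold-change thresholds must satisfy fc_up > 1, 0 < fc_down < 1")
        if self.min_shared < 1 or self.hub_threshold < 1:
            raise ValueError("min_shared and hub_threshold must be >= 1")
        if self.sample_scope not in {"tumor", "all"}:
            raise ValueError("sample_scope must be 'tumor' or 'all'")
        if not (self.b_permutations == "exact" or self.b_permutations >= 1):
            raise ValueError("b_permutations must be >= 1 or 'exact'")


def validate_config(path) -> PipelineConfig:
    """Parse a YAML config file, inject defaults, range-check and verify
    the referenced input files exist."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    base = path.parent
    resolved = {}
    for key, p in cfg.inputs.items():
        candidate = Path(p)
        if not candidate.is_absolute():
            candidate = base / candidate
        if not candidate.exists():
            raise FileNotFoundError(f"config input {key!r}: no such file {candidate}")
        resolved[key] = str(candidate)
    cfg.inputs = resolved
    for f in dataclasses.fields(PipelineConfig):
        if f.name not in raw and f.name != "inputs":
            logger.info("config: %s defaulted to %r", f.name, getattr(cfg, f.name))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name; partial outputs stay
    in the run directory for inspection.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}
    stage = "load"
    try:
        inputs = config.inputs
        lnc_ann = io_formats.read_annotation(inputs["lncrna_annotation"])
        gene_ann = io_formats.read_annotation(inputs["gene_annotation"])
        manifest = io_formats.read_probe_manifest(inputs["probes"])
        betas = io_formats.read_matrix(inputs["methylation"])
        lnc_expr = io_formats.read_matrix(inputs["lncrna_expression"])
        mrna_expr = io_formats.read_matrix(inputs["mrna_expression"])
        groups = io_formats.read_sample_groups(inputs["samples"])
        lnc_mirna = io_formats.read_interactions(inputs["mirna_lncrna"])
        mrna_mirna = io_formats.read_interactions(inputs["mirna_mrna"])
        clinical = io_formats.read_clinical(inputs["clinical"])
        term_table = io_formats.read_term_table(inputs["term_gene"], "term_id", "gene")
        is_a = io_formats.read_edge_table(inputs["go_isa"])
        disease_table = io_formats.read_term_table(inputs["disease_mirna"], "disease", "mirna_id")

        tumor = [s for s in betas.columns if groups.get(s) == "tumor"]
        normal = [s for s in betas.columns if groups.get(s) == "normal"]

        stage = "promoter_meth"
        betas_f = promoters.filter_and_impute(betas, config.max_missing_frac)
        proms = promoters.map_probes(
            promoters.define_promoters(lnc_ann, config.promoter_window), manifest
        )
        io_formats.write_promoters_bed(proms, outdir / "promoters.bed")
        profile = promoters.promoter_level(betas_f, proms)
        _write(profile, outdir / "promoter_methylation.tsv")
        ks_d, ks_p = promoters.ks_compare(
            profile[tumor].mean(axis=1), profile[normal].mean(axis=1)
        )
        counts["n_probes_kept"] = int(len(betas_f))
        counts["n_lncrnas_with_promoter_probes"] = int(len(profile))
        counts["ks_statistic"] = ks_d
        counts["ks_p"] = ks_p
        logger.info("promoter_meth: %d lncRNAs profiled, K-S D=%.4f p=%.3g",
                    len(profile), ks_d, ks_p)

        stage = "differential"
        b = config.b_permutations
        sam_meth = differential.sam_qvalues(profile, groups, b=b, seed=config.seed)
        sam_lnc = differential.sam_qvalues(lnc_expr, groups, b=b, seed=config.seed + 1,
                                           log2_stat=True)
        sam_mrna = differential.sam_qvalues(mrna_expr, groups, b=b, seed=config.seed + 2,
                                            log2_stat=True)
        dml = differential.call_dml(sam_meth, config.q_threshold, config.delta_threshold)
        dels = differential.call_del(sam_lnc, config.q_threshold)
        degs = differential.call_deg(sam_mrna, config.q_threshold, config.fc_up, config.fc_down)
        _write(dml, outdir / "dml.tsv", index_label="feature_id")
        _write(dels, outdir / "del.tsv", index_label="feature_id")
        _write(degs, outdir / "deg.tsv", index_label="feature_id")
        classes = differential.classify(dml, dels)
        _write(classes, outdir / "classification.tsv")
        counts["n_dml"] = int((dml["call"] != "none").sum())
        counts["n_del"] = int((dels["call"] != "none").sum())
        counts["n_deg"] = int((degs["call"] != "none").sum())
        grouped = classes[classes["group"] != "unclassified"]
        counts["n_classified"] = int(len(grouped))
        counts["n_hmlnc"] = int((grouped["methylation"] == "high").sum())
        counts["n_lmlnc"] = int((grouped["methylation"] == "low").sum())
        counts["group_sizes"] = {
            g: int((grouped["group"] == g).sum()) for g in differential.FOUR_GROUPS
        }
        logger.info("differential: %d DML, %d DEL, %d DEG, %d classified",
                    counts["n_dml"], counts["n_del"], counts["n_deg"], len(grouped))

        stage = "cerna"
        scope = tumor if config.sample_scope == "tumor" else list(lnc_expr.columns)
        scope = [s for s in scope if s in lnc_expr.columns and s in mrna_expr.columns]
        del_ids = sorted(dels.index[dels["call"] != "none"])
        deg_ids = sorted(degs.index[degs["call"] != "none"])
        # correlations on log2(x+1) expression: variance-stabilized scale
        background = cerna.build_background(
            del_ids, deg_ids, np.log2(lnc_expr[scope] + 1.0), np.log2(mrna_expr[scope] + 1.0),
            lnc_mirna, mrna_mirna,
            min_shared=config.min_shared, pcc_p=config.pcc_p, hyper_p=config.hyper_p,
        )
        io_formats.write_network(background, outdir / "background_network.tsv")
        counts["background_edges"] = background.number_of_edges()
        subnets: dict[str, object] = {}
        summary_rows = []
        for grp in differential.FOUR_GROUPS:
            seeds = sorted(grouped.index[grouped["group"] == grp])
            sub = cerna.extract_subnetwork(background, seeds)
            subnets[grp] = sub
            s = cerna.summarize(sub)
            summary_rows.append(
                {"group": grp, "lncRNAs": s.n_lncrnas, "miRNAs": s.n_mirnas,
                 "mRNAs": s.n_mrnas, "interaction_pairs": s.n_edges,
                 "mean_lncrna_degree": round(s.mean_lncrna_degree, 3)}
            )
            io_formats.write_network(sub, outdir / f"subnetwork_{grp}.tsv")
            io_formats.write_network(sub, outdir / f"subnetwork_{grp}.sif", fmt="sif")
        network_summary = pd.DataFrame(summary_rows).set_index("group")
        _write(network_summary, outdir / "network_summary.tsv")
        counts["network_summary"] = {
            r["group"]: {k: v for k, v in r.items() if k != "group"} for r in summary_rows
        }
        logger.info("cerna: background %d edges; per-group sizes %s",
                    background.number_of_edges(),
                    {r["group"]: r["interaction_pairs"] for r in summary_rows})

        stage = "enrichment"
        universe = [g.feature_id for g in gene_ann]
        cis_map = enrichment.nearest_gene(lnc_ann, gene_ann, config.max_distance)
        pd.Series(cis_map, name="nearest_gene").rename_axis("lncrna_id").to_csv(
            outdir / "cis_nearest_gene.tsv", sep="\t"
        )
        enr_frames = []
        for label, lnc_set in (("HMLnc", grouped.index[grouped["methylation"] == "high"]),
                               ("LMLnc", grouped.index[grouped["methylation"] == "low"])):
            genes = sorted({cis_map[l] for l in lnc_set if cis_map.get(l)})
            res = enrichment.enrich(genes, term_table.rename(
                columns={"term_id": "term_id", "term_name": "term_name", "gene": "gene"}),
                universe, config.fdr)
            sig = [r.term_id for r in res if r.fdr <= config.fdr]
            graph, comps = enrichment.build_term_graph(sig, is_a)
            enr_frames.append(_enrichment_frame(label + "_cis", res))
            counts[f"{label.lower()}_cis_terms"] = len(sig)
            counts[f"{label.lower()}_term_components"] = [len(c) for c in comps]
        mirna_of_lnc = cerna.mirna_sets(lnc_mirna)
        for grp in differential.FOUR_GROUPS:
            sub = subnets[grp]
            mrnas = sorted(n for n in sub if sub.nodes[n].get("kind") == "mrna")
            res = enrichment.enrich(mrnas, term_table, universe, config.fdr)
            enr_frames.append(_enrichment_frame(f"{grp}_network", res))
            freq = enrichment.gene_term_frequency(res, config.fdr)
            freq.to_csv(outdir / f"gene_term_frequency_{grp}.tsv", sep="\t")
            seeds = sorted(grouped.index[grouped["group"] == grp])
            mirnas = sorted(set().union(*(mirna_of_lnc.get(l, set()) for l in seeds))
                            if seeds else set())
            dres = enrichment.mirna_disease_enrich(mirnas, disease_table, config.disease_p)
            enr_frames.append(_enrichment_frame(f"{grp}_mirna_disease", dres))
            counts[f"{grp}_significant_terms"] = sum(r.fdr <= config.fdr for r in res)
            counts[f"{grp}_significant_diseases"] = sum(r.p < config.disease_p for r in dres)
        _write(pd.concat(enr_frames, ignore_index=True), outdir / "enrichment.tsv", index=False)

        stage = "survival"
        expr_model = np.log2(mrna_expr + 1.0)
        surv_rows = []
        for grp in differential.FOUR_GROUPS:
            _, hubs, _ = cerna.degrees_and_hubs(subnets[grp], config.hub_threshold)
            if not hubs:
                logger.info("survival: %s has no hub mRNAs; module skipped", grp)
                surv_rows.append({"group": grp, "n_hubs": 0, "chi2": np.nan,
                                  "logrank_p": np.nan, "note": "no hub mRNAs"})
                continue
            model = survival.module_survival(hubs, expr_model, clinical)
            risk = pd.DataFrame({"pi": model.pi, "risk_group": model.risk_group})
            risk.index.name = "sample"
            _write(risk, outdir / f"risk_table_{grp}.tsv")
            model.beta.to_csv(outdir / f"cox_beta_{grp}.tsv", sep="\t", header=["beta"])
            surv_rows.append({"group": grp, "n_hubs": len(hubs), "chi2": round(model.chi2, 6),
                              "logrank_p": model.p, "note": ""})
            logger.info("survival: %s module (%d hubs) log-rank p=%.4g",
                        grp, len(hubs), model.p)
        surv_summary = pd.DataFrame(surv_rows).set_index("group")
        _write(surv_summary, outdir / "survival_summary.tsv")
        counts["survival"] = {
            r["group"]: {"n_hubs": r["n_hubs"],
                         "logrank_p": None if pd.isna(r["logrank_p"]) else r["logrank_p"]}
            for r in surv_rows
        }
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); partial outputs in {outdir}"
        ) from exc

    manifest_doc = {
        "counts": counts,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest_doc, indent=2, sort_keys=True, default=str) + "\n"
    )
    return outdir


def _enrichment_frame(label: str, results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"analysis": label, "term_id": r.term_id, "term_name": r.term_name,
             "N": r.universe, "M": r.annotated, "n": r.query, "m": r.overlap,
             "p": r.p, "fdr": r.fdr}
            for r in results
        ],
        columns=["analysis", "term_id", "term_name", "N", "M", "n", "m", "p", "fdr"],
    )
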