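import dataclasses

import numpy as np
import pandas as pd
import pytest

from lncmeth import io as io_formats
from lncmeth.promoters import define_promoters, map_probes
from lncmeth.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_annotation,
    simulate_clinical,
    simulate_expression,
    simulate_interactions,
    simulate_methylation,
    write_dataset,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_lnc=0),
            dict(delta_beta=1.2),
            dict(delta_beta=0.0),
            dict(censor_rate=1.0),
            dict(missing_rate=1.0),
            dict(cerna_rho=0.0),
            dict(n_lnc=30),  # planted (80) exceed n_lnc
            dict(n_gene=50),  # partner demand exceeds genes
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **kwargs)

    def test_planted_counts_sum(self):
        cfg = SimulationConfig(seed=1)
        assert cfg.n_planted == 80
        assert sum(cfg.planted_counts.values()) == 80


class TestDeterminismAndStreams:
    def test_fixed_seed_reproduces_every_modality(self, small_config):
        a = simulate_all(small_config)
        b = simulate_all(dataclasses.replace(small_config))
        pd.testing.assert_frame_equal(a.betas, b.betas)
        pd.testing.assert_frame_equal(a.lnc_expr, b.lnc_expr)
        pd.testing.assert_frame_equal(a.mrna_expr, b.mrna_expr)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_series_equal(a.truth.classes, b.truth.classes)
        assert a.truth.pairs == b.truth.pairs

    def test_written_dataset_byte_identical(self, small_config, tmp_path):
        ds = simulate_all(small_config)
        write_dataset(ds, tmp_path / "one")
        write_dataset(simulate_all(small_config), tmp_path / "two")
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes(), f.name

    def test_probe_count_does_not_perturb_expression_stream(self, small_config):
        a = simulate_all(small_config)
        b = simulate_all(dataclasses.replace(small_config, n_probe=50))
        pd.testing.assert_frame_equal(a.lnc_expr, b.lnc_expr)


class TestAnnotation:
    def test_most_lncrnas_have_promoter_probes_and_some_probes_outside(self, small_config):
        lnc, _, manifest = simulate_annotation(small_config)
        proms = map_probes(define_promoters(lnc), manifest)
        covered = sum(1 for p in proms if p.probe_ids) / len(proms)
        assert covered >= 0.85
        inside = set().union(*(set(p.probe_ids) for p in proms))
        assert len(inside) < len(manifest)  # some probes fall outside promoters

    def test_zero_probes_supported(self, small_config):
        cfg = dataclasses.replace(small_config, n_probe=0)
        lnc, _, manifest = simulate_annotation(cfg)
        assert manifest.empty
        proms = map_probes(define_promoters(lnc), manifest)
        assert all(not p.probe_ids for p in proms)

    def test_strand_promoter_convention_on_generated_records(self, small_config):
        lnc, _, _ = simulate_annotation(small_config)
        for rec in lnc:
            (prom,) = define_promoters([rec])
            if rec.strand == "+":
                assert (prom.start, prom.end) == (rec.tss - 2000, rec.tss)
            else:
                assert (prom.start, prom.end) == (rec.tss, rec.tss + 2000)


class TestMethylation:
    def test_values_in_unit_interval(self, small_dataset):
        vals = small_dataset.betas.to_numpy()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_missing_rate_close_to_configured(self, small_dataset, small_config):
        frac = float(small_dataset.betas.isna().mean().mean())
        assert frac == pytest.approx(small_config.missing_rate, abs=0.01)

    def test_planted_shift_recovered_within_monte_carlo_error(self, default_dataset):
        ds = default_dataset
        cfg = ds.config
        proms = {p.lncrna_id: p for p in
                 map_probes(define_promoters(ds.lnc_annotation), ds.manifest)}
        tumor, normal = cfg.tumor_samples, cfg.normal_samples
        for direction, sign in (("high", +1), ("low", -1)):
            classes = [c for c in ("high-up", "high-down", "low-up", "low-down")
                       if c.startswith(direction)]
            probes: list[str] = []
            for cls in classes:
                for lnc in ds.truth.lncrnas_of(cls):
                    probes.extend(proms[lnc].probe_ids)
            assert len(probes) >= 50
            sub = ds.betas.loc[sorted(set(probes))]
            diff = float(np.nanmean(sub[tumor].to_numpy())
                         - np.nanmean(sub[normal].to_numpy()))
            assert diff == pytest.approx(sign * cfg.delta_beta, abs=0.03)

    def test_null_promoters_have_no_shift(self, default_dataset):
        ds = default_dataset
        cfg = ds.config
        proms = {p.lncrna_id: p for p in
                 map_probes(define_promoters(ds.lnc_annotation), ds.manifest)}
        probes = []
        for lnc in ds.truth.classes.index[ds.truth.classes == "null"]:
            probes.extend(proms[lnc].probe_ids)
        sub = ds.betas.loc[sorted(set(probes))]
        diff = float(np.nanmean(sub[cfg.tumor_samples].to_numpy())
                     - np.nanmean(sub[cfg.normal_samples].to_numpy()))
        assert abs(diff) < 0.02


class TestExpression:
    def test_planted_down_fold_change_at_most_half(self, default_dataset):
        ds = default_dataset
        cfg = ds.config
        fc = []
        for cls in ("high-down", "low-down"):
            for lnc in ds.truth.lncrnas_of(cls):
                row = ds.lnc_expr.loc[lnc]
                fc.append(row[cfg.tumor_samples].mean() / row[cfg.normal_samples].mean())
        assert np.mean(fc) <= 0.5

    def test_true_pairs_positively_correlated_in_tumor(self, default_dataset):
        ds = default_dataset
        tumor = ds.config.tumor_samples
        lx = np.log2(ds.lnc_expr[tumor] + 1)
        mx = np.log2(ds.mrna_expr[tumor] + 1)
        rhos = [np.corrcoef(lx.loc[l], mx.loc[m])[0, 1] for l, m in ds.truth.pairs]
        assert np.mean(np.array(rhos) > 0) > 0.99
        assert np.median(rhos) == pytest.approx(ds.config.cerna_rho, abs=0.12)

    def test_zero_effect_leaves_planted_and_null_exchangeable(self, small_config):
        import dataclasses as dc

        cfg = dc.replace(small_config, expr_effect=1e-12)
        ds = simulate_all(cfg)
        planted = ds.truth.classes[ds.truth.classes != "null"].index
        nulls = ds.truth.classes[ds.truth.classes == "null"].index
        lp = np.log2(ds.lnc_expr.loc[planted, cfg.tumor_samples] + 1).mean(axis=1)
        ln = np.log2(ds.lnc_expr.loc[nulls, cfg.tumor_samples] + 1).mean(axis=1)
        assert abs(lp.mean() - ln.mean()) < 1.0  # same baseline distribution


class TestInteractions:
    def test_true_pairs_share_at_least_overlap_mirnas(self, small_dataset):
        ds = small_dataset
        lnc_sets = ds.lnc_mirna.groupby("target_id")["mirna_id"].apply(set)
        mrna_sets = ds.mrna_mirna.groupby("target_id")["mirna_id"].apply(set)
        for l, m in ds.truth.pairs:
            assert len(lnc_sets[l] & mrna_sets[m]) >= ds.config.cerna_overlap

    def test_tables_deduplicated(self, small_dataset):
        for t in (small_dataset.lnc_mirna, small_dataset.mrna_mirna):
            assert not t.duplicated().any()


class TestClinical:
    def test_no_censoring_gives_all_events(self, small_config):
        cfg = dataclasses.replace(small_config, censor_rate=0.0)
        ds = simulate_all(cfg)
        assert (ds.clinical["event"] == 1).all()

    def test_censor_rate_achieved_in_expectation(self, default_dataset):
        frac = 1 - default_dataset.clinical["event"].mean()
        assert frac == pytest.approx(default_dataset.config.censor_rate, abs=0.12)

    def test_times_positive_and_tumor_only(self, small_dataset):
        c = small_dataset.clinical
        assert (c["time"] > 0).all()
        assert set(c["sample"]) == set(small_dataset.config.tumor_samples)


class TestRoundTrip:
    def test_written_files_load_back_through_io_readers(self, small_dataset, tmp_path):
        ds = small_dataset
        write_dataset(ds, tmp_path)
        lnc = io_formats.read_annotation(tmp_path / "lncrna_annotation.gtf")
        assert len(lnc) == len(ds.lnc_annotation)
        rec = {r.feature_id: r for r in lnc}
        for orig in ds.lnc_annotation:
            got = rec[orig.feature_id]
            assert (got.start, got.end, got.strand) == (orig.start, orig.end, orig.strand)
        betas = io_formats.read_matrix(tmp_path / "methylation_beta.tsv")
        pd.testing.assert_frame_equal(betas, ds.betas, check_names=False)
        inter = io_formats.read_interactions(tmp_path / "mirna_lncrna.tsv")
        assert len(inter) == len(ds.lnc_mirna)
        clin = io_formats.read_clinical(tmp_path / "clinical.tsv")
        assert len(clin) == len(ds.clinical)
        groups = io_formats.read_sample_groups(tmp_path / "samples.tsv")
        pd.testing.assert_series_equal(groups, ds.sample_groups)
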