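from itertools import combinations
from math import gamma

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from lncmeth.cerna import (
    build_background,
    degrees_and_hubs,
    extract_subnetwork,
    mirna_sets,
    pearson,
    pearson_pvalue,
    shared_mirna_test,
    summarize,
)


class TestPearson:
    def test_affine_relation_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_longhand_product_moment_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        assert num / den == pytest.approx(0.8)
        assert pearson(x, y) == pytest.approx(num / den)

    def test_two_formula_equivalence_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            cov_form = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
            assert abs(pearson(x, y) - cov_form) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])


class TestPearsonPvalue:
    def test_zero_correlation_gives_one(self):
        assert pearson_pvalue(0.0, 25) == pytest.approx(1.0)

    def test_monotone_decreasing_in_abs_rho(self):
        ps = [pearson_pvalue(r, 30) for r in (0.1, 0.3, 0.5, 0.7, 0.9, 0.999)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert pearson_pvalue(-0.5, 30) == pytest.approx(pearson_pvalue(0.5, 30))

    def test_matches_t_density_quadrature(self):
        rho, n = 0.5, 30
        nu = n - 2
        t = rho * np.sqrt(nu / (1 - rho**2))

        def t_pdf(u):
            c = gamma((nu + 1) / 2) / (np.sqrt(nu * np.pi) * gamma(nu / 2))
            return c * (1 + u * u / nu) ** (-(nu + 1) / 2)

        tail, _ = quad(t_pdf, t, np.inf)
        assert pearson_pvalue(rho, n) == pytest.approx(2 * tail, rel=1e-8)


def hypergeom_tail_by_enumeration(m, big_m, n, big_n):
    """Tail P(overlap >= m) by enumerating every n-subset of the universe."""
    universe = range(big_n)
    annotated = set(range(big_m))
    draws = list(combinations(universe, n))
    hits = sum(1 for d in draws if len(annotated & set(d)) >= m)
    return hits / len(draws)


class TestSharedMirnaTest:
    def test_zero_overlap_gives_one(self):
        assert shared_mirna_test(0, 5, 3, 20) == 1.0

    def test_small_case_enumeration(self):
        assert shared_mirna_test(2, 2, 2, 4) == pytest.approx(1 / 6)
        assert shared_mirna_test(2, 2, 2, 4) == pytest.approx(
            hypergeom_tail_by_enumeration(2, 2, 2, 4)
        )

    def test_full_overlap_universe(self):
        assert shared_mirna_test(3, 5, 3, 5) == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            shared_mirna_test(4, 3, 3, 10)

    def test_non_increasing_in_overlap(self):
        ps = [shared_mirna_test(m, 6, 5, 30) for m in range(6)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _fixture_tables():
    """5 lncRNAs x 8 mRNAs with hand-built miRNA overlaps.

    The universe is kept sparse (100 miRNAs, background degree 3) so a
    forced 3-miRNA overlap is hypergeometrically significant.
    """
    rng = np.random.default_rng(99)
    mirnas = [f"m{i}" for i in range(100)]
    lncs = [f"L{i}" for i in range(5)]
    mrnas = [f"G{i}" for i in range(8)]
    lnc_rows, mrna_rows = [], []
    for i, l in enumerate(lncs):
        for m in rng.choice(mirnas, size=3, replace=False):
            lnc_rows.append((m, l))
    for j, g in enumerate(mrnas):
        for m in rng.choice(mirnas, size=3, replace=False):
            mrna_rows.append((m, g))
    for m in mirnas:  # every miRNA appears so the universe is the full set
        mrna_rows.append((m, "G7"))
    # force a strong overlap for (L0, G0)
    for m in ("m0", "m1", "m2"):
        lnc_rows.append((m, "L0"))
        mrna_rows.append((m, "G0"))
    lnc_t = pd.DataFrame(lnc_rows, columns=["mirna_id", "target_id"]).drop_duplicates()
    mrna_t = pd.DataFrame(mrna_rows, columns=["mirna_id", "target_id"]).drop_duplicates()
    n = 30
    lx = pd.DataFrame(rng.normal(5, 1, size=(5, n)), index=lncs,
                      columns=[f"s{k}" for k in range(n)])
    mx = pd.DataFrame(rng.normal(5, 1, size=(8, n)), index=mrnas,
                      columns=[f"s{k}" for k in range(n)])
    # couple (L0, G0) strongly and (L1, G1) negatively
    mx.loc["G0"] = 0.9 * lx.loc["L0"] + 0.1 * mx.loc["G0"]
    mx.loc["G1"] = -lx.loc["L1"]
    return lncs, mrnas, lx, mx, lnc_t, mrna_t


def brute_force_background(lncs, mrnas, lx, mx, lnc_t, mrna_t,
                           min_shared=2, pcc_p=0.01, hyper_p=0.01):
    """Independent double loop applying all four edge criteria."""
    from scipy import stats

    lsets = mirna_sets(lnc_t)
    msets = mirna_sets(mrna_t)
    universe = set(lnc_t["mirna_id"]) | set(mrna_t["mirna_id"])
    edges = set()
    for l in lncs:
        for g in mrnas:
            shared = lsets.get(l, set()) & msets.get(g, set())
            r, p = stats.pearsonr(lx.loc[l], mx.loc[g])
            if r > 0 and p <= pcc_p and len(shared) >= min_shared:
                hp = stats.hypergeom.sf(len(shared) - 1, len(universe),
                                        len(lsets[l]), len(msets[g]))
                if hp <= hyper_p:
                    edges.add((l, g))
    return edges


class TestBuildBackground:
    def test_equals_brute_force_double_loop(self):
        lncs, mrnas, lx, mx, lnc_t, mrna_t = _fixture_tables()
        g = build_background(lncs, mrnas, lx, mx, lnc_t, mrna_t)
        got = {(u, v) if g.nodes[u]["kind"] == "lncrna" else (v, u) for u, v in g.edges()}
        assert got == brute_force_background(lncs, mrnas, lx, mx, lnc_t, mrna_t)
        assert ("L0", "G0") in got

    def test_single_shared_mirna_excluded_at_min_shared_two(self):
        rng = np.random.default_rng(1)
        lnc_t = pd.DataFrame({"mirna_id": ["m0"], "target_id": ["L"]})
        mrna_t = pd.DataFrame({"mirna_id": ["m0", "m1"], "target_id": ["G", "G"]})
        x = rng.normal(size=20)
        lx = pd.DataFrame([x], index=["L"], columns=[f"s{i}" for i in range(20)])
        mx = pd.DataFrame([x + rng.normal(0, 0.01, 20)], index=["G"], columns=lx.columns)
        g = build_background(["L"], ["G"], lx, mx, lnc_t, mrna_t, min_shared=2)
        assert g.number_of_edges() == 0
        g1 = build_background(["L"], ["G"], lx, mx, lnc_t, mrna_t, min_shared=1,
                              hyper_p=1.0)
        assert g1.number_of_edges() == 1

    def test_anticorrelated_pair_excluded(self):
        lncs, mrnas, lx, mx, lnc_t, mrna_t = _fixture_tables()
        for m in ("m0", "m1", "m2"):  # give (L1, G1) a strong miRNA overlap too
            lnc_t = pd.concat([lnc_t, pd.DataFrame({"mirna_id": [m], "target_id": ["L1"]})])
            mrna_t = pd.concat([mrna_t, pd.DataFrame({"mirna_id": [m], "target_id": ["G1"]})])
        g = build_background(lncs, mrnas, lx, mx, lnc_t, mrna_t)
        assert not g.has_edge("L1", "G1")

    def test_threshold_monotonicity(self):
        lncs, mrnas, lx, mx, lnc_t, mrna_t = _fixture_tables()
        strict = build_background(lncs, mrnas, lx, mx, lnc_t, mrna_t)
        for kw in ({"pcc_p": 0.1}, {"hyper_p": 0.1}, {"min_shared": 1}):
            loose = build_background(lncs, mrnas, lx, mx, lnc_t, mrna_t, **kw)
            assert set(strict.edges()) <= set(loose.edges())

    def test_empty_interactions_warns_and_gives_empty_network(self):
        empty = pd.DataFrame(columns=["mirna_id", "target_id"])
        lx = pd.DataFrame(np.ones((1, 5)), index=["L"], columns=list("abcde"))
        with pytest.warns(UserWarning, match="empty"):
            g = build_background(["L"], ["G"], lx, lx.rename(index={"L": "G"}),
                                 empty, empty)
        assert g.number_of_nodes() == 0

    def test_mismatched_sample_order_rejected(self):
        lx = pd.DataFrame(np.ones((1, 3)), index=["L"], columns=list("abc"))
        mx = pd.DataFrame(np.ones((1, 3)), index=["G"], columns=list("acb"))
        t = pd.DataFrame({"mirna_id": ["m"], "target_id": ["L"]})
        with pytest.raises(ValueError, match="sample order"):
            build_background(["L"], ["G"], lx, mx, t, t)


def _star(n_mrnas, lnc="L0"):
    g = nx.Graph()
    g.add_node(lnc, kind="lncrna")
    for i in range(n_mrnas):
        g.add_node(f"G{i}", kind="mrna")
        g.add_edge(lnc, f"G{i}", pcc=0.5, pcc_p=0.001, shared=2, hyper_p=0.005)
    return g


class TestSubnetworksAndHubs:
    def test_seed_without_edges_stays_isolated(self):
        sub = extract_subnetwork(_star(3), ["L9"])
        assert set(sub.nodes) == {"L9"} and sub.number_of_edges() == 0

    def test_star_subnetwork(self):
        sub = extract_subnetwork(_star(3), ["L0"])
        assert sub.number_of_nodes() == 4 and sub.number_of_edges() == 3

    def test_subnetwork_edges_subset_of_background(self, small_dataset):
        # any seed choice: induced edges never leave the background
        bg = _star(6)
        bg.add_node("L1", kind="lncrna")
        bg.add_edge("L1", "G0", pcc=0.4, pcc_p=0.002, shared=3, hyper_p=0.001)
        for seeds in (["L0"], ["L1"], ["L0", "L1"]):
            sub = extract_subnetwork(bg, seeds)
            assert {frozenset(e) for e in sub.edges()} <= {
                frozenset(e) for e in bg.edges()
            }

    def test_star_has_no_hub_mrnas(self):
        degrees, hubs, mean_deg = degrees_and_hubs(_star(6))
        assert hubs == [] and degrees["L0"] == 6 and mean_deg == 6.0

    def test_mrna_with_five_lncrnas_is_hub(self):
        g = nx.Graph()
        g.add_node("G", kind="mrna")
        for i in range(5):
            g.add_node(f"L{i}", kind="lncrna")
            g.add_edge(f"L{i}", "G")
        _, hubs, _ = degrees_and_hubs(g)
        assert hubs == ["G"]

    def test_degrees_match_brute_force_incidence_count(self, rng):
        g = nx.Graph()
        for i in range(8):
            g.add_node(f"L{i}", kind="lncrna")
        for j in range(12):
            g.add_node(f"G{j}", kind="mrna")
        for i in range(8):
            for j in range(12):
                if rng.random() < 0.3:
                    g.add_edge(f"L{i}", f"G{j}")
        degrees, _, mean_deg = degrees_and_hubs(g)
        for node in g:
            assert degrees[node] == sum(1 for _ in g.edges(node))
        assert mean_deg == pytest.approx(g.number_of_edges() / 8)

    def test_summary_counts(self):
        g = _star(3)
        s = summarize(g)
        assert (s.n_lncrnas, s.n_mrnas, s.n_edges) == (1, 3, 3)
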