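"""Pathway rewiring: eigenvector weights, MST wiring, permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coexrewire.compendium import Pathway
from coexrewire.datamodel import AnalysisConfig
from coexrewire.rewiring import (
    classify_dissolution,
    gsnca_test,
    weight_vector,
    wiring_network,
)
from conftest import make_dataset


def corr_df(values, genes=None):
    a = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=genes, columns=genes)


class TestWeightVector:
    def test_uniform_offdiagonal_gives_uniform_weights(self):
        a = np.full((6, 6), 0.4)
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(weight_vector(a), np.ones(6), atol=1e-9)

    def test_scale_invariance(self, rng):
        # scaling every off-diagonal |r| by c > 0 leaves the weights unchanged
        r = rng.uniform(0.1, 0.9, (5, 5))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        scaled = 0.5 * r
        np.fill_diagonal(scaled, 1.0)
        np.testing.assert_allclose(weight_vector(r), weight_vector(scaled),
                                   atol=1e-8)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_eigendecomposition(self, rng, trial):
        p = rng.integers(3, 12)
        r = rng.uniform(-1, 1, (p, p))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        w = weight_vector(r)
        a = np.abs(r).astype(float)
        np.fill_diagonal(a, 0.0)
        vals, vecs = np.linalg.eigh(a)
        dom = np.abs(vecs[:, np.argmax(vals)])
        oracle = dom * (p / dom.sum())
        np.testing.assert_allclose(w, oracle, atol=1e-8)
        assert w.sum() == pytest.approx(p)

    def test_three_gene_example(self):
        r = corr_df([[1.0, 0.9, 0.5], [0.9, 1.0, 0.1], [0.5, 0.1, 1.0]])
        w = weight_vector(r)
        a = np.array([[0, 0.9, 0.5], [0.9, 0, 0.1], [0.5, 0.1, 0]])
        vals, vecs = np.linalg.eigh(a)
        oracle = np.abs(vecs[:, -1])
        oracle *= 3 / oracle.sum()
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_all_zero_matrix_uniform_with_warning(self, caplog):
        a = np.eye(4)
        with caplog.at_level("WARNING"):
            w = weight_vector(a)
        np.testing.assert_allclose(w, 1.0)


def _tree_weight(edges, dist):
    return sum(dist[e] for e in edges)


def _enumerate_msts(genes, dist):
    """Brute-force minimum spanning tree(s) over the complete graph."""
    all_edges = list(itertools.combinations(genes, 2))
    n = len(genes)
    best, best_w = None, np.inf
    for cand in itertools.combinations(all_edges, n - 1):
        # spanning check by union-find
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        ok = True
        for u, v in cand:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if not ok:
            continue
        w = _tree_weight(cand, dist)
        if w < best_w - 1e-12:
            best, best_w = cand, w
    return set(best), best_w


class TestWiringNetwork:
    def test_mst_properties(self, rng):
        p = 7
        r = rng.uniform(-0.9, 0.9, (p, p))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        edges = wiring_network(corr_df(r))
        assert len(edges) == 2 * (p - 1)
        nodes = {g for u, v, _ in edges for g in (u, v)}
        assert len(nodes) == p

    @pytest.mark.parametrize("trial", range(4))
    def test_union_matches_enumeration(self, rng, trial):
        p = rng.integers(4, 6)
        genes = [f"G{i}" for i in range(p)]
        r = rng.uniform(0.05, 0.95, (p, p))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        dist = {tuple(sorted((genes[i], genes[j]))): 1 - abs(r[i, j])
                for i in range(p) for j in range(i + 1, p)}
        edges = wiring_network(corr_df(r, genes))
        mst1_edges = {tuple(sorted((u, v))) for u, v, _ in edges[:p - 1]}
        oracle1, w1 = _enumerate_msts(genes, dist)
        assert _tree_weight(mst1_edges, dist) == pytest.approx(w1)
        # second tree: minimum spanning tree of the remainder graph
        mst2_edges = {tuple(sorted((u, v))) for u, v, _ in edges[p - 1:]}
        assert mst1_edges.isdisjoint(mst2_edges)
        assert len(mst2_edges) == p - 1

    def test_equal_distances_deterministic(self):
        r = np.full((5, 5), 0.5)
        np.fill_diagonal(r, 1.0)
        e1 = wiring_network(corr_df(r))
        e2 = wiring_network(corr_df(r))
        assert e1 == e2

    def test_three_genes_returns_single_tree(self, caplog):
        r = corr_df([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        with caplog.at_level("WARNING"):
            edges = wiring_network(r)
        assert len(edges) == 2


class TestGsncaTest:
    def test_identical_conditions_give_zero_distance_p_one(self, rng, fast_cfg):
        block = rng.standard_normal((6, 10))
        ds = make_dataset(np.hstack([block, block]), 10, 10)
        pw = Pathway("pw", "syn", frozenset(ds.genes))
        res = gsnca_test(ds, pw, fast_cfg)
        assert res.d_obs == pytest.approx(0.0, abs=1e-9)
        assert res.p == 1.0
        assert res.hub1 == res.hub2

    def test_p_floor_attained_for_extreme_statistic(self, rng):
        from coexrewire.synthdata import SynthConfig, generate
        ds, pws, _ = generate(SynthConfig(
            n_pathways=1, n_background_genes=0,
            rho_within={"att": (0.9, 0.0)}, samples_per_condition=60,
            rng_seed=5))
        cfg = AnalysisConfig(n_perm_gsnca=50, rng_seed=1)
        res = gsnca_test(ds, pws[0], cfg)
        assert res.p == pytest.approx(1 / 51)

    def test_weights_sum_to_pathway_size(self, rng, fast_cfg):
        ds = make_dataset(rng.standard_normal((8, 16)), 8, 8)
        pw = Pathway("pw", "syn", frozenset(ds.genes[:5]))
        res = gsnca_test(ds, pw, fast_cfg)
        assert res.weights1.sum() == pytest.approx(5)
        assert res.weights2.sum() == pytest.approx(5)
        assert res.d_obs == pytest.approx(
            float(np.abs(res.weights1 - res.weights2).sum()))

    def test_skips_when_too_few_usable_genes(self, rng, fast_cfg):
        arr = rng.standard_normal((4, 12))
        arr[1] = 1.0
        arr[2] = 2.0
        ds = make_dataset(arr, 6, 6)
        pw = Pathway("pw", "syn", frozenset(ds.genes))
        res = gsnca_test(ds, pw, fast_cfg)
        assert res.status == "skipped"

    def test_reproducible_given_seed(self, rng, fast_cfg):
        ds = make_dataset(rng.standard_normal((6, 14)), 7, 7)
        pw = Pathway("pw", "syn", frozenset(ds.genes))
        r1 = gsnca_test(ds, pw, fast_cfg)
        r2 = gsnca_test(ds, pw, fast_cfg)
        assert r1.p == r2.p and r1.d_obs == r2.d_obs


class TestClassifyDissolution:
    def _links(self, rows):
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r1", "r2",
                                         "category"])
        df["is_dcl"] = True
        df["is_link"] = True
        return df

    def test_majority_rules_and_empty(self):
        pw = Pathway("pw", "s", frozenset({"a", "b", "c", "d"}))
        dec = [("a", "b", 0.8, 0.1, "decreased_positive")] * 5
        inc = [("a", "c", 0.1, 0.8, "increased_positive")] * 2
        assert classify_dissolution(pw, self._links(dec + inc)) == "dissolved"
        assert classify_dissolution(pw, self._links(dec[:1] + inc + inc[:1])) \
            == "consolidated"
        empty = self._links([])
        assert classify_dissolution(pw, empty) == "maintained"

    def test_sign_switch_with_smaller_magnitude_counts_decreased(self):
        pw = Pathway("pw", "s", frozenset({"a", "b", "c"}))
        rows = [("a", "b", 0.8, -0.3, "diff_signed"),
                ("a", "c", 0.2, 0.6, "increased_positive")]
        assert classify_dissolution(pw, self._links(rows)) == "maintained"

    def test_extra_pathway_links_ignored(self):
        pw = Pathway("pw", "s", frozenset({"a", "b"}))
        rows = [("a", "b", 0.9, 0.2, "decreased_positive"),
                ("x", "y", 0.1, 0.9, "increased_positive")] * 3
        assert classify_dissolution(pw, self._links(rows)) == "dissolved"
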