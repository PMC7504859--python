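"""DCL/DCG calling: correlations, density filter, LFC envelope, binomial test."""

import numpy as np
import pandas as pd
import pytest

from coexrewire.datamodel import AnalysisConfig
from coexrewire.diffcoexp import (
    call_dcgs,
    call_dcls,
    classify_dcl,
    condition_correlations,
    diff_coexpression,
    select_links,
)
from conftest import make_dataset


def pair_frame(pairs, cutoffs=(0.0, 0.0), all_links=True):
    """Build a link table directly from (gene_a, gene_b, r1, r2) rows."""
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b", "r1", "r2"])
    df["is_link"] = all_links
    df.attrs["cutoffs"] = cutoffs
    return df


class TestConditionCorrelations:
    def test_diagonal_and_affine_cases(self, rng):
        x = rng.standard_normal(8)
        arr = np.vstack([x, 2 * x + 1, -x, rng.standard_normal(8)])
        ds = make_dataset(np.hstack([arr, arr]), 8, 8)
        r1, _ = condition_correlations(ds)
        np.testing.assert_allclose(np.diag(r1), 1.0)
        np.testing.assert_allclose(r1.iloc[0, 1], 1.0)   # y = 2x + 1
        np.testing.assert_allclose(r1.iloc[0, 2], -1.0)  # y = -x
        np.testing.assert_allclose(r1.to_numpy(), r1.to_numpy().T)

    def test_hand_computed_pearson(self):
        # r((1,2,3,4), (1,3,2,4)) = cov/sd^2 = (4/3)/(5/3) = 0.8
        arr = np.array([[1, 2, 3, 4, 0, 1, 2, 5],
                        [1, 3, 2, 4, 1, 0, 3, 4]], dtype=float)
        ds = make_dataset(arr, 4, 4)
        r1, _ = condition_correlations(ds)
        assert r1.iloc[0, 1] == pytest.approx(0.8)

    def test_zero_variance_gene_excluded(self, rng):
        arr = rng.standard_normal((4, 10))
        arr[2] = 3.0  # flat in both conditions
        ds = make_dataset(arr, 5, 5)
        r1, r2 = condition_correlations(ds)
        assert "G002" not in r1.index and r1.shape == (3, 3)


class TestSelectLinks:
    def test_density_one_keeps_all_pairs(self, small_dataset):
        r1, r2 = condition_correlations(small_dataset)
        pairs = select_links(r1, r2, AnalysisConfig(density=1.0))
        assert pairs["is_link"].all()
        assert len(pairs) == 45  # C(10,2)

    def test_top_pair_at_low_density_matches_bruteforce(self, rng):
        arr = rng.standard_normal((5, 16))
        ds = make_dataset(arr, 8, 8)
        r1, r2 = condition_correlations(ds)
        pairs = select_links(r1, r2, AnalysisConfig(density=0.1))
        # brute-force oracle: the (1-density) quantile over the 10 |r| values
        for col, t in zip(("r1", "r2"), pairs.attrs["cutoffs"]):
            v = np.sort(np.abs(pairs[col].to_numpy()))
            assert t == np.quantile(v, 0.9, method="higher")
        expect = (np.abs(pairs["r1"]) >= pairs.attrs["cutoffs"][0]) | (
            np.abs(pairs["r2"]) >= pairs.attrs["cutoffs"][1])
        assert (pairs["is_link"] == expect).all()

    def test_identical_matrices_or_rule_degenerates(self, small_dataset):
        r1, _ = condition_correlations(small_dataset)
        both = select_links(r1, r1.copy(), AnalysisConfig(density=0.2))
        single_cut = np.quantile(np.abs(both["r1"]), 0.8, method="higher")
        assert (both["is_link"] == (np.abs(both["r1"]) >= single_cut)).all()

    def test_single_gene_rejected(self, small_dataset):
        r1, r2 = condition_correlations(small_dataset)
        with pytest.raises(ValueError):
            select_links(r1.iloc[:1, :1], r2.iloc[:1, :1], AnalysisConfig())


class TestCallDcls:
    def test_zero_fraction_no_sign_switch_gives_no_dcls(self, rng):
        rows = [(f"a{i}", f"b{i}", 0.5 + 0.04 * i, 0.3 + 0.02 * i)
                for i in range(10)]
        pairs = pair_frame(rows)
        out = call_dcls(pairs, AnalysisConfig(dcl_fraction=0.0))
        assert not out["is_dcl"].any()

    def test_one_bin_top_k_oracle(self, rng):
        # 20 same-signed pairs, one bin, q = 0.1 -> the 2 largest folds win
        r1 = rng.uniform(0.3, 0.9, 20)
        r2 = r1 / rng.uniform(1.1, 5.0, 20)
        rows = [(f"a{i:02d}", f"b{i:02d}", r1[i], r2[i]) for i in range(20)]
        pairs = pair_frame(rows)
        out = call_dcls(pairs, AnalysisConfig(dcl_fraction=0.1))
        folds = np.maximum(r1, r2) / np.minimum(r1, r2)
        expect = set(np.argsort(-folds)[:2])
        assert set(np.flatnonzero(out["is_dcl"])) == expect

    @pytest.mark.parametrize("n_pairs", [12, 25, 30])
    def test_small_instance_equals_bruteforce_oracle(self, rng, n_pairs):
        r1 = rng.uniform(0.05, 0.95, n_pairs)
        r2 = rng.uniform(0.05, 0.95, n_pairs)
        rows = [(f"a{i:02d}", f"b{i:02d}", r1[i], r2[i])
                for i in range(n_pairs)]
        out = call_dcls(pair_frame(rows), AnalysisConfig(dcl_fraction=0.2))
        folds = np.maximum(r1, r2) / np.maximum(np.minimum(r1, r2), 1e-4)
        k = int(np.ceil(0.2 * n_pairs))
        expect = set(np.argsort(-folds)[:k])  # single bin: plain top-k
        assert set(np.flatnonzero(out["is_dcl"])) == expect

    def test_sign_switch_above_cutoffs_is_direct_dcl(self):
        rows = [("a", "b", 0.9, -0.9), ("c", "d", 0.2, -0.1)]
        pairs = pair_frame(rows, cutoffs=(0.5, 0.5))
        out = call_dcls(pairs, AnalysisConfig())
        assert bool(out.loc[0, "is_dcl"]) and out.loc[0, "category"] == "diff_signed"
        assert not out.loc[1, "is_dcl"]  # below dual cutoff: not a DCL

    def test_fraction_monotonicity(self, rng):
        r1 = rng.uniform(0.05, 0.95, 40)
        r2 = rng.uniform(0.05, 0.95, 40)
        rows = [(f"a{i:02d}", f"b{i:02d}", r1[i], r2[i]) for i in range(40)]
        counts = []
        for q in (0.05, 0.1, 0.2, 0.4):
            out = call_dcls(pair_frame(rows), AnalysisConfig(dcl_fraction=q))
            counts.append(int(out["is_dcl"].sum()))
        assert counts == sorted(counts)


class TestClassifyDcl:
    @pytest.mark.parametrize("r1,r2,expect", [
        (0.8, 0.1, "decreased_positive"),
        (0.5, -0.6, "diff_signed"),
        (-0.7, -0.2, "same_signed_negative"),
        (0.1, 0.8, "increased_positive"),
        (0.0, 0.4, "increased_positive"),  # zero treated as positive sign
        (-0.3, 0.3, "diff_signed"),
    ])
    def test_categories(self, r1, r2, expect):
        assert classify_dcl(r1, r2) == expect

    def test_equal_magnitude_is_internal_error(self):
        with pytest.raises(RuntimeError):
            classify_dcl(0.5, 0.5)


class TestCallDcgs:
    def _links(self, rows):
        df = pair_frame([(a, b, 0.5, 0.1) for a, b, _ in rows])
        df["is_dcl"] = [d for _, _, d in rows]
        return df

    def test_binomial_tail_matches_pmf_sum(self):
        # hub gene g with k=10 links, d=5 DCLs; pi forced to 0.1 by filler
        from scipy.stats import binom
        k, d, pi = 10, 5, 0.1
        oracle = sum(binom.pmf(i, k, pi) for i in range(d, k + 1))
        links = [("g", f"n{i:02d}", i < d) for i in range(k)]
        # filler links fixing the global DCL fraction at 0.1
        n_fill = 40
        links += [(f"x{i:02d}", f"y{i:02d}", i < 0) for i in range(n_fill)]
        df = self._links(links)
        # global pi = 5/50 = 0.1
        out = call_dcgs(df, AnalysisConfig()).set_index("gene")
        assert out.attrs["pi_global"] == pytest.approx(pi)
        assert out.loc["g", "p"] == pytest.approx(oracle, rel=1e-10)
        assert oracle == pytest.approx(0.0016349374, rel=1e-5)

    def test_zero_dcls_gives_p_one(self):
        df = self._links([("g", f"n{i}", False) for i in range(5)]
                         + [("u", "v", True)])
        out = call_dcgs(df, AnalysisConfig()).set_index("gene")
        assert out.loc["g", "p"] == pytest.approx(1.0)

    def test_saturated_pi_gives_p_one(self):
        df = self._links([(f"a{i}", f"b{i}", True) for i in range(6)])
        out = call_dcgs(df, AnalysisConfig())
        assert np.allclose(out["p"], 1.0)


class TestEndToEnd:
    def test_category_shares_partition_and_pi(self, rng):
        from coexrewire.synthdata import SynthConfig, generate
        ds, _, _ = generate(SynthConfig(n_pathways=2, n_background_genes=20,
                                        rng_seed=3))
        res = diff_coexpression(ds, cfg=AnalysisConfig(rng_seed=3))
        n_dcl = int(res.links["is_dcl"].sum())
        n_link = int(res.links["is_link"].sum())
        assert n_dcl <= n_link
        assert res.pi_global == pytest.approx(n_dcl / n_link)
        assert sum(res.category_shares.values()) == pytest.approx(1.0)
        # every DCL is a link and categorized; non-DCLs are "none"
        dcl = res.links[res.links["is_dcl"]]
        assert dcl["is_link"].all()
        assert (dcl["category"] != "none").all()
        assert (res.links.loc[~res.links["is_dcl"], "category"] == "none").all()
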