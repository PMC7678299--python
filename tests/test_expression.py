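"""Normalization, filtering, BH-FDR, NB DE test, enrichment, PCA, correlation."""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from crispant_audit import (
    CountsMatrix,
    PhenotypeModel,
    SampleMeta,
    bh_fdr,
    correlate_with_phenotype,
    cpm,
    default_design,
    filter_genes,
    hypergeometric_enrichment,
    nb_de_test,
    pca_top_variant,
    simulate_counts,
    tpm,
)


def _cm(counts: dict, lengths: dict | None = None) -> CountsMatrix:
    df = pd.DataFrame(counts).T  # keys = gene ids, values = per-sample dicts
    lens = pd.Series(lengths) if lengths else None
    return CountsMatrix(df, lens)


class TestCpmTpm:
    def test_cpm_definition(self):
        cm = _cm({"g1": {"s1": 900_000}, "g2": {"s1": 100_000}})
        out = cpm(cm)
        assert out.loc["g1", "s1"] == pytest.approx(900_000.0)
        assert out.loc["g2", "s1"] == pytest.approx(100_000.0)

    def test_cpm_zero_library_is_error(self):
        cm = _cm({"g1": {"s1": 0, "s2": 5}})
        with pytest.raises(ValueError, match="zero library"):
            cpm(cm)

    def test_tpm_length_normalization(self):
        # equal counts, 2x length difference -> 2:1 TPM ratio favouring short
        cm = _cm({"g1": {"s1": 100}, "g2": {"s1": 100}}, {"g1": 1000, "g2": 2000})
        out = tpm(cm)
        assert out.loc["g1", "s1"] / out.loc["g2", "s1"] == pytest.approx(2.0)

    def test_tpm_columns_sum_to_1e6(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        counts.iloc[0] += 1  # guard against an all-zero column
        lengths = pd.Series(rng.integers(200, 5000, size=40), index=counts.index)
        out = tpm(CountsMatrix(counts, lengths))
        np.testing.assert_allclose(out.sum(axis=0).values, 1e6, rtol=1e-12)

    def test_tpm_requires_lengths(self):
        cm = _cm({"g1": {"s1": 10}})
        with pytest.raises(ValueError, match="length"):
            tpm(cm)
        with pytest.raises(ValueError, match="positive"):
            tpm(_cm({"g1": {"s1": 10}}, {"g1": 0}))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _cm({"g1": {"s1": -1}})


class TestFilterGenes:
    def test_cpm_threshold_and_sample_fraction(self):
        # library size 1e6 in every sample so CPM == count
        filler = {f"s{j}": 10**6 - 12 if j < 2 else 10**6 - 5 for j in range(4)}
        cm = _cm({
            "kept": {"s0": 12, "s1": 12, "s2": 5, "s3": 5},
            "filler": filler,
        })
        # "kept" has CPM [12, 12, 5, 5]; frac 0.75 of 4 samples needs 3 >= 1 CPM
        out = filter_genes(cm, min_cpm=10.0, min_sample_frac=0.75)
        assert "kept" not in out.genes  # only 2 of 4 samples reach 10 CPM
        out = filter_genes(cm, min_cpm=10.0, min_sample_frac=0.5)
        assert "kept" in out.genes

    def test_monotone_in_min_cpm(self):
        rng = np.random.default_rng(15)
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(8)],
        )
        counts.iloc[0] += 1
        cm = CountsMatrix(counts)
        prev = None
        for min_cpm in [0.5, 1.0, 2.0, 5.0, 20.0]:
            kept = set(filter_genes(cm, min_cpm=min_cpm).genes)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_invalid_fraction(self):
        cm = _cm({"g1": {"s1": 10}})
        with pytest.raises(ValueError):
            filter_genes(cm, min_sample_frac=0.0)


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up enumeration: q_(i) = min_{j >= i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_worked_example(self):
        # p = [0.01, 0.02, 0.03, 0.04], m=4: q_(i) = min_j>=i p_j*4/j = 0.04 each
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=100)
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            p = rng.uniform(size=64)
            sm_q = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_fdr(p), sm_q, rtol=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert (q <= 1.0).all() and (q >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone along sorted p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
        assert bh_fdr([]).size == 0


def _hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact P(X >= k) by brute-force mass summation."""
    total = Fraction(0)
    for j in range(max(k, max(0, K + n - N)), min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return total


class TestHypergeometricEnrichment:
    def test_worked_example_exact(self):
        # N=10, K=5, n=5, k=5 -> 1 / C(10,5) = 1/252
        universe = [f"g{i}" for i in range(10)]
        degs = universe[:5]
        res = hypergeometric_enrichment(degs, {"pw": universe[:5]}, universe)
        assert res.loc[0, "p"] == pytest.approx(1 / 252, rel=1e-12)
        assert bool(res.loc[0, "significant"])  # 1/252 < 0.005

    def test_k_zero_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeometric_enrichment(universe[:3], {"pw": universe[5:]}, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)
        assert not bool(res.loc[0, "significant"])

    def test_membership_intersected_with_universe(self):
        universe = ["a", "b", "c", "d"]
        res = hypergeometric_enrichment(["a"], {"pw": ["a", "zz"]}, universe)
        assert int(res.loc[0, "K"]) == 1  # "zz" outside the universe ignored

    def test_errors(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_enrichment([], {}, [])
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["x"], {}, ["a"])

    @pytest.mark.parametrize("N", [1, 2, 5, 8, 12])
    def test_exhaustive_small_grid_vs_fraction_oracle(self, N):
        universe = [f"g{i}" for i in range(N)]
        for n in range(N + 1):
            degs = universe[:n]
            pathways = {}
            expected = {}
            for K in range(N + 1):
                for k in range(max(0, K + n - N), min(K, n) + 1):
                    # k members among the DEGs, K - k among the rest
                    members = universe[:k] + universe[n : n + (K - k)]
                    pid = f"K{K}_k{k}"
                    pathways[pid] = members
                    expected[pid] = float(_hypergeom_tail_oracle(k, N, K, n))
            if not pathways:
                continue
            res = hypergeometric_enrichment(degs, pathways, universe, p_cut=0.005)
            for _, row in res.iterrows():
                assert row["p"] == pytest.approx(expected[row["pathway_id"]], rel=1e-10)


def _meta(n_per_group=6):
    return default_design(n_per_group=n_per_group)


class TestNbDeTest:
    def test_identical_groups_no_fold_change(self):
        # both groups see literally identical columns -> log2fc == 0, no DEGs
        meta = _meta(3)
        rng = np.random.default_rng(5)
        col = rng.integers(10, 500, size=80)
        counts = pd.DataFrame(
            {m.sample_id: col for m in meta},
            index=[f"g{i}" for i in range(80)],
        )
        res = nb_de_test(CountsMatrix(counts), meta, ("WT", None), ("d6abc5_mt", None))
        np.testing.assert_allclose(res["log2fc"].values, 0.0, atol=1e-9)
        assert not res["is_deg"].any()

    def test_all_zero_gene_neutral(self):
        meta = _meta(3)
        cm, meta, _ = simulate_counts(50, meta, seed=4)
        counts = cm.counts.copy()
        counts.iloc[0] = 0
        res = nb_de_test(CountsMatrix(counts), meta, ("WT", None), ("d6abc5_mt", None))
        g0 = res.iloc[0]
        assert g0["p"] == 1.0 and g0["log2fc"] == 0.0 and not g0["is_deg"]

    def test_small_group_rejected(self):
        meta = _meta(3)
        cm, meta, _ = simulate_counts(20, meta, seed=4)
        with pytest.raises(ValueError, match="at least 2"):
            nb_de_test(cm, meta, [meta[0].sample_id], ("d6abc5_mt", None))

    def test_overlapping_groups_rejected(self):
        meta = _meta(3)
        cm, meta, _ = simulate_counts(20, meta, seed=4)
        ids = [m.sample_id for m in meta[:4]]
        with pytest.raises(ValueError, match="overlap"):
            nb_de_test(cm, meta, ids[:3], ids[2:])

    def test_null_type_i_error_calibrated(self):
        meta = default_design(6)
        cm, meta, _ = simulate_counts(2000, meta, baseline_mean=100.0,
                                      dispersion=0.1, seed=42)
        res = nb_de_test(cm, meta, ("WT", None), ("d6abc5_mt", None))
        type_i = float((res["p"] < 0.05).mean())
        assert 0.03 <= type_i <= 0.07

    def test_planted_effects_recovered(self):
        meta = default_design(6)
        cm, meta, truth = simulate_counts(
            2000, meta, baseline_mean=100.0, dispersion=0.1,
            de_fraction=0.1, planted_log2fc=2.0, seed=7,
        )
        res = nb_de_test(cm, meta, ("WT", None), ("d6abc5_mt", None))
        is_de = truth.table.set_index("gene_id")["is_de"].reindex(res.index)
        called = res["q"] < 0.05
        recall = float((called & is_de).sum() / is_de.sum())
        fdp = float((called & ~is_de).sum() / max(int(called.sum()), 1))
        median_lfc = float(res.loc[is_de.values, "log2fc"].median())
        assert recall >= 0.8
        assert fdp <= 0.1
        assert abs(median_lfc - 2.0) <= 0.2


class TestPca:
    def test_two_samples_lie_on_a_line(self):
        # with two samples the centred matrix has rank 1: PC1 explains 100%
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(30, 2)),
            index=[f"g{i}" for i in range(30)],
            columns=["s1", "s2"],
        )
        res = pca_top_variant(CountsMatrix(counts), top_n=30)
        assert res.varexp[0] == pytest.approx(100.0, abs=1e-6)

    def test_varexp_sums_to_100(self):
        meta = _meta(3)
        cm, meta, _ = simulate_counts(300, meta, seed=11)
        res = pca_top_variant(cm, top_n=100)
        assert res.varexp.sum() == pytest.approx(100.0, rel=1e-9)

    def test_groups_separate_on_pc1(self):
        meta = default_design(6)
        cm, meta, _ = simulate_counts(
            500, meta, de_fraction=0.2, planted_log2fc=2.0, seed=11
        )
        res = pca_top_variant(cm, top_n=200)
        strain_of = {m.sample_id: m.strain for m in meta}
        pc1 = res.scores["PC1"]
        wt = pc1[[s for s in pc1.index if strain_of[s] == "WT"]]
        mt = pc1[[s for s in pc1.index if strain_of[s] != "WT"]]
        # strains form disjoint clusters along PC1
        assert max(wt.min(), mt.min()) > min(wt.max(), mt.max()) or \
            wt.max() < mt.min() or mt.max() < wt.min()

    def test_sample_order_invariance_up_to_sign(self):
        meta = _meta(3)
        cm, meta, _ = simulate_counts(200, meta, de_fraction=0.2,
                                      planted_log2fc=1.5, seed=13)
        res1 = pca_top_variant(cm, top_n=100)
        shuffled = cm.counts[list(reversed(cm.counts.columns))]
        res2 = pca_top_variant(CountsMatrix(shuffled), top_n=100)
        np.testing.assert_allclose(res1.varexp, res2.varexp, rtol=1e-8, atol=1e-9)
        a = res1.scores["PC1"].sort_index().values
        b = res2.scores["PC1"].sort_index().values
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_top_n_warning_and_errors(self):
        cm = _cm({"g1": {"s1": 10, "s2": 20}, "g2": {"s1": 5, "s2": 5}})
        with pytest.warns(UserWarning, match="exceeds"):
            pca_top_variant(cm, top_n=10)
        single = _cm({"g1": {"s1": 10}})
        with pytest.raises(ValueError, match="at least 2"):
            pca_top_variant(single)


class TestCorrelation:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate_with_phenotype(x, [2 * v + 1 for v in x], "g")
        assert res.r == pytest.approx(1.0)
        res = correlate_with_phenotype(x, [-2 * v + 1 for v in x], "g")
        assert res.r == pytest.approx(-1.0)

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        res = correlate_with_phenotype(x, y, "g")
        from scipy import stats
        n, r = res.n, res.r
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_zero_variance_reported(self):
        res = correlate_with_phenotype([1.0, 1.0, 1.0], [0.5, 0.7, 0.2], "g")
        assert res.r is None and res.reason == "zero_variance"

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            correlate_with_phenotype([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlate_with_phenotype([1.0, 2.0, 3.0], [1.0, 2.0])


class TestSampleMetaVocabulary:
    def test_valid_and_invalid(self):
        SampleMeta("s", "d6bc_mt", "fish_oil")
        with pytest.raises(ValueError, match="strain"):
            SampleMeta("s", "mutantX", "fish_oil")
        with pytest.raises(ValueError, match="diet"):
            SampleMeta("s", "WT", "chow")


class TestPhenotypeCorrelationEndToEnd:
    def test_planted_slope_detected(self):
        meta = default_design(6)
        pm = PhenotypeModel(n_correlated=20, slope=1.5)
        cm, meta, truth = simulate_counts(300, meta, phenotype_model=pm, seed=23)
        pheno = [m.phenotype for m in meta]
        assert all(p is not None for p in pheno)
        logcpm = np.log2(cpm(cm) + 1.0)
        slopes = truth.table.set_index("gene_id")["phenotype_slope"]
        corr_genes = slopes[slopes != 0].index
        null_genes = slopes[slopes == 0].index[:20]
        r_corr = np.median([
            abs(correlate_with_phenotype(logcpm.loc[g].values, pheno, g).r)
            for g in corr_genes
        ])
        r_null = np.median([
            abs(correlate_with_phenotype(logcpm.loc[g].values, pheno, g).r)
            for g in null_genes
        ])
        assert r_corr > 0.5 > r_null
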