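"""Differential-expression engine: size factors, NB Wald fits, DEG and rescue
classification, and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from dbsomics.diffexpr import (CountMatrix, classify_degs, classify_rescue,
                               cluster_samples, estimate_size_factors,
                               fit_differential, normalized_group_means)
from dbsomics.simulate import PlantedEffect, SimConfig, generate_counts

from conftest import make_samples


def brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Independent median-of-ratios: explicit loops, no shared code path."""
    rows = [i for i in counts.index if (counts.loc[i] > 0).all()]
    geo = {
        i: np.exp(sum(np.log(v) for v in counts.loc[i]) / counts.shape[1])
        for i in rows
    }
    sf = []
    for s in counts.columns:
        ratios = sorted(counts.loc[i, s] / geo[i] for i in rows)
        m = len(ratios)
        med = ratios[m // 2] if m % 2 else 0.5 * (ratios[m // 2 - 1] + ratios[m // 2])
        sf.append(med)
    sf = np.array(sf)
    return sf / np.exp(np.mean(np.log(sf)))


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        counts.index = ["g1", "g2", "g3"]
        sf = estimate_size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_gets_double_factor(self):
        a = pd.Series([10, 20, 30], index=["g1", "g2", "g3"])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        sf = estimate_size_factors(counts)
        assert np.isclose(sf["b"] / sf["a"], 2.0)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(200, 8)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(8)],
        )
        sf = estimate_size_factors(counts)
        assert np.allclose(sf.to_numpy(), brute_force_size_factors(counts), rtol=1e-12)

    def test_no_universally_expressed_feature_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(counts)


class TestFitDifferential:
    def test_flat_gene_has_zero_lfc_and_p_one(self, two_group_samples):
        rng = np.random.default_rng(1)
        # every gene constant across samples: no depth differences, no signal
        vals = rng.integers(50, 500, size=40)
        counts = pd.DataFrame(
            np.tile(vals[:, None], (1, 10)),
            index=[f"g{i}" for i in range(40)],
            columns=two_group_samples.index,
        )
        cm = CountMatrix(counts=counts, samples=two_group_samples)
        res = fit_differential(cm, ("DBS", "sham"), batch_col=None, min_mean=40)
        assert res.loc["g0", "lfc"] == 0.0
        assert res.loc["g0", "stat"] == 0.0
        assert res.loc["g0", "pvalue"] == 1.0

    def test_low_mean_features_excluded(self, two_group_samples):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(100, size=(30, 10)),
            index=[f"g{i}" for i in range(30)],
            columns=two_group_samples.index,
        )
        counts.iloc[5] = rng.poisson(10, size=10)
        cm = CountMatrix(counts=counts, samples=two_group_samples)
        res = fit_differential(cm, ("DBS", "sham"), min_mean=40)
        assert "g5" not in res.index

    def test_confounded_batch_raises(self):
        samples = make_samples([("WT", "sham", 3), ("WT", "DBS", 3)])
        samples["batch"] = ["b1"] * 3 + ["b2"] * 3  # batch == condition
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(100, size=(20, 6)),
            index=[f"g{i}" for i in range(20)],
            columns=samples.index,
        )
        cm = CountMatrix(counts=counts, samples=samples)
        with pytest.raises(ValueError, match="confounded"):
            fit_differential(cm, ("DBS", "sham"))

    def test_planted_lfc_recovered_against_likelihood_grid(self):
        """Point estimates agree with a brute-force NB profile-likelihood grid."""
        cfg = SimConfig(seed=11, n_genes=300, dispersion=0.05)
        cfg.samples = make_samples([("WT", "sham", 10), ("WT", "DBS", 10)])
        cfg.planted_effects = [
            PlantedEffect(feature=f"g{i:05d}", log2fc=1.0, treatment="DBS")
            for i in range(60, 90)
        ]
        cm, _ = generate_counts(cfg)
        res = fit_differential(cm, ("DBS", "sham"), batch_col=None, min_mean=40)

        # oracle: per-gene grid over (log2 baseline, log2 fc) at the fitted alpha
        from scipy.stats import nbinom

        def grid_mle(k, is_dbs, alpha):
            grid_b = np.linspace(np.log2(k.mean()) - 1, np.log2(k.mean()) + 1, 81)
            grid_f = np.linspace(-1.0, 3.0, 161)
            best, best_ll = None, -np.inf
            r = 1.0 / alpha
            for b in grid_b:
                mu = 2.0 ** (b + grid_f[:, None] * is_dbs[None, :])
                p = r / (r + mu)
                ll = nbinom.logpmf(k[None, :], r, p).sum(axis=1)
                j = np.argmax(ll)
                if ll[j] > best_ll:
                    best_ll, best = ll[j], grid_f[j]
            return best

        is_dbs = (cm.samples["treatment"] == "DBS").to_numpy().astype(float)
        planted = [f"g{i:05d}" for i in range(60, 90) if f"g{i:05d}" in res.index]
        diffs = []
        for gid in planted[:12]:
            k = cm.counts.loc[gid].to_numpy(dtype=float)
            mle = grid_mle(k, is_dbs, 0.05)
            diffs.append(res.loc[gid, "lfc"] - mle)
        assert np.mean(np.abs(diffs)) < 0.1

    def test_size_factor_invariance_of_lfc(self, small_counts):
        res0 = fit_differential(small_counts, ("DBS", "sham"), min_mean=10)
        scaled = small_counts.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 4
        cm = CountMatrix(counts=scaled, samples=small_counts.samples)
        res1 = fit_differential(cm, ("DBS", "sham"), min_mean=10)
        sf0 = estimate_size_factors(small_counts.counts)
        sf1 = estimate_size_factors(scaled)
        assert np.isclose(sf1.iloc[0] / sf0.iloc[0] / (sf1.iloc[1] / sf0.iloc[1]), 4.0,
                          rtol=1e-6)
        # rescaled counts carry different shot noise, so dispersion estimates
        # (and hence fits) shift slightly; invariance is approximate
        common = res0.index.intersection(res1.index)
        assert np.allclose(res0.loc[common, "lfc"], res1.loc[common, "lfc"], atol=0.05)

    def test_bh_fdr_monotone_in_p_rank(self, small_counts):
        res = fit_differential(small_counts, ("DBS", "sham"), min_mean=10)
        assert res["padj"].between(0, 1).all()
        srt = res.sort_values("pvalue")
        assert (np.diff(srt["padj"].to_numpy()) >= -1e-12).all()

    def test_shrunken_lfc_never_exceeds_raw(self, small_counts):
        res = fit_differential(small_counts, ("DBS", "sham"), min_mean=10)
        assert (res["lfcShrunk"].abs() <= res["lfc"].abs() + 1e-9).all()


class TestClassifyDegs:
    @pytest.mark.parametrize(
        "lfc,padj,fc,expected",
        [
            (1.2, 0.01, 2.0, "up"),       # fold 2.3 at FDR 0.01 passes 2-fold
            (1.2, 0.5, 2.0, "none"),      # non-significant excluded regardless
            (np.log2(1.87), 0.001, 2.0, "none"),   # fold 1.87 below 2-fold
            (np.log2(1.87), 0.001, 1.2, "up"),     # same gene passes at 1.2-fold
            (-1.5, 0.01, 2.0, "down"),
        ],
    )
    def test_threshold_gates(self, lfc, padj, fc, expected):
        res = pd.DataFrame({"lfcShrunk": [lfc], "padj": [padj]}, index=["g"])
        up, down = classify_degs(res, fc_threshold=fc, fdr_threshold=0.05)
        got = "up" if "g" in up else ("down" if "g" in down else "none")
        assert got == expected

    def test_rejects_nonpositive_thresholds(self):
        res = pd.DataFrame({"lfcShrunk": [1.0], "padj": [0.01]}, index=["g"])
        with pytest.raises(ValueError):
            classify_degs(res, fc_threshold=0.0)


def _mk_result(lfc, padj):
    return pd.DataFrame({"lfcShrunk": lfc, "lfc": lfc, "padj": padj},
                        index=[f"g{i}" for i in range(len(lfc))])


class TestClassifyRescue:
    def test_taxonomy(self):
        down = _mk_result([-1.0, -1.0, -1.0], [0.01, 0.01, 0.01])
        # +35% rescued; +10% partial (significant but <20%); +50% non-sig unchanged
        dbs = _mk_result([np.log2(1.35), np.log2(1.10), np.log2(1.50)],
                         [0.01, 0.01, 0.2])
        table = classify_rescue(down, dbs)
        assert table.loc["g0", "class"] == "rescued"
        assert table.loc["g1", "class"] == "partial"
        assert table.loc["g2", "class"] == "unchanged"

    def test_classes_partition_input(self):
        rng = np.random.default_rng(5)
        n = 40
        down = _mk_result(-np.abs(rng.normal(1, 0.3, n)), np.full(n, 0.01))
        dbs = _mk_result(rng.normal(0.2, 0.4, n), rng.uniform(0, 0.2, n))
        table = classify_rescue(down, dbs)
        assert len(table) == n
        assert set(table["class"]) <= {"unchanged", "partial", "rescued"}

    def test_strict_baseline_is_a_subset(self):
        rng = np.random.default_rng(6)
        n = 30
        down = _mk_result(-np.abs(rng.normal(1, 0.3, n)), np.full(n, 0.01))
        dbs = _mk_result(rng.normal(0.4, 0.3, n), rng.uniform(0, 0.1, n))
        means = pd.DataFrame(
            {"KO:DBS": rng.uniform(50, 150, n), "WT:sham": rng.uniform(50, 150, n)},
            index=down.index,
        )
        loose = classify_rescue(down, dbs, means, strict_baseline=False)
        strict = classify_rescue(down, dbs, means, strict_baseline=True)
        loose_set = set(loose.index[loose["class"] == "rescued"])
        strict_set = set(strict.index[strict["class"] == "rescued"])
        assert strict_set <= loose_set
        assert "baseline_reached" in strict.columns

    def test_missing_gene_raises_with_ids(self):
        down = _mk_result([-1.0], [0.01])
        dbs = _mk_result([], [])
        with pytest.raises(KeyError, match="g0"):
            classify_rescue(down, dbs)


class TestClusterSamples:
    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.poisson(100, size=(30, 4)).astype(float),
                         columns=["a", "b", "c", "d"])
        m["d"] = m["a"]
        order, Z = cluster_samples(m)
        # the first merge joins the zero-distance pair
        first = sorted([int(Z[0, 0]), int(Z[0, 1])])
        assert first == [0, 3]

    def test_matches_brute_force_average_linkage_on_six_samples(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.poisson(80, size=(40, 6)).astype(float),
                         columns=list("abcdef"))
        _, Z = cluster_samples(m)
        logm = np.log2(m.to_numpy() + 1)
        corr = np.corrcoef(logm.T)
        dist = 1 - corr
        np.fill_diagonal(dist, 0)
        Z_oracle = hierarchy.linkage(squareform((dist + dist.T) / 2, checks=False),
                                     method="average")
        # same merge heights and same flat clusters at every level
        assert np.allclose(np.sort(Z[:, 2]), np.sort(Z_oracle[:, 2]), atol=1e-12)
        for t in Z_oracle[:, 2]:
            a = hierarchy.fcluster(Z, t, criterion="distance")
            b = hierarchy.fcluster(Z_oracle, t, criterion="distance")
            assert len(set(zip(a, b))) == len(set(a))

    def test_treatment_split_dominates_genotype_when_planted(self):
        cfg = SimConfig(seed=10, n_genes=300)
        cfg.samples = make_samples(
            [("WT", "sham", 3), ("WT", "DBS", 3), ("KO", "sham", 3), ("KO", "DBS", 3)]
        )
        # heterogeneous per-gene effect sizes: correlation distance is
        # invariant to a uniform log-scale shift, so the treatment signature
        # must vary across genes to separate the groups
        cfg.planted_effects = [
            PlantedEffect(feature=f"g{i:05d}", log2fc=1.0 + 2.0 * (i % 4) / 3.0,
                          treatment="DBS")
            for i in range(50, 150)
        ] + [
            PlantedEffect(feature=f"g{i:05d}", log2fc=0.2 + 0.1 * (i % 2),
                          genotype="KO")
            for i in range(50, 100)
        ]
        cm, _ = generate_counts(cfg)
        sf = estimate_size_factors(cm.counts)
        subset = [f"g{i:05d}" for i in range(50, 150)]
        order, Z = cluster_samples(cm.counts / sf, subset)
        k2 = hierarchy.fcluster(Z, 2, criterion="maxclust")
        treatment = cm.samples["treatment"].to_numpy()
        assert len(set(zip(k2, treatment))) == 2  # top split == treatment split

    def test_constant_matrix_warns_and_returns_flat_order(self):
        m = pd.DataFrame(np.full((10, 3), 5.0), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="constant"):
            order, Z = cluster_samples(m)
        assert order == ["a", "b", "c"]
        assert Z is None


def test_normalized_group_means_shape(small_counts):
    means = normalized_group_means(small_counts)
    assert list(means.columns) == ["WT:DBS", "WT:sham"]
    assert len(means) == small_counts.counts.shape[0]


class TestCrossCheckAgainstEstablishedTool:
    def test_agrees_with_independent_nb_implementation(self):
        """Point estimates and calls line up with the reference NB Wald tool
        (used here purely as an independent oracle on a small dataset)."""
        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = SimConfig(seed=51, n_genes=200)
        cfg.samples = make_samples([("WT", "sham", 5), ("WT", "DBS", 5)])
        cfg.planted_effects = [
            PlantedEffect(feature=f"g{i:05d}", log2fc=1.5, treatment="DBS")
            for i in range(50, 70)
        ]
        cm, _ = generate_counts(cfg)
        res = fit_differential(cm, ("DBS", "sham"), batch_col=None, min_mean=40)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=cm.counts.loc[res.index].T,
                               metadata=cm.samples.copy(),
                               design="~treatment", refit_cooks=False, quiet=True)
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["treatment", "DBS", "sham"], quiet=True)
            ds.summary()
        ref = ds.results_df

        both = res.join(ref[["log2FoldChange", "padj"]], rsuffix="_ref")
        assert np.corrcoef(both["lfc"], both["log2FoldChange"])[0, 1] > 0.999
        assert (both["lfc"] - both["log2FoldChange"]).abs().max() < 0.05
        sf = estimate_size_factors(cm.counts.loc[res.index])
        assert np.abs(sf.to_numpy() - dds.obs["size_factors"].to_numpy()).max() < 0.01
        calls_mine = res["padj"] < 0.05
        calls_ref = ref["padj"] < 0.05
        assert (calls_mine == calls_ref).mean() > 0.95
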