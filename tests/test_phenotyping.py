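import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plaqueomics.io_core import AbundanceMatrix, Fraction, SampleMetadata
from plaqueomics.phenotyping import (build_combined_matrix,
                                     characterize_clusters, km_curves,
                                     kmeans_phenotypes, logrank_test,
                                     pca_embed, silhouette_scan)

from conftest import minimal_metadata


def _m(rows, fraction=Fraction.SDS, samples=None):
    df = pd.DataFrame(rows).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return AbundanceMatrix(fraction, df)


class TestCombinedMatrix:
    def test_single_fraction_rows_are_zscored(self):
        rng = np.random.default_rng(0)
        m = _m({f"P{i}": rng.normal(3, 2, 20) for i in range(5)})
        out = build_combined_matrix(m)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_restricted_to_shared_samples(self):
        rng = np.random.default_rng(1)
        a = _m({f"P{i}": rng.normal(size=12) for i in range(3)},
               samples=[f"s{i}" for i in range(12)])
        b = _m({f"Q{i}": rng.normal(size=10) for i in range(3)},
               fraction=Fraction.GUHCL,
               samples=[f"s{i}" for i in range(10)])
        out = build_combined_matrix(a, b)
        assert out.shape[1] == 10
        assert out.index.str.startswith("SDS:").sum() == 3
        assert out.index.str.startswith("GuHCl:").sum() == 3

    def test_constant_row_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        m = _m({"A": rng.normal(size=10), "K": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            out = build_combined_matrix(m)
        assert list(out.index) == ["SDS:A"]

    def test_no_shared_samples_errors(self):
        a = _m({"A": np.arange(3.0)}, samples=["s1", "s2", "s3"])
        b = _m({"B": np.arange(3.0)}, fraction=Fraction.NACL,
               samples=["t1", "t2", "t3"])
        with pytest.raises(ValueError, match="no shared samples"):
            build_combined_matrix(a, b)


class TestPCAEmbed:
    def test_rank_one_data(self):
        u = np.linspace(-1, 1, 30)
        x = pd.DataFrame(np.outer([1.0, 2.0, -1.0], u),
                         index=list("ABC"),
                         columns=[f"s{i}" for i in range(30)])
        scores, ev = pca_embed(x, n_components=2)
        assert ev[0] == pytest.approx(1.0)
        assert ev[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.standard_normal((10, 500)),
                         index=[f"P{i}" for i in range(10)],
                         columns=[f"s{i}" for i in range(500)])
        _, ev = pca_embed(x, n_components=10)
        assert ((ev > 0.05) & (ev < 0.15)).all()

    def test_deterministic_orientation_under_column_permutation(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.standard_normal((8, 40)),
                         index=[f"P{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(40)])
        s1, _ = pca_embed(x, 3)
        s2, _ = pca_embed(x[x.columns[::-1]], 3)
        assert np.allclose(s1.loc[s2.index].to_numpy(), s2.to_numpy(),
                           atol=1e-8)

    def test_excessive_components_error(self):
        x = pd.DataFrame(np.eye(3), index=list("ABC"),
                         columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="exceeds"):
            pca_embed(x, 5)


class TestKMeansPhenotypes:
    def _planted(self, seed=5, k=4, n_per=25, sep=10.0):
        rng = np.random.default_rng(seed)
        centers = rng.standard_normal((k, 3)) * sep
        pts = np.vstack([centers[i] + rng.standard_normal((n_per, 3))
                         for i in range(k)])
        truth = np.repeat(np.arange(k), n_per)
        scores = pd.DataFrame(pts, columns=["PC1", "PC2", "PC3"],
                              index=[f"s{i}" for i in range(k * n_per)])
        return scores, truth

    def test_well_separated_clusters_exact_recovery(self):
        scores, truth = self._planted()
        model = kmeans_phenotypes(scores, k=4, seed=0)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_labels_size_ordered(self):
        scores, _ = self._planted()
        drop = scores.iloc[5:]  # cluster 0 smaller than the rest
        model = kmeans_phenotypes(drop, k=4, seed=0)
        sizes = model.labels.value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_k_equals_samples_zero_inertia(self):
        scores = pd.DataFrame(np.arange(12.0).reshape(6, 2),
                              columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(6)])
        model = kmeans_phenotypes(scores, k=6, seed=0, n_components=2)
        assert model.inertia == pytest.approx(0.0)
        assert model.labels.nunique() == 6

    def test_same_seed_identical_labels(self):
        scores, _ = self._planted(sep=2.0)
        a = kmeans_phenotypes(scores, k=4, seed=3)
        b = kmeans_phenotypes(scores, k=4, seed=3)
        assert (a.labels == b.labels).all()

    def test_k_validation(self):
        scores, _ = self._planted()
        with pytest.raises(ValueError):
            kmeans_phenotypes(scores, k=1)
        with pytest.raises(ValueError):
            kmeans_phenotypes(scores.head(3), k=5)

    def test_silhouette_scan_reports_range(self):
        scores, _ = self._planted()
        scan = silhouette_scan(scores, range(2, 6))
        assert list(scan["k"]) == [2, 3, 4, 5]
        assert scan.loc[scan["k"] == 4, "silhouette"].iloc[0] == \
            scan["silhouette"].max()


class TestCharacterizeClusters:
    def test_point_biserial_hand_value(self):
        # r of x=(0,0,1,1) vs y=(1,2,3,4) is 2/sqrt(5) = 0.8944
        labels = pd.Series([0, 0, 1, 1], index=[f"s{i}" for i in range(4)])
        scores = pd.DataFrame({"PC1": [0.0, 0, 1, 1]}, index=labels.index)
        from plaqueomics.phenotyping import PhenotypeModel
        model = PhenotypeModel(pc_scores=scores, explained_variance=np.array([]),
                               k=2, labels=labels, centroids=np.zeros((2, 1)),
                               inertia=0.0, n_components_used=1, seed=0)
        meta = minimal_metadata(4, age=[1.0, 2.0, 3.0, 4.0])
        out = characterize_clusters(model, meta, ["age"])
        r = out[(out["cluster"] == 1) & (out["feature"] == "age")]["r"]
        assert r.iloc[0] == pytest.approx(2 / np.sqrt(5), abs=1e-4)

    def test_indicator_identical_to_binary_feature(self):
        labels = pd.Series([0, 0, 1, 1, 0, 1],
                           index=[f"s{i}" for i in range(6)])
        from plaqueomics.phenotyping import PhenotypeModel
        model = PhenotypeModel(pc_scores=pd.DataFrame(index=labels.index),
                               explained_variance=np.array([]), k=2,
                               labels=labels, centroids=np.zeros((2, 1)),
                               inertia=0.0, n_components_used=1, seed=0)
        meta = minimal_metadata(6, calcified=(labels == 1).to_numpy())
        out = characterize_clusters(model, meta, ["calcified"])
        r1 = out[(out["cluster"] == 1)]["r"].iloc[0]
        assert r1 == pytest.approx(1.0)

    def test_constant_feature_reported_missing(self):
        labels = pd.Series([0, 1, 0, 1], index=[f"s{i}" for i in range(4)])
        from plaqueomics.phenotyping import PhenotypeModel
        model = PhenotypeModel(pc_scores=pd.DataFrame(index=labels.index),
                               explained_variance=np.array([]), k=2,
                               labels=labels, centroids=np.zeros((2, 1)),
                               inertia=0.0, n_components_used=1, seed=0)
        meta = minimal_metadata(4)  # statin constant False
        out = characterize_clusters(model, meta, ["statin"])
        assert out["r"].isna().all()


class TestSurvival:
    def test_km_product_limit_by_hand(self):
        meta = minimal_metadata(4, follow_up=[1.0, 2.0, 3.0, 4.0],
                                event=True)
        curves = km_curves(meta, pd.Series(["g"] * 4,
                                           index=meta.table["sample_id"]))
        tab = curves.strata["g"].set_index("time")
        assert np.allclose(tab.loc[[1.0, 2.0, 3.0, 4.0], "survival"],
                           [0.75, 0.5, 0.25, 0.0], atol=1e-12)
        assert list(tab.loc[[1.0, 2.0, 3.0, 4.0], "at_risk"]) == [4, 3, 2, 1]

    def test_no_events_curve_stays_at_one(self):
        meta = minimal_metadata(5, follow_up=[1.0, 2, 3, 4, 5], event=False)
        curves = km_curves(meta, pd.Series(["g"] * 5,
                                           index=meta.table["sample_id"]))
        assert (curves.strata["g"]["survival"] == 1.0).all()

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(6)
        t = np.round(rng.exponential(2.0, 40), 3)
        meta = minimal_metadata(40, follow_up=t, event=True)
        curves = km_curves(meta, pd.Series(["g"] * 40,
                                           index=meta.table["sample_id"]))
        tab = curves.strata["g"]
        emp = [(t > time).mean() for time in tab["time"]]
        assert np.allclose(tab["survival"], emp, atol=1e-12)

    def test_logrank_identical_groups_chi2_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        chi2, df, p = logrank_test(t, [True] * 6, [0, 0, 0, 1, 1, 1])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_logrank_permutation_null_calibrated(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1.0, 60)
        event = rng.random(60) < 0.8
        rejections = 0
        n_perm = 400
        for _ in range(n_perm):
            g = rng.permutation(np.repeat([0, 1], 30))
            _, _, p = logrank_test(t, event, g)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_perm <= 0.08

    def test_negative_followup_errors(self):
        with pytest.raises(ValueError, match="negative"):
            logrank_test([-1.0, 2.0], [True, True], [0, 1])

    def test_single_stratum_errors(self):
        with pytest.raises(ValueError, match="2 strata"):
            logrank_test([1.0, 2.0], [True, True], [0, 0])
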