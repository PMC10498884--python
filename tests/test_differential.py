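import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaqueomics.differential import (DesignSpec, EBayesPrior, bh_adjust,
                                      differential_abundance, estimate_prior,
                                      one_vs_all_differential, top_n)
from plaqueomics.io_core import AbundanceMatrix, Fraction, SampleMetadata

from conftest import minimal_metadata


def _null_matrix(seed, n_proteins=300, n=30, d0=4.0, s0=1.0):
    rng = np.random.default_rng(seed)
    sigma2 = s0 * d0 / rng.chisquare(d0, n_proteins)
    x = rng.normal(0, np.sqrt(sigma2)[:, None], (n_proteins, n))
    m = AbundanceMatrix(Fraction.SDS, pd.DataFrame(
        x, index=[f"P{i:04d}" for i in range(n_proteins)],
        columns=[f"s{i}" for i in range(n)]))
    group = np.repeat([False, True], n // 2)
    return m, minimal_metadata(n, symptomatic=group)


class TestModeratedStatistic:
    def test_infinite_prior_gives_fixed_variance_z(self):
        m, meta = _null_matrix(0)
        res = differential_abundance(m, meta, DesignSpec("symptomatic"),
                                     prior=EBayesPrior(np.inf, 1.0))
        tab = res.table
        # t must equal beta / (se_unit * s0) exactly; check via a huge-d0 fit
        res_big = differential_abundance(m, meta, DesignSpec("symptomatic"),
                                         prior=EBayesPrior(1e8, 1.0))
        assert np.allclose(tab["t"], res_big.table["t"], atol=1e-3)
        assert np.isinf(tab["df_total"]).all()

    def test_tiny_prior_df_recovers_ordinary_t(self):
        m, meta = _null_matrix(1, n_proteins=40)
        res = differential_abundance(m, meta, DesignSpec("symptomatic"),
                                     prior=EBayesPrior(1e-9, 1.0))
        group = meta.table["symptomatic"].to_numpy()
        for i, pid in enumerate(res.table["protein_id"]):
            y = m.data.loc[pid].to_numpy()
            t_ref, _ = stats.ttest_ind(y[group], y[~group], equal_var=True)
            assert res.table["t"].iloc[i] == pytest.approx(t_ref, rel=1e-6)

    def test_prior_estimation_recovers_planted_hyperparameters(self):
        rng = np.random.default_rng(5)
        d0, s0, df = 4.0, 1.0, 38
        s2 = s0 * d0 / rng.chisquare(d0, 3000) * rng.chisquare(df, 3000) / df
        prior = estimate_prior(s2, np.full(3000, df))
        assert 2.5 <= prior.d0 <= 6.5
        assert prior.s0_sq == pytest.approx(1.0, rel=0.2)

    def test_homogeneous_variances_give_full_shrinkage(self):
        rng = np.random.default_rng(2)
        df = 20
        s2 = rng.chisquare(df, 2000) / df  # common sigma^2 = 1
        prior = estimate_prior(s2, np.full(2000, df))
        # no real heterogeneity: shrinkage is (near-)total — d0 is either
        # infinite or orders of magnitude above the residual df
        assert np.isinf(prior.d0) or prior.d0 > 100 * df
        assert prior.s0_sq == pytest.approx(1.0, rel=0.1)

    def test_orthogonal_covariate_leaves_log2fc_unchanged(self):
        # noise-free data: adding a covariate orthogonal to the contrast
        # must not move the contrast coefficient
        n = 40
        group = np.repeat([False, True], n // 2)
        cov = np.tile([-1.0, 1.0], n // 2)  # orthogonal to group by design
        y = 1.0 + 2.0 * group
        m = AbundanceMatrix(Fraction.SDS, pd.DataFrame(
            [y, y + 0.5], index=["A", "B"],
            columns=[f"s{i}" for i in range(n)]))
        meta = minimal_metadata(n, symptomatic=group, age=cov)
        fix = EBayesPrior(4.0, 1.0)
        plain = differential_abundance(m, meta, DesignSpec("symptomatic"),
                                       prior=fix)
        adjusted = differential_abundance(
            m, meta, DesignSpec("symptomatic", ["age"]), prior=fix)
        assert np.allclose(plain.table["log2fc"], adjusted.table["log2fc"],
                           atol=1e-8)

    def test_rank_deficient_design_lists_aliased_column(self):
        n = 20
        group = np.repeat([False, True], n // 2)
        m, _ = _null_matrix(3, n_proteins=5, n=n)
        meta = minimal_metadata(n, symptomatic=group,
                                age=group.astype(float))  # age == contrast
        with pytest.raises(ValueError, match="aliased"):
            differential_abundance(m, meta,
                                   DesignSpec("symptomatic", ["age"]))

    def test_matches_limma_reference(self, tmp_path):
        """Dual-route check: the moderated fit must agree with the
        Bioconductor reference implementation on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the reference fit")
        rng = np.random.default_rng(42)
        n, p = 24, 120
        sigma2 = 0.8 * 5 / rng.chisquare(5, p)
        x = rng.normal(0, np.sqrt(sigma2)[:, None], (p, n))
        group = np.repeat([0, 1], n // 2)
        age = rng.normal(70, 8, n)
        x[:20] += 0.7 * group
        xdf = pd.DataFrame(x, index=[f"P{i}" for i in range(p)],
                           columns=[f"s{i}" for i in range(n)])
        xdf.to_csv(tmp_path / "x.csv")
        pd.DataFrame({"group": group, "age": age},
                     index=xdf.columns).to_csv(tmp_path / "meta.csv")
        rscript = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv('{tmp_path}/x.csv', row.names=1))
        meta <- read.csv('{tmp_path}/meta.csv', row.names=1)
        design <- model.matrix(~ group + age, data=meta)
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(coef=fit$coefficients[,'group'],
                          t=fit$t[,'group'], p=fit$p.value[,'group'])
        write.csv(out, '{tmp_path}/limma.csv')
        """
        (tmp_path / "check.R").write_text(rscript)
        subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True,
                       capture_output=True)
        lim = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        meta = minimal_metadata(n, calcified=group.astype(bool), age=age)
        res = differential_abundance(
            AbundanceMatrix(Fraction.SDS, xdf), meta,
            DesignSpec("calcified", ["age"]))
        tab = res.table.set_index("protein_id")
        assert np.max(np.abs(tab["t"] - lim["t"])) < 1e-8
        assert np.max(np.abs(tab["log2fc"] - lim["coef"])) < 1e-8
        assert np.max(np.abs(tab["p"] - lim["p"])) < 1e-8


class TestBHAdjust:
    def test_stepup_by_hand(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_order_preserved_with_input(self):
        p = np.array([0.9, 0.001, 0.5, 0.02])
        q = bh_adjust(p)
        assert np.argmin(q) == np.argmin(p)
        # sorting by p and by q give the same order
        assert list(np.argsort(p, kind="stable")) == \
            list(np.argsort(q, kind="stable"))


class TestOneVsAll:
    def test_two_clusters_reduce_to_two_group_contrast(self):
        m, meta = _null_matrix(7, n_proteins=50)
        labels = pd.Series(np.repeat([0, 1], 15), index=m.sample_ids)
        ova = one_vs_all_differential(m, meta, labels, 1)
        direct = differential_abundance(
            m, minimal_metadata(30, symptomatic=(labels == 1).to_numpy()),
            DesignSpec("symptomatic"))
        assert np.allclose(ova.table["t"], direct.table["t"])

    def test_planted_cluster_proteins_rank_top5(self):
        hits = 0
        n_seeds = 25
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            n, p = 100, 60
            labels = pd.Series(rng.integers(0, 4, n))
            x = rng.normal(0, 0.5, (p, n))
            x[:5, (labels == 2).to_numpy()] += 2.0
            m = AbundanceMatrix(Fraction.SDS, pd.DataFrame(
                x, index=[f"P{i:02d}" for i in range(p)],
                columns=[f"s{i}" for i in range(n)]))
            labels.index = m.sample_ids
            ova = one_vs_all_differential(m, minimal_metadata(n), labels, 2)
            best = set(top_n(ova, 5)["protein_id"])
            hits += best == {f"P{i:02d}" for i in range(5)}
        assert hits / n_seeds >= 0.95

    def test_single_cluster_errors(self):
        m, meta = _null_matrix(9, n_proteins=5)
        labels = pd.Series(0, index=m.sample_ids)
        with pytest.raises(ValueError, match="two distinct"):
            one_vs_all_differential(m, meta, labels, 0)

    def test_permuted_labels_yield_no_discoveries(self):
        ok = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(200 + s)
            n, p = 60, 200
            x = rng.normal(0, 1, (p, n))
            m = AbundanceMatrix(Fraction.SDS, pd.DataFrame(
                x, index=[f"P{i:03d}" for i in range(p)],
                columns=[f"s{i}" for i in range(n)]))
            labels = pd.Series(rng.permutation(np.repeat([0, 1, 2], n // 3)),
                               index=m.sample_ids)
            ova = one_vs_all_differential(m, minimal_metadata(n), labels, 0)
            ok += ova.table["q"].min() > 0.05
        assert ok / n_seeds >= 0.9


def test_complete_case_fitting_with_missing_values():
    m, meta = _null_matrix(11, n_proteins=30)
    data = m.data.copy()
    data.iloc[0, :5] = np.nan
    m2 = AbundanceMatrix(m.fraction, data)
    res = differential_abundance(m2, meta, DesignSpec("symptomatic"))
    tab = res.table.set_index("protein_id")
    assert tab.loc["P0000", "n_used"] == 25
    assert (tab["n_used"][1:] == 30).all()
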