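"""Molecular plaque phenotypes: PCA + k-means over the combined proteome,
cluster characterization, and survival stratification.

The cellular and matrisome fractions are z-scored per protein, concatenated
over a shared sample set, embedded by PCA, and clustered with k-means (default
k = 4).  Clusters are related to clinical features by point-biserial /
Spearman correlation, and to the composite cardiovascular endpoint by
Kaplan-Meier curves with a k-sample log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .differential import bh_adjust
from .io_core import AbundanceMatrix, SampleMetadata

__all__ = [
    "PhenotypeModel", "SurvivalCurves",
    "build_combined_matrix", "pca_embed", "kmeans_phenotypes",
    "characterize_clusters", "km_curves", "logrank_test",
    "silhouette_scan",
]


@dataclass
class PhenotypeModel:
    pc_scores: pd.DataFrame          # samples x components
    explained_variance: np.ndarray   # variance-explained ratio per component
    k: int
    labels: pd.Series                # sample -> cluster id (0 = largest)
    centroids: np.ndarray            # cluster x components used
    inertia: float
    n_components_used: int
    seed: int


@dataclass
class SurvivalCurves:
    strata: dict                     # label -> DataFrame(time, at_risk, events, survival)
    logrank_chi2: float
    logrank_df: int
    logrank_p: float


def build_combined_matrix(*matrices: AbundanceMatrix) -> pd.DataFrame:
    """Per-fraction z-scored, median-imputed matrices stacked over shared
    samples.  Row index is ``fraction:protein``; constant rows are dropped
    with a warning."""
    if not matrices:
        raise ValueError("need at least one matrix")
    shared = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        shared &= set(m.sample_ids)
    if not shared:
        raise ValueError("no shared samples between fractions")
    order = [s for s in matrices[0].sample_ids if s in shared]
    blocks = []
    for m in matrices:
        imp = m.imputed().loc[:, order]
        sd = imp.std(axis=1, ddof=0)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant protein rows dropped from "
                f"{m.fraction.value}", stacklevel=2)
            imp, sd = imp.loc[~const], sd[~const]
        z = imp.sub(imp.mean(axis=1), axis=0).div(sd, axis=0)
        z.index = [f"{m.fraction.value}:{p}" for p in z.index]
        blocks.append(z)
    return pd.concat(blocks, axis=0)


def pca_embed(x: pd.DataFrame, n_components: int = 10,
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered SVD of samples x proteins with deterministic orientation.

    Each component is signed so its largest-|loading| protein has a positive
    loading.  ``x`` is proteins x samples (as from build_combined_matrix).
    """
    obs = x.to_numpy(dtype=float).T  # samples x proteins
    max_rank = min(obs.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound "
                         f"{max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(obs)
    loadings = pca.components_
    for c in range(n_components):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] *= -1
            scores[:, c] *= -1
    score_df = pd.DataFrame(
        scores, index=x.columns,
        columns=[f"PC{c + 1}" for c in range(n_components)])
    return score_df, pca.explained_variance_ratio_


def kmeans_phenotypes(pc_scores: pd.DataFrame, k: int = 4, seed: int = 0,
                      n_init: int = 25, n_components: int = 3,
                      explained_variance: np.ndarray | None = None,
                      ) -> PhenotypeModel:
    """Best-of-n_init k-means (k-means++ seeding) on the leading components.

    Cluster ids are renumbered by descending size, ties broken by centroid
    lexicographic order, so labels are reproducible across runs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > pc_scores.shape[0]:
        raise ValueError("k exceeds the number of samples")
    n_components = min(n_components, pc_scores.shape[1])
    xs = pc_scores.iloc[:, :n_components].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(xs)
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k),
                   key=lambda c: (-sizes[c], tuple(km.cluster_centers_[c])))
    relabel = {old: new for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=pc_scores.index,
                       name="phenotype")
    centroids = km.cluster_centers_[order]
    ev = (np.asarray(explained_variance)
          if explained_variance is not None else np.array([]))
    return PhenotypeModel(pc_scores=pc_scores, explained_variance=ev, k=k,
                          labels=labels, centroids=centroids,
                          inertia=float(km.inertia_),
                          n_components_used=n_components, seed=seed)


def silhouette_scan(pc_scores: pd.DataFrame, k_range=range(2, 9),
                    seed: int = 0, n_components: int = 3) -> pd.DataFrame:
    """Mean silhouette width for a range of k (reported, not used for
    selection unless requested)."""
    from sklearn.metrics import silhouette_score
    xs = pc_scores.iloc[:, :n_components].to_numpy(dtype=float)
    rows = []
    for k in k_range:
        if k >= xs.shape[0]:
            break
        labels = KMeans(n_clusters=k, n_init=10,
                        random_state=seed).fit_predict(xs)
        rows.append((k, float(silhouette_score(xs, labels))))
    return pd.DataFrame(rows, columns=["k", "silhouette"])


def _is_binary(col: pd.Series) -> bool:
    if col.dtype == bool:
        return True
    vals = col.dropna().unique()
    return len(vals) == 2


def characterize_clusters(model: PhenotypeModel, meta: SampleMetadata,
                          features: list[str]) -> pd.DataFrame:
    """Correlate each cluster one-hot indicator with clinical features.

    Binary features use point-biserial (Pearson on the 0/1 coding); continuous
    features use Spearman.  BH is applied across the full matrix of tests.
    Constant features are reported as missing.
    """
    from scipy import stats
    aligned = meta.aligned(list(model.labels.index))
    missing = [f for f in features if f not in aligned.columns]
    if missing:
        raise KeyError(f"features not in metadata: {missing}")
    rows = []
    for c in range(model.k):
        ind = (model.labels == c).to_numpy(dtype=float)
        for feat in features:
            col = aligned[feat]
            ok = col.notna().to_numpy()
            if ok.sum() < 3 or col[ok].nunique() < 2:
                rows.append((c, feat, np.nan, np.nan))
                continue
            if _is_binary(col):
                vals = col[ok]
                if vals.dtype == object or vals.dtype.name == "category":
                    levels = sorted(vals.astype(str).unique())
                    x = (vals.astype(str) == levels[-1]).to_numpy(dtype=float)
                else:
                    x = vals.to_numpy(dtype=float)
                r, p = stats.pearsonr(ind[ok], x)
            else:
                r, p = stats.spearmanr(ind[ok], col[ok].to_numpy(dtype=float))
            rows.append((c, feat, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["cluster", "feature", "r", "p"])
    q = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        q[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def logrank_test(durations, event_observed, groups) -> tuple[float, int, float]:
    """Unweighted (Mantel-Haenszel) k-sample log-rank test.

    Returns (chi2, df, p).  Simultaneous events at identical times are
    handled by the pooled risk-set construction.
    """
    durations = np.asarray(durations, dtype=float)
    if (durations < 0).any():
        raise ValueError("negative follow-up time")
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank needs at least 2 strata")
    res = multivariate_logrank_test(durations, groups,
                                    np.asarray(event_observed, dtype=bool))
    df = len(np.unique(groups)) - 1
    return float(res.test_statistic), df, float(res.p_value)


def km_curves(meta: SampleMetadata, strata: pd.Series | dict,
              ) -> SurvivalCurves:
    """Kaplan-Meier product-limit curves per stratum + the log-rank test."""
    strata = pd.Series(strata)
    aligned = meta.aligned(list(strata.index))
    durations = aligned["follow_up"].to_numpy(dtype=float)
    if (durations < 0).any():
        raise ValueError("negative follow-up time")
    events = aligned["event"].to_numpy(dtype=bool)
    labels = strata.to_numpy()
    out: dict = {}
    for lab in pd.unique(labels):
        mask = labels == lab
        kmf = KaplanMeierFitter()
        kmf.fit(durations[mask], events[mask])
        et = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[lab] = pd.DataFrame({
            "time": et.index.to_numpy(dtype=float),
            "at_risk": et["at_risk"].to_numpy(dtype=int),
            "events": et["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
        }).reset_index(drop=True)
    if len(out) >= 2:
        chi2, df, p = logrank_test(durations, events, labels)
    else:
        chi2, df, p = np.nan, 0, np.nan
    return SurvivalCurves(strata=out, logrank_chi2=chi2, logrank_df=df,
                          logrank_p=p)
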