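"""Covariate-adjusted per-protein linear models with empirical-Bayes moderation.

Each protein is fit by ordinary least squares on a design matrix of
[intercept, contrast indicator, covariates] over its complete cases.  Residual
variances s_g^2 (d_g df) are shrunk towards a prior (d0, s0^2) estimated once
across proteins by moment-matching the distribution of log s_g^2 (digamma /
trigamma inversion).  The moderated statistic

    t_g = beta_g / (u_g * s~_g),    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom (a normal when
d0 is infinite), with u_g the unscaled standard error of the contrast
coefficient.  If the spread of log s_g^2 is no larger than expected under a
common variance, d0 is set to infinity (full shrinkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_core import AbundanceMatrix, SampleMetadata

__all__ = [
    "DesignSpec", "EBayesPrior", "DifferentialTable",
    "differential_abundance", "one_vs_all_differential",
    "bh_adjust", "top_n", "estimate_prior",
]


@dataclass
class DesignSpec:
    """Contrast + adjustment covariates, all drawn from the metadata table."""

    contrast: str
    covariates: list[str] | tuple[str, ...] = ()
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if self.contrast in self.covariates:
            raise ValueError("contrast variable cannot also be a covariate")


@dataclass
class EBayesPrior:
    """Moderation hyperparameters: prior df d0 (may be inf) and variance s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be positive")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


@dataclass
class DifferentialTable:
    """Per-protein results plus the shared prior used for moderation."""

    table: pd.DataFrame  # protein_id, log2fc, t, df_total, p, q, n_used
    prior: EBayesPrior
    design_columns: list[str]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _encode_column(col: pd.Series, reference: str | None = None) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy(dtype=float)
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(dtype=float)
    levels = sorted(col.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"column {col.name!r} has {len(levels)} levels; binary or numeric "
            "required for the contrast (one-hot covariates are expanded "
            "separately)")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not among {levels}")
    other = [x for x in levels if x != ref][0]
    return (col.astype(str) == other).to_numpy(dtype=float)


def build_design(meta: pd.DataFrame, design: DesignSpec,
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, contrast, covariates...] from aligned metadata rows."""
    for name in (design.contrast, *design.covariates):
        if name not in meta.columns:
            raise KeyError(f"metadata has no column {name!r}")
    cols: list[np.ndarray] = [np.ones(len(meta))]
    names = ["intercept", design.contrast]
    cols.append(_encode_column(meta[design.contrast], design.reference_level))
    for cov in design.covariates:
        col = meta[cov]
        if col.dtype == bool or np.issubdtype(col.dtype, np.number):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy(dtype=float))
                names.append(f"{cov}[{dcol}]")
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = _aliased_columns(x, names)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return x, names


def _aliased_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[j] for j in range(x.shape[1]) if diag[j] < tol]


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation (moment matching on log variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Estimate (d0, s0^2) from residual variances with their df.

    Matches the first two moments of log s^2 under the scaled-F model:
    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has mean log s0^2 and excess
    variance trigamma(d0/2) beyond mean(trigamma(d_g/2)).  Non-positive excess
    variance means no detectable heterogeneity and yields d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def _posterior_variance(s2: np.ndarray, df: np.ndarray,
                        prior: EBayesPrior) -> np.ndarray:
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, int]:
    """OLS of y on x; returns (contrast beta, unscaled se, s^2, residual df).

    The contrast coefficient is column 1 of the design.
    """
    n, p = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - p
    s2 = float(resid @ resid / df) if df > 0 else np.nan
    xtx_inv = np.linalg.inv(x.T @ x)
    u = float(np.sqrt(xtx_inv[1, 1]))
    return float(beta[1]), u, s2, df


def differential_abundance(
    m: AbundanceMatrix,
    meta: SampleMetadata,
    design: DesignSpec,
    prior: EBayesPrior | None = None,
    min_per_level: int = 2,
) -> DifferentialTable:
    """Moderated differential abundance for every protein in ``m``.

    Complete-case per protein: samples with a missing value are dropped from
    that protein's fit only.  ``prior`` overrides the estimated moderation
    hyperparameters (``EBayesPrior(d0=np.inf, ...)`` gives full shrinkage; a
    tiny d0 approaches the ordinary t-test).
    """
    aligned = meta.aligned(m.sample_ids)
    x_full, names = build_design(aligned, design)
    contrast_col = x_full[:, 1]
    values = m.values()

    rows = []
    for i, pid in enumerate(m.protein_ids):
        y = values[i]
        keep = ~np.isnan(y)
        xk, yk = x_full[keep], y[keep]
        ck = contrast_col[keep]
        n_lvl1 = int((ck != 0).sum())
        n_lvl0 = int((ck == 0).sum())
        if n_lvl0 < min_per_level or n_lvl1 < min_per_level:
            warnings.warn(f"protein {pid!r}: fewer than {min_per_level} "
                          "samples per contrast level; excluded", stacklevel=2)
            continue
        if xk.shape[0] <= xk.shape[1]:
            warnings.warn(f"protein {pid!r}: non-positive residual df; "
                          "excluded", stacklevel=2)
            continue
        if np.linalg.matrix_rank(xk) < xk.shape[1]:
            warnings.warn(f"protein {pid!r}: design not full rank on complete "
                          "cases; excluded", stacklevel=2)
            continue
        beta, u, s2, df = _fit_ols(yk, xk)
        rows.append((pid, beta, u, s2, df, int(keep.sum())))

    if not rows:
        raise ValueError("no protein could be fit")
    tab = pd.DataFrame(rows, columns=["protein_id", "log2fc", "se_unit",
                                      "s2", "df_resid", "n_used"])
    fitted_prior = prior if prior is not None else estimate_prior(
        tab["s2"].to_numpy(), tab["df_resid"].to_numpy())

    s2_post = _posterior_variance(tab["s2"].to_numpy(),
                                  tab["df_resid"].to_numpy(), fitted_prior)
    t = tab["log2fc"].to_numpy() / (tab["se_unit"].to_numpy()
                                    * np.sqrt(s2_post))
    df_total = tab["df_resid"].to_numpy() + fitted_prior.d0
    if np.isinf(fitted_prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({
        "protein_id": tab["protein_id"],
        "log2fc": tab["log2fc"],
        "t": t,
        "df_total": df_total,
        "p": p,
        "q": bh_adjust(p),
        "n_used": tab["n_used"],
    })
    return DifferentialTable(table=out, prior=fitted_prior,
                             design_columns=names)


def one_vs_all_differential(
    m: AbundanceMatrix,
    meta: SampleMetadata,
    labels: pd.Series | dict,
    k,
    covariates: list[str] | tuple[str, ...] = (),
    prior: EBayesPrior | None = None,
) -> DifferentialTable:
    """Cluster k vs all other clusters, as a two-group moderated contrast."""
    labels = pd.Series(labels)
    lab = labels.reindex(m.sample_ids)
    if lab.isna().any():
        raise KeyError("every sample needs a cluster label")
    if lab.nunique() < 2:
        raise ValueError("one-vs-all needs at least two distinct clusters")
    if (lab == k).sum() == 0:
        raise ValueError(f"cluster {k!r} is empty")
    meta2 = meta.table.copy()
    meta2["in_cluster"] = (lab == k).reindex(meta2.index).fillna(False)
    return differential_abundance(
        m, SampleMetadata(meta2),
        DesignSpec(contrast="in_cluster", covariates=tuple(covariates)),
        prior=prior)


def top_n(result: DifferentialTable, n: int = 5,
          positive_only: bool = False) -> pd.DataFrame:
    """Top proteins by q, ties broken by |log2fc| descending then id."""
    tab = result.table
    if positive_only:
        tab = tab[tab["log2fc"] > 0]
    tab = tab.assign(_absfc=tab["log2fc"].abs())
    tab = tab.sort_values(["q", "_absfc", "protein_id"],
                          ascending=[True, False, True], kind="stable")
    return tab.drop(columns="_absfc").head(n).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
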