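"""Signature scoring, score correlations and Fisher-exact set enrichment.

A signature is a named set of proteins (optionally signed).  Samples are scored
by the first principal component of the standardized member submatrix, which
summarises the coordinated abundance of e.g. the inflammation signature
(calprotectin, myeloperoxidase, ...) or the calcification signature (fetuin-A,
osteopontin, gamma-carboxylated proteins) in one number per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .differential import bh_adjust
from .io_core import AbundanceMatrix

__all__ = [
    "SignatureDefinition", "SignatureScores",
    "score_first_pc", "correlate_scores", "marker_correlations",
    "fisher_enrichment", "read_signatures_yaml",
]


@dataclass
class SignatureDefinition:
    name: str
    members: tuple[str, ...]
    direction: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("signature needs at least one member")
        self.members = tuple(dict.fromkeys(self.members))  # dedupe, keep order


@dataclass
class SignatureScores:
    """Standardized per-sample scores (mean 0, sd 1) for one signature."""

    name: str
    scores: pd.Series                 # sample_id -> score
    variance_explained: float | None = None
    members_used: tuple[str, ...] = ()
    members_dropped: tuple[str, ...] = ()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def score_first_pc(m: AbundanceMatrix, sig: SignatureDefinition,
                   ) -> SignatureScores:
    """First-PC score of the signature members, oriented and standardized.

    Member rows are median-imputed and z-scored; the PC sign is fixed so the
    mean member loading is positive (so "more signature" means a higher
    score).  Members absent from the matrix are reported as dropped; fewer
    than 2 present members is an error.
    """
    present = [p for p in sig.members if p in m.data.index]
    dropped = tuple(p for p in sig.members if p not in m.data.index)
    if len(present) < 2:
        raise ValueError(
            f"signature {sig.name!r}: fewer than 2 members present "
            f"(missing: {list(dropped)})")
    sub = m.data.loc[present]
    sub = sub.apply(lambda row: row.fillna(row.median()), axis=1)
    z = np.vstack([_standardize(sub.loc[p].to_numpy(dtype=float))
                   for p in present])
    for i, p in enumerate(present):
        sign = sig.direction.get(p, 1)
        if sign < 0:
            z[i] = -z[i]
    # samples as observations
    x = z.T - z.T.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[0]
    scores = u[:, 0] * s[0]
    if loadings.mean() < 0:
        loadings, scores = -loadings, -scores
    total_var = (s ** 2).sum()
    var_explained = float(s[0] ** 2 / total_var) if total_var > 0 else 0.0
    return SignatureScores(
        name=sig.name,
        scores=pd.Series(_standardize(scores), index=m.sample_ids,
                         name=sig.name),
        variance_explained=var_explained,
        members_used=tuple(present),
        members_dropped=dropped,
    )


def correlate_scores(a: SignatureScores, b: SignatureScores,
                     method: str = "pearson") -> tuple[float, float]:
    """Correlation of two score vectors over their shared samples."""
    shared = a.scores.index.intersection(b.scores.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    xa = a.scores.loc[shared].to_numpy()
    xb = b.scores.loc[shared].to_numpy()
    if method == "pearson":
        r, p = stats.pearsonr(xa, xb)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, xb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def marker_correlations(targets: list[str], m: AbundanceMatrix,
                        marker_scores: list[SignatureScores],
                        ) -> pd.DataFrame:
    """Spearman rho of each target protein against each marker score.

    Returns a long-format table (target, marker, rho, p, q) with BH applied
    across the whole matrix of tests.  Constant target vectors give missing
    rho.
    """
    absent = [t for t in targets if t not in m.data.index]
    if absent:
        raise KeyError(f"targets not in matrix: {absent}")
    rows = []
    for t in targets:
        y = m.data.loc[t]
        for ms in marker_scores:
            shared = y.dropna().index.intersection(ms.scores.index)
            yv = y.loc[shared].to_numpy(dtype=float)
            sv = ms.scores.loc[shared].to_numpy(dtype=float)
            if len(shared) < 3 or np.ptp(yv) == 0:
                rows.append((t, ms.name, np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(yv, sv)
            rows.append((t, ms.name, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["target", "marker", "rho", "p"])
    q = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        q[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


def fisher_enrichment(hits: set, clusters, background: set) -> pd.DataFrame:
    """One-sided (enrichment) Fisher exact test of hits against protein sets.

    ``clusters`` is a mapping name -> set, or a single set (tested alone).
    The p-value is the upper hypergeometric tail of the observed overlap at
    fixed margins; BH is applied across the clusters tested in one call.
    Returns a table (cluster, overlap, cluster_size, hits, background,
    odds_ratio, p, q).
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    hits = set(hits)
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    if not isinstance(clusters, dict):
        clusters = {"set": set(clusters)}
    rows = []
    n = len(background)
    for name, cluster in clusters.items():
        cluster = set(cluster)
        if not cluster <= background:
            raise ValueError(f"cluster {name!r} not a subset of background")
        a = len(hits & cluster)
        # upper tail: P(overlap >= a) under hypergeom(N=n, K=|hits|, n=|cluster|)
        p = float(stats.hypergeom.sf(a - 1, n, len(hits), len(cluster)))
        b = len(hits) - a
        c = len(cluster) - a
        d = n - len(hits) - c
        if b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = np.inf if a * d > 0 else np.nan
        rows.append((name, a, len(cluster), len(hits), n, odds, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["cluster", "overlap", "cluster_size",
                                      "n_hits", "n_background", "odds_ratio",
                                      "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def read_signatures_yaml(path) -> list[SignatureDefinition]:
    """Signature definitions from YAML: {name: [members...]} or
    {name: {members: [...], direction: {id: -1}}}."""
    raw = yaml.safe_load(open(path))
    sigs = []
    for name, spec in raw.items():
        if isinstance(spec, dict):
            sigs.append(SignatureDefinition(
                name, tuple(spec["members"]),
                {k: int(v) for k, v in spec.get("direction", {}).items()}))
        else:
            sigs.append(SignatureDefinition(name, tuple(spec)))
    return sigs
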