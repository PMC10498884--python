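"""Matrisome association networks from conditional mutual information.

Edges are weighted by a Gaussian-copula mutual information estimator: each
protein's abundance vector is rank-transformed to normal scores, and for
normal scores MI has the closed form -1/2 ln(1 - rho^2) (nats), with rho the
(partial) correlation.  The estimator is invariant to strictly monotone
transforms of the inputs, which suits non-Gaussian proteomic intensities.

Indirect associations are pruned data-processing-inequality style: for each
kept edge (i, j), the conditional MI given every common neighbour k is
computed, and the edge is dropped when min_k CMI(i;j|k) falls below
``dpi_epsilon`` times the marginal MI — the signature of a chain i - k - j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import bh_adjust
from .io_core import AbundanceMatrix
from .signatures import fisher_enrichment

__all__ = [
    "ProteinNetwork", "gaussian_copula_cmi", "reconstruct_network",
    "cluster_network", "cluster_enrichment", "to_networkx", "write_graphml",
]


@dataclass
class ProteinNetwork:
    """Undirected weighted network over proteins.

    ``edges`` columns: source, target, mi (nats), cmi_min (nats), p_perm, q.
    ``cluster_of`` maps every node to a hierarchical-cluster id (assigned by
    :func:`cluster_network`; empty until then).
    """

    nodes: list[str]
    edges: pd.DataFrame
    cluster_of: dict[str, int] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom-type, ties -> average)."""
    n = x.shape[0]
    ranks = stats.rankdata(x)
    return stats.norm.ppf(ranks / (n + 1.0))


def _mi_from_rho(rho) -> np.ndarray:
    rho = np.clip(np.abs(rho), 0.0, 1.0 - 1e-12)
    return -0.5 * np.log1p(-(rho ** 2))


def gaussian_copula_cmi(x: np.ndarray, y: np.ndarray,
                        z: np.ndarray | None = None) -> float:
    """MI(x;y) or CMI(x;y|z) in nats via normal-scores (partial) correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if z is not None:
        z = np.asarray(z, dtype=float)
        keep &= ~np.isnan(z)
    min_n = 10
    if keep.sum() < min_n:
        raise ValueError(f"need at least {min_n} complete observations")
    x, y = x[keep], y[keep]
    zc = z[keep] if z is not None else None
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"degenerate variable {name}: constant vector")
    gx, gy = _normal_scores(x), _normal_scores(y)
    if zc is None:
        rho = np.corrcoef(gx, gy)[0, 1]
        return float(_mi_from_rho(rho))
    if np.ptp(zc) == 0:
        raise ValueError("degenerate variable z: constant vector")
    gz = _normal_scores(zc)
    rxy = np.corrcoef(gx, gy)[0, 1]
    rxz = np.corrcoef(gx, gz)[0, 1]
    ryz = np.corrcoef(gy, gz)[0, 1]
    denom = np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
    rho = (rxy - rxz * ryz) / denom if denom > 0 else 0.0
    return float(_mi_from_rho(rho))


def _partial_rho(r: np.ndarray, i: int, j: int, k: int) -> float:
    denom = np.sqrt((1 - r[i, k] ** 2) * (1 - r[j, k] ** 2))
    if denom <= 0:
        return 0.0
    return (r[i, j] - r[i, k] * r[j, k]) / denom


def reconstruct_network(
    m: AbundanceMatrix,
    n_perm: int = 1000,
    q_max: float = 0.05,
    dpi_epsilon: float = 0.05,
    seed: int = 0,
) -> ProteinNetwork:
    """Pairwise MI network with a permutation null and DPI pruning.

    1. Median-impute, rank-transform every protein to normal scores, and
       compute all pairwise MI values.
    2. Permutation null: per permutation one side of the pairing is shuffled
       over samples; edge p = (1 + #{null >= observed}) / (1 + n_perm), BH
       across pairs, keep q <= q_max.
    3. For each kept edge, cmi_min = min over common neighbours k of
       CMI(i;j|k); drop the edge if cmi_min < dpi_epsilon * mi.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100: permutation null too coarse")
    if len(m.protein_ids) < 3:
        raise ValueError("need at least 3 proteins")
    rng = np.random.default_rng(seed)
    data = m.imputed().to_numpy(dtype=float)
    p, n = data.shape
    const = np.ptp(data, axis=1) == 0
    if const.any():
        raise ValueError(
            f"degenerate variable: constant protein "
            f"{m.protein_ids[int(np.where(const)[0][0])]!r}")
    scores = np.vstack([_normal_scores(row) for row in data])
    zs = scores - scores.mean(axis=1, keepdims=True)
    norms = np.sqrt((zs ** 2).sum(axis=1))
    zs = zs / norms[:, None]
    r = np.clip(zs @ zs.T, -1.0, 1.0)
    mi = _mi_from_rho(r)

    iu, ju = np.triu_indices(p, k=1)
    obs = mi[iu, ju]
    exceed = np.zeros(obs.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        null_r = zs[:, perm] @ zs.T  # one side shuffled over samples
        null_mi = _mi_from_rho(null_r)
        exceed += null_mi[iu, ju] >= obs
    p_perm = (1.0 + exceed) / (1.0 + n_perm)
    q = bh_adjust(p_perm)

    keep = q <= q_max
    adj: dict[int, set[int]] = {i: set() for i in range(p)}
    for a, b in zip(iu[keep], ju[keep]):
        adj[a].add(b)
        adj[b].add(a)

    rows = []
    for idx in np.where(keep)[0]:
        a, b = int(iu[idx]), int(ju[idx])
        common = adj[a] & adj[b]
        if common:
            cmi_min = min(
                _mi_from_rho(_partial_rho(r, a, b, k)) for k in common)
        else:
            cmi_min = float(mi[a, b])
        if common and cmi_min < dpi_epsilon * mi[a, b]:
            continue  # indirect association pruned
        rows.append((m.protein_ids[a], m.protein_ids[b], float(mi[a, b]),
                     float(cmi_min), float(p_perm[idx]), float(q[idx])))
    edges = pd.DataFrame(rows, columns=["source", "target", "mi", "cmi_min",
                                        "p_perm", "q"])
    return ProteinNetwork(nodes=list(m.protein_ids), edges=edges,
                          n_perm=n_perm, seed=seed)


def cluster_network(net: ProteinNetwork, m: AbundanceMatrix,
                    n_clusters: int = 20) -> ProteinNetwork:
    """Average-linkage hierarchical clustering on 1 - |Spearman rho|.

    The tree is cut at ``n_clusters``; labels are written into
    ``net.cluster_of``.  Deterministic given the inputs.
    """
    nodes = net.nodes
    if n_clusters < 2 or n_clusters > len(nodes):
        raise ValueError("n_clusters must be in [2, n_nodes]")
    data = m.imputed().loc[nodes].to_numpy(dtype=float)
    rho, _ = stats.spearmanr(data, axis=1)
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    linkage = hierarchy.linkage(squareform(dist, checks=False),
                                method="average")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    net.cluster_of = {node: int(lab) for node, lab in zip(nodes, labels)}
    return net


def cluster_enrichment(net: ProteinNetwork, hits: set,
                       background: set | None = None) -> pd.DataFrame:
    """Fisher enrichment of ``hits`` in every network cluster, BH across
    clusters."""
    if not net.cluster_of:
        raise ValueError("network has no cluster labels; run cluster_network")
    background = set(background) if background is not None else set(net.nodes)
    if not set(net.nodes) <= background:
        raise ValueError("background must contain all network nodes")
    clusters: dict[str, set] = {}
    for node, lab in net.cluster_of.items():
        clusters.setdefault(f"C{lab}", set()).add(node)
    return fisher_enrichment(set(hits) & background, clusters, background)


def to_networkx(net: ProteinNetwork) -> nx.Graph:
    g = nx.Graph()
    for node in net.nodes:
        g.add_node(node, cluster=net.cluster_of.get(node, -1))
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, mi=row.mi, cmi_min=row.cmi_min,
                   q=row.q)
    return g


def write_graphml(net: ProteinNetwork, path) -> None:
    nx.write_graphml(to_networkx(net), path)
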