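import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from plaqueomics.io_core import AbundanceMatrix, Fraction
from plaqueomics.network import (cluster_enrichment, cluster_network,
                                 gaussian_copula_cmi, reconstruct_network,
                                 to_networkx)


def _matrix(rows: dict) -> AbundanceMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return AbundanceMatrix(Fraction.GUHCL, df)


class TestCopulaCMI:
    def test_matches_gaussian_closed_form(self):
        rng = np.random.default_rng(0)
        rho, n = 0.5, 2000
        errs = []
        for _ in range(5):
            x = rng.standard_normal(n)
            y = rho * x + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            errs.append(gaussian_copula_cmi(x, y)
                        - (-0.5 * math.log1p(-rho ** 2)))
        assert abs(np.mean(errs)) < 0.02

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(1)
        small = 0
        for _ in range(50):
            mi = gaussian_copula_cmi(rng.standard_normal(500),
                                     rng.standard_normal(500))
            small += mi < 0.02
        assert small / 50 >= 0.9

    def test_conditional_independence_given_z(self):
        rng = np.random.default_rng(2)
        n = 2000
        z = rng.standard_normal(n)
        y = 0.9 * z + 0.3 * rng.standard_normal(n)
        x = rng.standard_normal(n)
        assert gaussian_copula_cmi(x, y, z) < 0.02

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = 0.6 * x + 0.8 * rng.standard_normal(500)
        base = gaussian_copula_cmi(x, y)
        assert gaussian_copula_cmi(np.exp(x), y) == pytest.approx(base)
        assert gaussian_copula_cmi(x, y ** 3) == pytest.approx(base)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            gaussian_copula_cmi(np.ones(20), np.arange(20.0))

    def test_too_few_observations_errors(self):
        with pytest.raises(ValueError, match="at least"):
            gaussian_copula_cmi(np.arange(5.0), np.arange(5.0))


class TestReconstructNetwork:
    def test_chain_prunes_indirect_edge(self):
        rng = np.random.default_rng(4)
        n, rho = 2000, 0.7
        x = rng.standard_normal(n)
        y = rho * x + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        z = rho * y + math.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        net = reconstruct_network(_matrix({"x": x, "y": y, "z": z}),
                                  n_perm=500, seed=0)
        edges = {frozenset((r.source, r.target))
                 for r in net.edges.itertuples(index=False)}
        assert edges == {frozenset(("x", "y")), frozenset(("y", "z"))}

    def test_null_matrix_controls_fdr(self):
        # all-independent proteins: kept-edge count stays near q_max * pairs
        total_kept = 0
        n_seeds = 20
        p = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(500 + s)
            rows = {f"P{i:02d}": rng.standard_normal(100) for i in range(p)}
            net = reconstruct_network(_matrix(rows), n_perm=200, q_max=0.05,
                                      seed=s)
            total_kept += len(net.edges)
        n_pairs = p * (p - 1) / 2
        assert total_kept / n_seeds <= 1.5 * 0.05 * n_pairs

    def test_duplicated_protein_edge_has_maximal_mi(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(200)
        rows = {"A": base, "B": base + 1e-9 * rng.standard_normal(200),
                "C": rng.standard_normal(200),
                "D": 0.5 * base + rng.standard_normal(200)}
        net = reconstruct_network(_matrix(rows), n_perm=200, seed=0)
        top = net.edges.sort_values("mi", ascending=False).iloc[0]
        assert {top["source"], top["target"]} == {"A", "B"}

    def test_too_few_permutations_error(self):
        rng = np.random.default_rng(7)
        rows = {c: rng.standard_normal(50) for c in "abc"}
        with pytest.raises(ValueError, match="n_perm"):
            reconstruct_network(_matrix(rows), n_perm=50)


class TestClusterNetwork:
    def _blocks(self, seed=8, n=200, within=0.8):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        lam = math.sqrt(within / (1 - within))
        rows = {}
        for i in range(5):
            rows[f"A{i}"] = lam * a + rng.standard_normal(n)
            rows[f"B{i}"] = lam * b + rng.standard_normal(n)
        return _matrix(rows)

    def test_two_planted_blocks_recovered_exactly(self):
        m = self._blocks()
        net = reconstruct_network(m, n_perm=200, seed=0)
        net = cluster_network(net, m, n_clusters=2)
        truth = [0 if p.startswith("A") else 1 for p in net.nodes]
        got = [net.cluster_of[p] for p in net.nodes]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_singletons_at_k_equal_nodes(self):
        m = self._blocks()
        net = reconstruct_network(m, n_perm=200, seed=0)
        net = cluster_network(net, m, n_clusters=len(net.nodes))
        assert len(set(net.cluster_of.values())) == len(net.nodes)

    def test_protein_order_invariance(self):
        m = self._blocks()
        net = cluster_network(reconstruct_network(m, n_perm=200, seed=0),
                              m, 2)
        m2 = AbundanceMatrix(m.fraction, m.data.iloc[::-1])
        net2 = cluster_network(reconstruct_network(m2, n_perm=200, seed=0),
                               m2, 2)
        a = [net.cluster_of[p] for p in sorted(net.cluster_of)]
        b = [net2.cluster_of[p] for p in sorted(net2.cluster_of)]
        assert adjusted_rand_score(a, b) == 1.0

    def test_k_larger_than_nodes_errors(self):
        m = self._blocks()
        net = reconstruct_network(m, n_perm=200, seed=0)
        with pytest.raises(ValueError):
            cluster_network(net, m, n_clusters=99)


class TestClusterEnrichment:
    def test_hits_matching_one_cluster_minimize_q(self):
        m = TestClusterNetwork()._blocks()
        net = cluster_network(reconstruct_network(m, n_perm=200, seed=0),
                              m, 2)
        a_members = {p for p in net.nodes if p.startswith("A")}
        out = cluster_enrichment(net, a_members)
        target = [f"C{lab}" for p, lab in net.cluster_of.items()
                  if p in a_members][0]
        assert out.set_index("cluster")["q"].idxmin() == target

    def test_empty_hits_all_p_one(self):
        m = TestClusterNetwork()._blocks()
        net = cluster_network(reconstruct_network(m, n_perm=200, seed=0),
                              m, 2)
        out = cluster_enrichment(net, set())
        assert (out["p"] == 1.0).all()

    def test_proteoglycan_block_clusters_together_and_is_sex_enriched(
            self, small_study):
        from plaqueomics.differential import (DesignSpec,
                                              differential_abundance)
        m = small_study.matrices["GuHCl"]
        net = reconstruct_network(m, n_perm=300, seed=0)
        net = cluster_network(net, m, n_clusters=8)
        pg = ["CSPG2", "PGCA", "HPLN1", "HPLN3"]
        labs = {net.cluster_of[p] for p in pg}
        assert len(labs) == 1
        res = differential_abundance(m, small_study.metadata,
                                     DesignSpec("sex", ["age", "statin"]))
        tab = res.table
        hits = set(tab.loc[tab["q"] < 0.05, "protein_id"])
        out = cluster_enrichment(net, hits)
        row = out[out["cluster"] == f"C{labs.pop()}"]
        assert row["q"].iloc[0] < 0.05


def test_networkx_export_carries_attributes():
    rng = np.random.default_rng(9)
    base = rng.standard_normal(100)
    rows = {"A": base + 0.1 * rng.standard_normal(100),
            "B": base + 0.1 * rng.standard_normal(100),
            "C": rng.standard_normal(100)}
    m = _matrix(rows)
    net = cluster_network(reconstruct_network(m, n_perm=200, seed=0), m, 2)
    g = to_networkx(net)
    assert set(g.nodes) == {"A", "B", "C"}
    assert g.has_edge("A", "B")
    assert "mi" in g.edges["A", "B"]
    assert all("cluster" in g.nodes[n] for n in g.nodes)
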