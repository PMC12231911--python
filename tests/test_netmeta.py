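"""Network construction, WLS synthesis, heterogeneity and FDR correction."""

import numpy as np
import pandas as pd
import pytest

from ifnsig.dge import ContrastEstimate
from ifnsig.netmeta import (
    COMPARISONS,
    NODES,
    adjust_fdr,
    build_network,
    estimate_tau2,
    nma_fixed,
    nma_random,
    run_network_meta,
)

from conftest import make_network, make_result


def brute_force_bh(pvals: np.ndarray) -> np.ndarray:
    """Step-up definition: q_i = min over j with p_(j) >= p_(i) of m p_(j)/j."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, m * pvals[idx] / (rank_from_top + 1))
        q[idx] = min(running, 1.0)
    return q


def dense_wls_oracle(edges: pd.DataFrame, variances: np.ndarray):
    """Reference-coded dense weighted least squares, solved with lstsq."""
    nodes = sorted(set(edges["a"]) | set(edges["b"]))
    ref = nodes[0]
    free = nodes[1:]
    x = np.zeros((len(edges), len(free)))
    for row, (a, b) in enumerate(zip(edges["a"], edges["b"])):
        if a != ref:
            x[row, free.index(a)] = 1.0
        if b != ref:
            x[row, free.index(b)] = -1.0
    w = 1.0 / variances
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(x * sw[:, None], edges["effect"].to_numpy() * sw,
                               rcond=None)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    theta = {ref: 0.0}
    theta.update({node: beta[i] for i, node in enumerate(free)})

    def pair(a, b):
        c = np.zeros(len(free))
        if a != ref:
            c[free.index(a)] = 1.0
        if b != ref:
            c[free.index(b)] = -1.0
        return theta[a] - theta[b], float(np.sqrt(c @ cov @ c))

    return pair


def random_connected_network(rng, max_edges=6):
    nodes = list(NODES)[: rng.integers(2, 5)]
    rows = []
    # spanning chain keeps the graph connected
    for i in range(len(nodes) - 1):
        rows.append((f"s{i}", nodes[i + 1], nodes[i],
                     rng.normal(0, 2), rng.uniform(0.1, 1.0)))
    while len(rows) < rng.integers(len(nodes) - 1, max_edges + 1):
        a, b = rng.choice(nodes, size=2, replace=False)
        rows.append((f"s{len(rows)}", a, b, rng.normal(0, 2),
                     rng.uniform(0.1, 1.0)))
    if not rows:  # two-node degenerate draw
        rows.append(("s0", nodes[1], nodes[0], rng.normal(), 0.5))
    return make_network(rows)


class TestBuildNetwork:
    def test_single_study_two_nodes_one_edge(self):
        contrasts = [ContrastEstimate("g", "s1", "IFNa", "control", 1.0, 0.3)]
        net = build_network(contrasts)
        assert set(net.nodes) == {"IFNa", "control"}
        assert len(net.edges) == 1

    def test_multiarm_study_reduced_to_control_basis_with_covariance(self):
        # shared control arm: cov(a,b) = (va + vb - vab) / 2
        contrasts = [
            ContrastEstimate("g", "s1", "IFNa", "control", 1.0, 0.5),
            ContrastEstimate("g", "s1", "IFNg", "control", 2.0, 0.5),
            ContrastEstimate("g", "s1", "IFNa", "IFNg", -1.0, 0.6),
            ContrastEstimate("g", "s1", "IFNg", "IFNa", 1.0, 0.6),
        ]
        net = build_network(contrasts)
        assert set(zip(net.edges["a"], net.edges["b"])) == {
            ("IFNa", "control"), ("IFNg", "control")
        }
        expected_cov = 0.5 * (0.25 + 0.25 - 0.36)
        assert net.covariance[0, 1] == pytest.approx(expected_cov)

    def test_disconnected_network_errors(self):
        contrasts = [
            ContrastEstimate("g", "s1", "IFNa", "control", 1.0, 0.3),
            ContrastEstimate("g", "s2", "IFNg", "IFNb", 1.0, 0.3),
        ]
        with pytest.raises(ValueError, match="disconnected"):
            build_network(contrasts)

    def test_discovery_availability_spans_all_four_nodes(self):
        studies = {
            "s1": ["IFNa", "IFNg"], "s2": ["IFNa", "IFNb", "IFNg"],
            "s3": ["IFNg"], "s4": ["IFNa"], "s5": ["IFNb"],
        }
        contrasts = []
        for study, arms in studies.items():
            for arm in arms:
                contrasts.append(
                    ContrastEstimate("g", study, arm, "control", 1.0, 0.4)
                )
            for i, a in enumerate(arms):
                for b in arms[i + 1:]:
                    contrasts.append(ContrastEstimate("g", study, a, b, 0.0, 0.5))
        net = build_network(contrasts)
        assert set(net.nodes) == set(NODES)
        # reduced basis: one control edge per arm per study
        assert len(net.edges) == 8


class TestFixedEffects:
    def test_saturated_single_edge_returns_direct_estimate(self):
        res = nma_fixed(make_network([("s1", "IFNa", "control", 1.2, 0.3)]))
        assert res.effect.loc["IFNa", "control"] == pytest.approx(1.2)
        assert res.se.loc["IFNa", "control"] == pytest.approx(0.3)

    def test_two_studies_inverse_variance_mean(self):
        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.5),
            ("s2", "IFNa", "control", 2.0, 0.5),
        ])
        res = nma_fixed(net)
        assert res.effect.loc["IFNa", "control"] == pytest.approx(1.5)
        assert res.se.loc["IFNa", "control"] == pytest.approx(0.5 / np.sqrt(2))

    def test_chain_gives_indirect_sum_with_additive_variance(self):
        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.1),
            ("s2", "IFNb", "IFNa", 2.0, 0.1),
        ])
        res = nma_fixed(net)
        assert res.effect.loc["IFNb", "control"] == pytest.approx(3.0)
        assert res.se.loc["IFNb", "control"] == pytest.approx(np.sqrt(0.02))

    def test_matches_dense_wls_oracle(self, rng):
        for _ in range(100):
            net = random_connected_network(rng)
            res = nma_fixed(net)
            pair = dense_wls_oracle(net.edges, net.edges["se"].to_numpy() ** 2)
            for a in net.nodes:
                for b in net.nodes:
                    if a == b:
                        continue
                    eff, se = pair(a, b)
                    assert res.effect.loc[a, b] == pytest.approx(eff, abs=1e-8)
                    assert res.se.loc[a, b] == pytest.approx(se, abs=1e-8)

    def test_adding_a_study_never_inflates_se(self, rng):
        for _ in range(20):
            net = random_connected_network(rng)
            res = nma_fixed(net)
            extra = net.edges.iloc[[0]].copy()
            extra["study"] = "extra"
            extra["se"] = rng.uniform(0.1, 2.0)
            bigger = make_network(
                list(pd.concat([net.edges, extra]).itertuples(index=False, name=None))
            )
            res2 = nma_fixed(bigger)
            a, b = extra.iloc[0]["a"], extra.iloc[0]["b"]
            assert res2.se.loc[a, b] <= res.se.loc[a, b] + 1e-12


class TestHeterogeneity:
    def test_identical_replicates_have_zero_tau2(self):
        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.5),
            ("s2", "IFNa", "control", 1.0, 0.5),
        ])
        assert estimate_tau2(net, nma_fixed(net)) == 0.0

    def test_tree_network_has_zero_tau2(self):
        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.5),
            ("s2", "IFNb", "IFNa", 2.0, 0.5),
        ])
        assert estimate_tau2(net, nma_fixed(net)) == 0.0

    def test_matches_scalar_dersimonian_laird(self):
        effects, se = np.array([0.0, 1.0, 2.0]), 0.5
        net = make_network([
            (f"s{i}", "IFNa", "control", e, se) for i, e in enumerate(effects)
        ])
        w = np.full(3, 1 / se**2)
        mean = np.sum(w * effects) / w.sum()
        q = np.sum(w * (effects - mean) ** 2)
        c = w.sum() - np.sum(w**2) / w.sum()
        expected = max(0.0, (q - 2) / c)
        assert estimate_tau2(net, nma_fixed(net)) == pytest.approx(expected)
        assert expected == pytest.approx(0.75)


class TestRandomEffects:
    def test_reduces_to_fixed_when_tau2_zero(self):
        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.5),
            ("s2", "IFNa", "control", 1.0, 0.5),
        ])
        fixed, random = nma_fixed(net), nma_random(net)
        assert random.tau2 == 0.0
        pd.testing.assert_frame_equal(fixed.effect, random.effect)
        pd.testing.assert_frame_equal(fixed.se, random.se)

    def test_heterogeneity_inflates_se(self):
        net = make_network([
            ("s1", "IFNa", "control", 0.0, 0.5),
            ("s2", "IFNa", "control", 1.0, 0.5),
            ("s3", "IFNa", "control", 2.0, 0.5),
        ])
        fixed, random = nma_fixed(net), nma_random(net)
        assert random.tau2 > 0
        assert (random.se.loc["IFNa", "control"]
                >= fixed.se.loc["IFNa", "control"])

    def test_externally_fixed_tau2_matches_weighted_mean_oracle(self):
        # two studies se 0.5, tau2 = 0.25: each inflated weight 1/0.5,
        # pooled se = sqrt(1 / sum w) = 0.5
        from ifnsig.netmeta import _solve_wls

        net = make_network([
            ("s1", "IFNa", "control", 1.0, 0.5),
            ("s2", "IFNa", "control", 2.0, 0.5),
        ])
        res = _solve_wls(net, net.covariance + 0.25 * np.eye(2), "random", 0.25)
        assert res.effect.loc["IFNa", "control"] == pytest.approx(1.5)
        assert res.se.loc["IFNa", "control"] == pytest.approx(0.5)

    def test_matches_dense_wls_oracle_with_inflated_variances(self, rng):
        for _ in range(100):
            net = random_connected_network(rng)
            res = nma_random(net)
            pair = dense_wls_oracle(
                net.edges, net.edges["se"].to_numpy() ** 2 + res.tau2
            )
            for a in net.nodes:
                for b in net.nodes:
                    if a != b:
                        eff, se = pair(a, b)
                        assert res.effect.loc[a, b] == pytest.approx(eff, abs=1e-8)
                        assert res.se.loc[a, b] == pytest.approx(se, abs=1e-8)


class TestRunNetworkMeta:
    def _contrast_table(self, rng, genes=5):
        rows = []
        for g in range(genes):
            rows += [
                (f"g{g}", "s1", "IFNa", "control", rng.normal(), 0.3),
                (f"g{g}", "s2", "IFNg", "control", rng.normal(), 0.4),
                (f"g{g}", "s2", "IFNa", "control", rng.normal(), 0.4),
            ]
        return pd.DataFrame(rows, columns=["gene", "study", "a", "b", "effect", "se"])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            run_network_meta(pd.DataFrame(columns=["gene", "study", "a", "b",
                                                   "effect", "se"]))

    def test_antisymmetry_and_triple_consistency(self, rng):
        results = run_network_meta(self._contrast_table(rng), model="random")
        for r in results:
            eff = r.effect.to_numpy()
            mask = np.isfinite(eff)
            assert (mask == mask.T).all()
            np.testing.assert_allclose(eff[mask], -eff.T[mask], atol=1e-12)
            nodes = [n for n in NODES if np.isfinite(r.effect.loc[n, n])]
            for a in nodes:
                for b in nodes:
                    for c in nodes:
                        assert r.effect.loc[a, c] == pytest.approx(
                            r.effect.loc[a, b] + r.effect.loc[b, c], abs=1e-10
                        )

    def test_disconnected_genes_are_skipped(self, rng):
        table = self._contrast_table(rng, genes=2)
        bad = pd.DataFrame(
            [("lonely", "s9", "IFNg", "IFNb", 1.0, 0.5),
             ("lonely", "s8", "IFNa", "control", 1.0, 0.5)],
            columns=table.columns,
        )
        results = run_network_meta(pd.concat([table, bad]), model="fixed")
        assert {r.gene for r in results} == {"g0", "g1"}

    def test_matches_per_gene_dense_oracle(self, rng):
        table = self._contrast_table(rng)
        results = run_network_meta(table, model="fixed")
        for r in results:
            edges = table[table["gene"] == r.gene]
            pair = dense_wls_oracle(edges, edges["se"].to_numpy() ** 2)
            eff, se = pair("IFNg", "IFNa")
            assert r.effect.loc["IFNg", "IFNa"] == pytest.approx(eff, abs=1e-8)
            assert r.se.loc["IFNg", "IFNa"] == pytest.approx(se, abs=1e-8)


class TestAdjustFdr:
    def _results_with_p(self, pvals, comparison=("IFNa", "control")):
        results = []
        for i, p in enumerate(pvals):
            r = make_result(f"g{i}", {})
            r.p.loc[:, :] = np.nan
            r.p.loc[comparison[0], comparison[1]] = p
            r.p.loc[comparison[1], comparison[0]] = p
            results.append(r)
        return results

    def test_worked_example(self):
        results = adjust_fdr(self._results_with_p([0.01, 0.02, 0.03, 0.04]))
        qs = [r.fdr.loc["IFNa", "control"] for r in results]
        np.testing.assert_allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_single_gene_q_equals_p(self):
        results = adjust_fdr(self._results_with_p([0.037]))
        assert results[0].fdr.loc["IFNa", "control"] == pytest.approx(0.037)
        assert results[0].fdr.loc["control", "IFNa"] == pytest.approx(0.037)

    def test_equal_pvalues_are_a_fixed_point(self):
        results = adjust_fdr(self._results_with_p([0.2] * 7))
        for r in results:
            assert r.fdr.loc["IFNa", "control"] == pytest.approx(0.2)

    def test_matches_brute_force_step_up(self, rng):
        # 17 batches x 6 independent comparisons = 102 random p-vectors
        for _ in range(17):
            drawn = {c: rng.uniform(size=500) for c in COMPARISONS}
            results = []
            for i in range(500):
                r = make_result(f"g{i}", {})
                r.p.loc[:, :] = np.nan
                for (a, b), pvals in drawn.items():
                    r.p.loc[a, b] = r.p.loc[b, a] = pvals[i]
                results.append(r)
            adjust_fdr(results)
            for (a, b), pvals in drawn.items():
                got = np.array([r.fdr.loc[a, b] for r in results])
                np.testing.assert_allclose(got, brute_force_bh(pvals), atol=1e-12)

    def test_comparisons_are_corrected_independently(self, rng):
        results = []
        for i in range(50):
            r = make_result(f"g{i}", {})
            for a, b in COMPARISONS:
                p = rng.uniform()
                r.p.loc[a, b] = p
                r.p.loc[b, a] = p
            results.append(r)
        adjust_fdr(results)
        for a, b in COMPARISONS:
            pvals = np.array([r.p.loc[a, b] for r in results])
            got = np.array([r.fdr.loc[a, b] for r in results])
            np.testing.assert_allclose(got, brute_force_bh(pvals), atol=1e-12)
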