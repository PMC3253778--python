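"""Benchmark machinery: AUC, tIDR/tIRR, motifs, edge ensembles, CAT."""

import itertools

import networkx as nx
import numpy as np
import pytest

from grnmeta import (
    DataError,
    Edge,
    GeneNetwork,
    InferredEnsemble,
    cat_curve,
    compare_auc_samples,
    edge_ensemble_report,
    enumerate_motifs,
    hub_ranked_list,
    motif_reconstruction_rate,
    roc_auc,
    tidr,
    tirr,
)
from grnmeta.datatypes import all_pairs, pair_key
from grnmeta.evaluate import colour_of


def _full_table(factory, genes, high_pairs, method="rn", p_for_high=1e-15):
    """Score table over all pairs; high_pairs score 1/p small, rest 0/p=1."""
    pairs = all_pairs(genes)
    high = {pair_key(*p) for p in high_pairs}
    scores = [1.0 if p in high else 0.0 for p in pairs]
    ps = [p_for_high if p in high else 1.0 for p in pairs]
    return factory(pairs, scores, p_values=ps, method=method)


@pytest.fixture
def truth():
    return GeneNetwork(
        ["a", "b", "c", "d"], [Edge("a", "b"), Edge("b", "c"), Edge("b", "d")]
    )


class TestRocAuc:
    def test_perfect_ranking(self, truth, score_table_factory):
        t = _full_table(score_table_factory, truth.genes, truth.skeleton())
        assert roc_auc(t, truth) == 1.0

    def test_reversed_ranking(self, truth, score_table_factory):
        pairs = all_pairs(truth.genes)
        skel = truth.skeleton()
        scores = [0.0 if p in skel else 1.0 for p in pairs]
        t = score_table_factory(pairs, scores)
        assert roc_auc(t, truth) == 0.0

    def test_random_scores_near_half(self, score_table_factory):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        net = GeneNetwork(genes, [Edge("g0", "g1"), Edge("g2", "g3"), Edge("g4", "g5")])
        pairs = all_pairs(genes)
        aucs = [
            roc_auc(score_table_factory(pairs, rng.uniform(size=len(pairs))), net)
            for _ in range(200)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_truth_rejected(self, score_table_factory):
        net = GeneNetwork(["a", "b"], [])
        t = score_table_factory([("a", "b")], [1.0])
        with pytest.raises(DataError, match="AUC undefined"):
            roc_auc(t, net)


class TestTidrTirr:
    def test_set_arithmetic_example(self, truth, score_table_factory):
        # T = {ab, bc, bd}; M = {ab, bc}; union I = {bc}
        meta = _full_table(score_table_factory, truth.genes, [("a", "b"), ("b", "c")], "ftcct")
        single = _full_table(score_table_factory, truth.genes, [("b", "c")])
        singles = InferredEnsemble([single])
        assert tidr(meta, singles, truth) == pytest.approx(1 / 3)
        assert tirr(meta, singles, truth) == 0.0

    def test_disjoint_discoveries(self, truth, score_table_factory):
        meta = _full_table(score_table_factory, truth.genes, [("a", "b")], "ftcct")
        single = _full_table(score_table_factory, truth.genes, [("b", "c")])
        singles = InferredEnsemble([single])
        assert tidr(meta, singles, truth) == pytest.approx(1 / 3)
        assert tirr(meta, singles, truth) == pytest.approx(1 / 3)

    def test_empty_meta_and_full_novelty_limits(self, truth, score_table_factory):
        empty = _full_table(score_table_factory, truth.genes, [], "ftcct")
        full = _full_table(score_table_factory, truth.genes, truth.skeleton(), "ftcct")
        nothing = InferredEnsemble([_full_table(score_table_factory, truth.genes, [])])
        assert tidr(empty, nothing, truth) == 0.0
        assert tidr(full, nothing, truth) == 1.0
        assert tirr(full, nothing, truth) == 0.0

    def test_rates_are_disjoint_fractions(self, truth, score_table_factory):
        meta = _full_table(score_table_factory, truth.genes, [("a", "b"), ("b", "d")], "ftcct")
        single = _full_table(score_table_factory, truth.genes, [("b", "c"), ("b", "d")])
        singles = InferredEnsemble([single])
        assert tidr(meta, singles, truth) + tirr(meta, singles, truth) <= 1.0


def _brute_force_motifs(net: GeneNetwork):
    """Oracle: classify each triple from its induced digraph via networkx."""
    g = net.to_networkx()
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for triple in itertools.combinations(net.genes, 3):
        sub = g.subgraph(triple)
        n_e = sub.number_of_edges()
        degs = sorted((sub.in_degree(v), sub.out_degree(v)) for v in triple)
        if n_e == 2:
            if degs == [(0, 1), (0, 1), (2, 0)]:
                counts[2] += 1
            elif degs == [(0, 2), (1, 0), (1, 0)]:
                counts[3] += 1
            elif degs == [(0, 1), (1, 0), (1, 1)]:
                counts[1] += 1
        elif n_e == 3 and nx.is_directed_acyclic_graph(sub):
            if degs == [(0, 2), (1, 1), (2, 0)]:
                counts[4] += 1
    return counts


class TestEnumerateMotifs:
    def test_chain(self):
        net = GeneNetwork(["a", "b", "c"], [Edge("a", "b"), Edge("b", "c")])
        assert enumerate_motifs(net).counts == {1: 1, 2: 0, 3: 0, 4: 0}

    def test_collider(self):
        net = GeneNetwork(["a", "b", "c"], [Edge("a", "c"), Edge("b", "c")])
        assert enumerate_motifs(net).counts == {1: 0, 2: 1, 3: 0, 4: 0}

    def test_fork(self):
        net = GeneNetwork(["a", "b", "c"], [Edge("b", "a"), Edge("b", "c")])
        assert enumerate_motifs(net).counts == {1: 0, 2: 0, 3: 1, 4: 0}

    def test_triangle(self):
        net = GeneNetwork(
            ["a", "b", "c"], [Edge("a", "b"), Edge("b", "c"), Edge("a", "c")]
        )
        assert enumerate_motifs(net).counts == {1: 0, 2: 0, 3: 0, 4: 1}

    def test_matches_brute_force_oracle_on_random_dags(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            genes = [f"g{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        edges.append(Edge(genes[i], genes[j]))
            net = GeneNetwork(genes, edges)
            assert enumerate_motifs(net).counts == _brute_force_motifs(net)


class TestMotifReconstruction:
    def test_perfect_inference_scores_one(self, score_table_factory):
        net = GeneNetwork(
            ["a", "b", "c"], [Edge("a", "b"), Edge("b", "c"), Edge("a", "c")]
        )
        perfect = _full_table(score_table_factory, net.genes, net.skeleton())
        report = motif_reconstruction_rate(InferredEnsemble([perfect] * 3), net)
        assert report.rates[4] == 1.0

    def test_empty_inference_limits(self, truth, score_table_factory):
        empty = _full_table(score_table_factory, truth.genes, [])
        report = motif_reconstruction_rate(InferredEnsemble([empty]), truth)
        # truth a->b->c, b->d: two chains (a,b,c and a,b,d), one fork (c<-b->d)
        assert report.counts[1] == 2 and report.counts[3] == 1
        for mtype in (1, 3):
            assert report.rates[mtype] == pytest.approx(0.5)  # TPR 0, TNR 1

    def test_absent_motif_type_reports_zero(self, truth, score_table_factory):
        t = _full_table(score_table_factory, truth.genes, truth.skeleton())
        report = motif_reconstruction_rate(InferredEnsemble([t]), truth)
        assert report.counts[4] == 0 and report.rates[4] == 0.0


class TestEdgeEnsemble:
    def test_colour_bin_boundaries(self):
        assert colour_of(0.0) == "red"
        assert colour_of(0.25) == "red"
        assert colour_of(0.5) == "green"
        assert colour_of(0.75) == "blue"  # black requires TPR > 0.75
        assert colour_of(0.76) == "black"
        assert colour_of(1.0) == "black"

    def test_always_and_never_recovered(self, truth, score_table_factory):
        hit = _full_table(score_table_factory, truth.genes, [("a", "b")])
        ens = InferredEnsemble([hit] * 4)
        report = edge_ensemble_report(ens, truth)
        by_pair = report.edges.set_index(["regulator", "target"])
        assert by_pair.loc[("a", "b"), "colour"] == "black"
        assert by_pair.loc[("b", "c"), "colour"] == "red"

    def test_exact_three_quarters_is_blue(self, truth, score_table_factory):
        hit = _full_table(score_table_factory, truth.genes, [("a", "b")])
        miss = _full_table(score_table_factory, truth.genes, [])
        report = edge_ensemble_report(InferredEnsemble([hit] * 3 + [miss]), truth)
        row = report.edges.set_index(["regulator", "target"]).loc[("a", "b")]
        assert row["mean_tpr"] == pytest.approx(0.75)
        assert row["colour"] == "blue"

    def test_tally_percentages_sum_to_hundred(self, truth, score_table_factory):
        hit = _full_table(score_table_factory, truth.genes, [("a", "b"), ("b", "c")])
        tally = edge_ensemble_report(InferredEnsemble([hit]), truth).tally()
        net_pct = tally[tally["scope"] == "network"]["pct_scope"].sum()
        assert net_pct == pytest.approx(100.0, abs=0.1)


class TestHubRanking:
    def test_master_excluded_and_strongest_first(self, score_table_factory):
        pairs = [("m", "x"), ("m", "y"), ("m", "z"), ("x", "y"), ("x", "z"), ("y", "z")]
        t = score_table_factory(
            pairs,
            [0.9, 0.5, 0.1, 0.3, 0.3, 0.3],
            p_values=[1e-8, 1e-4, 0.5, 0.9, 0.9, 0.9],
        )
        ranked = hub_ranked_list(t, "m")
        assert ranked == ["x", "y", "z"]
        assert "m" not in ranked

    def test_ties_broken_by_effect_then_id(self, score_table_factory):
        pairs = [("m", "w"), ("m", "x"), ("m", "y"), ("m", "z")]
        t = score_table_factory(
            pairs,
            scores=[0.2, 0.8, 0.8, 0.2],
            effects=[-0.2, 0.8, -0.8, 0.2],
            p_values=[0.01, 0.01, 0.01, 0.01],
        )
        # equal p: |effect| 0.8 beats 0.2; within each, lexicographic id
        assert hub_ranked_list(t, "m") == ["x", "y", "w", "z"]

    def test_unknown_master_rejected(self, score_table_factory):
        t = score_table_factory([("a", "b")], [1.0])
        with pytest.raises(DataError, match="master"):
            hub_ranked_list(t, "q")


class TestCatCurve:
    def test_identical_lists_agree_everywhere(self):
        lst = [f"g{i}" for i in range(10)]
        curve = cat_curve(lst, list(lst), n_max=10)
        np.testing.assert_allclose(curve.agreement, 1.0)

    def test_disjoint_prefixes(self):
        a = ["a1", "a2", "a3", "b1", "b2", "b3"]
        b = ["b1", "b2", "b3", "a1", "a2", "a3"]
        curve = cat_curve(a, b, n_max=6)
        np.testing.assert_allclose(curve.agreement[:3], 0.0)
        assert curve.agreement[5] == pytest.approx(1.0)

    def test_hand_example_swapped_halves(self):
        curve = cat_curve(["g1", "g2", "g3", "g4"], ["g3", "g4", "g1", "g2"], n_max=4)
        assert curve.agreement[1] == 0.0  # n = 2
        assert curve.agreement[3] == 1.0  # n = 4
        assert curve.mode == "meta"

    def test_individual_mode_averages_reference_overlap(self):
        a = ["g1", "g2"]
        b = ["g3", "g4"]
        ref = ["g1", "g3"]
        curve = cat_curve(a, b, reference=ref, n_max=2)
        # n=2: a overlaps ref in {g1}, b in {g3} -> (1+1)/2/2 = 0.5
        assert curve.agreement[1] == pytest.approx(0.5)
        assert curve.mode == "individual"

    def test_short_lists_truncate_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            curve = cat_curve(["a", "b"], ["a", "c"], n_max=10)
        assert curve.n[-1] == 2


class TestCompareAuc:
    def test_identical_samples_not_significant(self):
        p = compare_auc_samples([0.7, 0.8, 0.9, 0.75], [0.7, 0.8, 0.9, 0.75])
        assert p > 0.99

    def test_strong_offset_detected(self, rng):
        a = rng.normal(0.8, 0.01, size=24)
        b = rng.normal(0.7, 0.01, size=24)
        assert compare_auc_samples(a, b) < 1e-4

    def test_small_samples_rejected(self):
        with pytest.raises(DataError):
            compare_auc_samples([0.5, 0.6], [0.7, 0.8, 0.9])

    def test_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0.75, 0.05, size=8)
        b = rng.normal(0.70, 0.05, size=8)
        p_rank = compare_auc_samples(a, b)
        # permutation test on the rank-sum statistic
        combined = np.concatenate([a, b])
        centre = len(a) * (len(combined) - 1) / 2  # mean rank-sum, 0-based ranks
        obs = np.sum(np.argsort(np.argsort(combined))[: len(a)])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(combined)
            s = np.sum(np.argsort(np.argsort(perm))[: len(a)])
            count += abs(s - centre) >= abs(obs - centre) - 1e-9
        p_perm = count / n_perm
        assert 0.5 * p_perm <= p_rank <= 2.0 * p_perm or p_rank > 0.2
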