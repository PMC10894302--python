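"""Cluster-based and network-based drug-class recommendation."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from transdx.prescriptions import PrescriptionRecord
from transdx.profiling import ClusterAssignment, SimilarityGraph
from transdx.recommendation import (
    cluster_based_recommend,
    cluster_class_probability,
    cluster_prescription_rate,
    evaluate_recommendations,
    network_based_recommend,
)


def _rx(mapping: dict[str, set[str]]) -> list[PrescriptionRecord]:
    return [
        PrescriptionRecord(s, tuple(sorted(c)), frozenset(c)) for s, c in mapping.items()
    ]


def _assignment(labels):
    labels = np.asarray(labels)
    return ClusterAssignment(
        method="kmeans",
        subject_ids=[f"P{i:03d}" for i in range(len(labels))],
        labels=labels,
    )


def _line_graph(n: int) -> SimilarityGraph:
    """Path graph P000 - P001 - ... for hand-traceable rings."""
    ids = [f"P{i:03d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(zip(ids, ids[1:]))
    return SimilarityGraph(node_ids=ids, graph=g, k_nn=1, p=2)


def _star_rings(ring_sizes: list[int]) -> tuple[SimilarityGraph, list[list[str]]]:
    """Graph with a center C and concentric rings: every ring-r node links
    to every ring-(r-1) node, so BFS rings from C are exactly the layers."""
    g = nx.Graph()
    g.add_node("C")
    rings, prev = [], ["C"]
    counter = 0
    for size in ring_sizes:
        ring = [f"R{counter + i:03d}" for i in range(size)]
        counter += size
        for node in ring:
            for parent in prev:
                g.add_edge(parent, node)
        rings.append(ring)
        prev = ring
    return SimilarityGraph(node_ids=["C"] + [n for r in rings for n in r], graph=g, k_nn=1, p=2), rings


class TestClusterRates:
    def test_labeled_ratio_per_cluster(self):
        assignment = _assignment([0] * 10 + [1] * 5)
        rx = _rx({"P000": {"AD"}, "P001": {"SH"}, "P002": {"AD", "MS"}})
        table = cluster_prescription_rate(assignment, rx)
        rate = dict(zip(table["cluster"], table["rate"]))
        assert rate[0] == pytest.approx(0.30)
        assert rate[1] == 0.0
        assert rate[-1] == pytest.approx(3 / 15)  # overall row

    def test_no_labels_gives_zero_everywhere_and_full_labels_one(self):
        assignment = _assignment([0, 0, 1, 1])
        empty = cluster_prescription_rate(assignment, [])
        assert (empty[empty.cluster >= 0]["rate"] == 0).all()
        full = cluster_prescription_rate(
            assignment, _rx({f"P{i:03d}": {"AD"} for i in range(4)})
        )
        assert (full["rate"] == 1.0).all()


class TestClassProbability:
    def test_multiclass_members_count_per_class(self):
        assignment = _assignment([0, 0, 0, 0])
        rx = _rx({"P000": {"AD"}, "P001": {"AD"}, "P002": {"AD", "SH"}})
        table = cluster_class_probability(assignment, rx)
        assert table.loc[0, "AD"] == pytest.approx(1.0)
        assert table.loc[0, "SH"] == pytest.approx(1 / 3)
        assert table.loc[0, "AP"] == 0.0

    def test_zero_labeled_cluster_is_missing_with_warning(self, caplog):
        assignment = _assignment([0, 0, 1, 1])
        rx = _rx({"P000": {"MS"}})
        import logging

        with caplog.at_level(logging.WARNING):
            table = cluster_class_probability(assignment, rx)
        assert table.loc[0, "MS"] == 1.0
        assert table.loc[1].isna().all()
        assert any("no labeled members" in rec.getMessage() for rec in caplog.records)


class TestClusterEngine:
    def test_threshold_one_takes_argmax(self):
        assignment = _assignment([0, 0])
        rx = _rx({"P000": {"AD"}, "P001": {"AD", "SH"}})
        # probs: AD 1.0, SH 0.5
        table = cluster_class_probability(assignment, rx)
        rec = cluster_based_recommend("P001", assignment, table, rank_threshold=1)
        assert rec.recommended == frozenset({"AD"})

    def test_tied_top_probabilities_share_rank_one(self):
        assignment = _assignment([0, 0, 0, 0])
        rx = _rx(
            {"P000": {"AD"}, "P001": {"SH"}, "P002": {"AD", "SH", "AP"}, "P003": set()}
        )
        table = cluster_class_probability(assignment, rx)
        rec = cluster_based_recommend("P000", assignment, table, rank_threshold=1)
        assert rec.recommended == frozenset({"AD", "SH"})
        ranks = {cls: rank for cls, _, _, rank in rec.ranked}
        assert ranks["AD"] == ranks["SH"] == 1 and ranks["AP"] == 3

    def test_same_recommendation_for_all_members(self):
        assignment = _assignment([0, 0, 1, 1])
        rx = _rx({"P000": {"AD"}, "P002": {"MS"}})
        table = cluster_class_probability(assignment, rx)
        a = cluster_based_recommend("P000", assignment, table)
        b = cluster_based_recommend("P001", assignment, table)
        assert a.recommended == b.recommended

    def test_zero_labeled_cluster_directs_to_network_engine(self):
        assignment = _assignment([0, 0, 1, 1])
        table = cluster_class_probability(assignment, _rx({"P000": {"AD"}}))
        with pytest.raises(ValueError, match="network_based_recommend"):
            cluster_based_recommend("P002", assignment, table)


class TestNetworkEngine:
    def test_default_min_labeled_is_twenty(self):
        import inspect

        sig = inspect.signature(network_based_recommend)
        assert sig.parameters["min_labeled"].default == 20

    def test_whole_rings_stop_rule_hand_traceable(self):
        # ring 1: 8 nodes, 5 labeled; ring 2: 25 nodes, 18 labeled
        g, rings = _star_rings([8, 25, 6])
        labeled = {n: {"AD"} for n in rings[0][:5]}
        labeled.update({n: {"SH"} for n in rings[1][:18]})
        labeled.update({n: {"MS"} for n in rings[2]})  # never reached
        rec = network_based_recommend("C", g, _rx(labeled), min_labeled=20)
        assert rec.rings_expanded == 2
        assert rec.neighborhood_labeled == 23
        assert rec.neighborhood_total == 33
        assert "MS" not in {cls for cls, *_ in rec.ranked}

    def test_tie_for_top_count_recommends_both(self):
        g, rings = _star_rings([25])
        labeled = {n: {"AD"} for n in rings[0][:10]}
        labeled.update({n: {"SH"} for n in rings[0][10:20]})
        rec = network_based_recommend("C", g, _rx(labeled), min_labeled=20)
        assert rec.recommended == frozenset({"AD", "SH"})
        assert all(rank == 1 for _, _, _, rank in rec.ranked)

    def test_unanimous_class_is_sole_recommendation(self):
        g, rings = _star_rings([30])
        labeled = {n: {"AD"} for n in rings[0][:22]}
        rec = network_based_recommend("C", g, _rx(labeled))
        assert rec.recommended == frozenset({"AD"})
        assert len(rec.ranked) == 1

    def test_component_exhausted_flags_quota_unmet(self):
        g = _line_graph(4)
        rec = network_based_recommend(
            "P000", g, _rx({"P003": {"MS"}}), min_labeled=20
        )
        assert "quota_unmet" in rec.flags
        assert rec.neighborhood_labeled == 1
        assert rec.recommended == frozenset({"MS"})

    def test_component_without_labels_errors(self):
        g = _line_graph(3)
        with pytest.raises(ValueError, match="no labeled"):
            network_based_recommend("P000", g, _rx({}), min_labeled=5)

    def test_own_prescriptions_excluded_from_tally(self):
        g = _line_graph(3)
        rec = network_based_recommend(
            "P001", g, _rx({"P001": {"AP"}, "P000": {"AD"}, "P002": {"AD"}}), min_labeled=2
        )
        assert rec.recommended == frozenset({"AD"})

    def test_min_labeled_monotone_in_neighborhood_size(self):
        rng = np.random.default_rng(7)
        g_nx = nx.gnp_random_graph(120, 0.05, seed=3)
        ids = [f"P{i:03d}" for i in range(120)]
        g = SimilarityGraph(
            ids, nx.relabel_nodes(g_nx, dict(enumerate(ids))), k_nn=6, p=2
        )
        rx = _rx({i: {"AD"} for i in rng.choice(ids, 40, replace=False)})
        prev = 0
        for quota in (1, 5, 10, 20, 30):
            rec = network_based_recommend(ids[0], g, rx, min_labeled=quota)
            assert rec.neighborhood_total >= prev
            prev = rec.neighborhood_total


def brute_force_network_recommend(subject, graph: nx.Graph, classes_of, min_labeled, rank_threshold):
    """Independent oracle: shortest-path rings + explicit counting."""
    dist = nx.single_source_shortest_path_length(graph, subject)
    max_r = max(dist.values()) if dist else 0
    neighborhood, labeled = [], 0
    rings = 0
    for r in range(1, max_r + 1):
        ring = [n for n, d in dist.items() if d == r]
        if not ring:
            break
        neighborhood += ring
        labeled += sum(1 for n in ring if n in classes_of)
        rings = r
        if labeled >= min_labeled:
            break
    if labeled == 0:
        raise ValueError("no labeled members")
    from collections import Counter

    counts: Counter = Counter()
    for n in neighborhood:
        if n in classes_of and n != subject:
            counts.update(classes_of[n])
    ordered = sorted(counts.items(), key=lambda t: (-t[1], t[0]))
    recommended, rank = set(), 0
    for i, (cls, c) in enumerate(ordered):
        rank = i + 1 if i == 0 or c != ordered[i - 1][1] else rank
        if rank <= rank_threshold:
            recommended.add(cls)
    return recommended, labeled, rings, len(neighborhood)


@pytest.mark.parametrize("seed", range(10))
def test_network_engine_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 150))
    ids = [f"P{i:03d}" for i in range(n)]
    g_nx = nx.relabel_nodes(
        nx.gnp_random_graph(n, float(rng.uniform(0.02, 0.15)), seed=seed),
        dict(enumerate(ids)),
    )
    g = SimilarityGraph(ids, g_nx, k_nn=5, p=2)
    frac = float(rng.uniform(0.1, 0.5))
    classes_of = {}
    for i in ids:
        if rng.random() < frac:
            k = int(rng.integers(1, 4))
            classes_of[i] = set(rng.choice(["AD", "AP", "MS", "SH"], k, replace=False))
    rx = _rx(classes_of)
    quota = int(rng.choice([1, 5, 20]))
    for subject in rng.choice(ids, 10, replace=False):
        subject = str(subject)
        try:
            expected = brute_force_network_recommend(subject, g_nx, classes_of, quota, 3)
        except ValueError:
            with pytest.raises(ValueError):
                network_based_recommend(subject, g, rx, min_labeled=quota)
            continue
        rec = network_based_recommend(subject, g, rx, min_labeled=quota)
        assert rec.recommended == expected[0]
        assert rec.neighborhood_labeled == expected[1]
        assert rec.rings_expanded == expected[2]
        assert rec.neighborhood_total == expected[3]


class TestEvaluation:
    def test_hit_and_exact_flags(self):
        g, rings = _star_rings([10])
        labeled = {n: {"AD"} for n in rings[0][:5]}
        labeled["C"] = {"AD"}
        rec = network_based_recommend("C", g, _rx(labeled), min_labeled=3)
        report = evaluate_recommendations([rec], _rx(labeled))
        assert report["hit_rate"] == 1.0
        assert report["exact_match_rate"] == 1.0

    def test_disjoint_recommendation_is_no_hit(self):
        g, rings = _star_rings([10])
        labeled = {n: {"AD", "SH"} for n in rings[0][:5]}
        labeled["C"] = {"MS"}
        rec = network_based_recommend("C", g, _rx(labeled), min_labeled=3)
        report = evaluate_recommendations([rec], _rx(labeled))
        assert report["hit_rate"] == 0.0

    def test_size_distribution_hand_counted(self):
        recs = []
        g, rings = _star_rings([30])
        labelings = [
            {n: {"AD"} for n in rings[0][:6]},  # -> 1 class
            {n: {"AD"} for n in rings[0][:6]},
            dict(
                {n: {"AD"} for n in rings[0][:3]},
                **{n: {"SH"} for n in rings[0][3:6]},
            ),  # tie -> 2 classes
            dict(
                {n: {"AD"} for n in rings[0][:2]},
                **{n: {"SH"} for n in rings[0][2:4]},
                **{n: {"MS"} for n in rings[0][4:6]},
            ),  # -> 3 classes
        ]
        for labeling in labelings:
            labeling["C"] = {"AD"}
            recs.append(network_based_recommend("C", g, _rx(labeling), min_labeled=5))
        report = evaluate_recommendations(recs, _rx({"C": {"AD"}}))
        assert report["size_distribution"] == {1: 0.5, 2: 0.25, 3: 0.25}

    def test_unlabeled_subject_rejected(self):
        g, rings = _star_rings([10])
        labeled = {n: {"AD"} for n in rings[0][:5]}
        rec = network_based_recommend("C", g, _rx(labeled), min_labeled=3)
        with pytest.raises(ValueError, match="without prescriptions"):
            evaluate_recommendations([rec], _rx(labeled))
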