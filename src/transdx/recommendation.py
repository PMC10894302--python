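"""Drug-class recommendation engines and their evaluation.

Two engines operate on the same inputs (a clustering or a patient
similarity graph, plus the sparse prescription table):

* cluster-based: every member of a cluster receives the classes with the
  highest prescription probability among the cluster's labeled members;
* network-based: each subject's neighborhood on the kNN graph is grown
  ring by ring (breadth-first) until it holds at least ``min_labeled``
  subjects with prescription history (default 20); classes are then
  ranked by prescription count within that adaptive neighborhood.

Ranking is competition-style: tied classes share a rank and are
recommended together, so a rank threshold of 3 can return more than
three classes ("the three most commonly recommended" with ties).
Zero-count classes are never recommended. The target subject's own
prescriptions are excluded from its neighborhood tally.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from transdx.prescriptions import DEFAULT_CLASS_VOCABULARY, PrescriptionRecord, labeled_classes
from transdx.profiling import ClusterAssignment, SimilarityGraph

logger = logging.getLogger(__name__)

DEFAULT_MIN_LABELED = 20
DEFAULT_RANK_THRESHOLD = 3


@dataclass
class Recommendation:
    """Ranked drug classes for one subject with neighborhood provenance."""

    subject_id: str
    ranked: list[tuple[str, int, float, int]]  # (class, count, frequency, rank)
    recommended: frozenset[str]
    neighborhood_total: int = 0
    neighborhood_labeled: int = 0
    rings_expanded: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


def _competition_rank(counts: dict[str, float]) -> list[tuple[str, float, int]]:
    """Competition ranking (1224): tied values share a rank and the next
    rank is offset by the tie-group size. Zero-count classes excluded;
    ties listed in class-name order for display."""
    nonzero = [(cls, c) for cls, c in counts.items() if c > 0]
    nonzero.sort(key=lambda t: (-t[1], t[0]))
    out: list[tuple[str, float, int]] = []
    for i, (cls, c) in enumerate(nonzero):
        rank = i + 1 if (i == 0 or c != nonzero[i - 1][1]) else out[-1][2]
        out.append((cls, c, rank))
    return out


def cluster_prescription_rate(
    assignment: ClusterAssignment, prescriptions: list[PrescriptionRecord]
) -> pd.DataFrame:
    """Fraction of labeled subjects per cluster (plus an overall row)."""
    label_of = assignment.label_of()
    labeled = set(labeled_classes(prescriptions))
    unknown = labeled - set(assignment.subject_ids)
    if unknown:
        raise ValueError(f"prescriptions for subjects outside the assignment: {sorted(unknown)[:5]}")
    rows = []
    for cluster in range(assignment.n_clusters):
        members = [s for s, c in label_of.items() if c == cluster]
        n_lab = sum(1 for s in members if s in labeled)
        rows.append(
            {
                "cluster": cluster,
                "size": len(members),
                "labeled": n_lab,
                "rate": n_lab / len(members) if members else 0.0,
            }
        )
    overall = {
        "cluster": -1,
        "size": len(assignment.subject_ids),
        "labeled": len(labeled),
        "rate": len(labeled) / len(assignment.subject_ids),
    }
    return pd.DataFrame(rows + [overall])


def cluster_class_probability(
    assignment: ClusterAssignment,
    prescriptions: list[PrescriptionRecord],
    vocabulary: tuple[str, ...] = DEFAULT_CLASS_VOCABULARY,
) -> pd.DataFrame:
    """P(class | cluster) among the cluster's labeled members.

    A labeled member holding several classes counts toward each. Clusters
    with zero labeled members get NaN probabilities (with a warning).
    Returns a cluster x class DataFrame.
    """
    label_of = assignment.label_of()
    classes_of = labeled_classes(prescriptions)
    table = np.full((assignment.n_clusters, len(vocabulary)), np.nan)
    for cluster in range(assignment.n_clusters):
        members = [s for s, c in label_of.items() if c == cluster]
        lab = [s for s in members if s in classes_of]
        if not lab:
            logger.warning("cluster %d has no labeled members; probabilities undefined", cluster)
            continue
        for j, cls in enumerate(vocabulary):
            table[cluster, j] = sum(1 for s in lab if cls in classes_of[s]) / len(lab)
    return pd.DataFrame(table, index=range(assignment.n_clusters), columns=list(vocabulary))


def cluster_based_recommend(
    subject_id: str,
    assignment: ClusterAssignment,
    probability_table: pd.DataFrame,
    rank_threshold: int = DEFAULT_RANK_THRESHOLD,
) -> Recommendation:
    """Recommend the top-ranked classes of the subject's cluster.

    Identical for every member of a cluster. A subject in a cluster with
    undefined probabilities (no labeled members) is an error; use the
    network-based engine for such subjects.
    """
    label_of = assignment.label_of()
    if subject_id not in label_of:
        raise KeyError(subject_id)
    cluster = label_of[subject_id]
    probs = probability_table.loc[cluster]
    if probs.isna().any():
        raise ValueError(
            f"cluster {cluster} has no labeled members; "
            "use network_based_recommend for this subject"
        )
    ranked_raw = _competition_rank({cls: float(p) for cls, p in probs.items()})
    ranked = [(cls, 0, p, rank) for cls, p, rank in ranked_raw]
    recommended = frozenset(cls for cls, _, _, rank in ranked if rank <= rank_threshold)
    members = sum(1 for c in label_of.values() if c == cluster)
    return Recommendation(
        subject_id=subject_id,
        ranked=ranked,
        recommended=recommended,
        neighborhood_total=members,
        neighborhood_labeled=0,
        rings_expanded=0,
        flags=("cluster_engine",),
    )


def network_based_recommend(
    subject_id: str,
    g: SimilarityGraph,
    prescriptions: list[PrescriptionRecord],
    min_labeled: int = DEFAULT_MIN_LABELED,
    rank_threshold: int = DEFAULT_RANK_THRESHOLD,
) -> Recommendation:
    """Adaptive-neighborhood recommendation on the similarity graph.

    The neighborhood grows breadth-first from the subject: ring 1 are the
    direct neighbors, ring r the nodes at graph distance r. Whole rings
    are always included — expansion stops after the first complete ring
    at which the cumulative count of labeled neighbors reaches
    ``min_labeled``. Class counts are tallied over the labeled members
    (the target subject's own prescriptions excluded), competition-ranked
    by count, and classes at rank <= ``rank_threshold`` recommended.

    If the subject's connected component runs out before the quota is
    met, the recommendation is computed on all available labeled members
    and flagged ``quota_unmet``; a component with no labeled member at
    all is an error.
    """
    if subject_id not in g.graph:
        raise KeyError(f"subject {subject_id!r} not in the graph")
    if min_labeled < 1:
        raise ValueError("min_labeled must be >= 1")
    classes_of = labeled_classes(prescriptions)

    visited = {subject_id}
    frontier = [subject_id]
    neighborhood: list[str] = []
    n_labeled = 0
    rings = 0
    while frontier and n_labeled < min_labeled:
        next_frontier: list[str] = []
        for node in frontier:
            for nbr in g.graph.neighbors(node):
                if nbr not in visited:
                    visited.add(nbr)
                    next_frontier.append(nbr)
        if not next_frontier:
            break
        rings += 1
        neighborhood.extend(next_frontier)
        n_labeled += sum(1 for node in next_frontier if node in classes_of)
        frontier = next_frontier

    flags: list[str] = []
    if n_labeled < min_labeled:
        if n_labeled == 0:
            raise ValueError(
                f"component of subject {subject_id!r} has no labeled members"
            )
        flags.append("quota_unmet")
        logger.warning(
            "subject %s: component exhausted with %d < %d labeled neighbors",
            subject_id,
            n_labeled,
            min_labeled,
        )

    counts = {cls: 0 for cls in DEFAULT_CLASS_VOCABULARY}
    for node in neighborhood:
        held = classes_of.get(node)
        if held:
            for cls in held:
                counts[cls] = counts.get(cls, 0) + 1
    ranked_raw = _competition_rank({cls: float(c) for cls, c in counts.items()})
    ranked = [
        (cls, int(c), c / n_labeled if n_labeled else 0.0, rank)
        for cls, c, rank in ranked_raw
    ]
    recommended = frozenset(cls for cls, _, _, rank in ranked if rank <= rank_threshold)
    return Recommendation(
        subject_id=subject_id,
        ranked=ranked,
        recommended=recommended,
        neighborhood_total=len(neighborhood),
        neighborhood_labeled=n_labeled,
        rings_expanded=rings,
        flags=tuple(flags),
    )


def evaluate_recommendations(
    recs: list[Recommendation],
    prescriptions: list[PrescriptionRecord],
    assignment: ClusterAssignment | None = None,
) -> dict:
    """Compare recommendations against observed prescriptions.

    Every evaluated subject must be labeled. Reports the distribution of
    recommendation-set sizes, per-class recommendation frequency (overall
    and per cluster when an assignment is given), per-subject hit
    (recommended and actual classes overlap) and exact-match flags, and
    the aggregate hit rate.
    """
    classes_of = labeled_classes(prescriptions)
    unlabeled = [r.subject_id for r in recs if r.subject_id not in classes_of]
    if unlabeled:
        raise ValueError(f"evaluated subjects without prescriptions: {unlabeled[:5]}")
    if not recs:
        raise ValueError("no recommendations to evaluate")
    size_counts: dict[int, int] = {}
    class_counts: dict[str, int] = {}
    hits = exacts = 0
    per_subject = []
    for rec in recs:
        actual = classes_of[rec.subject_id]
        size = len(rec.recommended)
        size_counts[size] = size_counts.get(size, 0) + 1
        for cls in rec.recommended:
            class_counts[cls] = class_counts.get(cls, 0) + 1
        hit = bool(rec.recommended & actual)
        exact = rec.recommended == actual
        hits += hit
        exacts += exact
        per_subject.append(
            {
                "subject_id": rec.subject_id,
                "recommended": ";".join(sorted(rec.recommended)),
                "actual": ";".join(sorted(actual)),
                "hit": hit,
                "exact": exact,
            }
        )
    n = len(recs)
    report = {
        "n_evaluated": n,
        "size_distribution": {k: size_counts[k] / n for k in sorted(size_counts)},
        "class_frequency": {k: class_counts[k] / n for k in sorted(class_counts)},
        "hit_rate": hits / n,
        "exact_match_rate": exacts / n,
        "per_subject": per_subject,
    }
    if assignment is not None:
        label_of = assignment.label_of()
        by_cluster: dict[int, dict[str, float]] = {}
        for cluster in range(assignment.n_clusters):
            members = [r for r in recs if label_of.get(r.subject_id) == cluster]
            if not members:
                continue
            counts: dict[str, int] = {}
            for rec in members:
                for cls in rec.recommended:
                    counts[cls] = counts.get(cls, 0) + 1
            by_cluster[cluster] = {
                cls: counts[cls] / len(members) for cls in sorted(counts)
            }
        report["class_frequency_by_cluster"] = by_cluster
    return report
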