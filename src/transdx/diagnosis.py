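"""Score-based diagnosis rules and diagnosis-source comparison.

A scale-based diagnosis (DxS) assigns a label whenever any threshold
clause on a clinical rating scale fires; the shipped defaults follow the
clinical cut-offs: depression at HAMD >= 7, anxiety at HAMA >= 10 or
PDSS >= 8, bipolar disorder at MDQ >= 7 or HCL-32 >= 12. Comparing DxS
against another label source (e.g. self-report) yields a per-subject
agreement flag and an overall inconsistency rate.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_COMPARATORS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt}


@dataclass(frozen=True)
class ScoreDiagnosisRule:
    """One diagnosis with OR-combined threshold clauses on scale scores."""

    diagnosis: str
    clauses: tuple[tuple[str, str, float], ...]  # (scale_id, comparator, threshold)

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError(f"rule {self.diagnosis!r} has no clauses")
        for scale_id, comp, threshold in self.clauses:
            if comp not in _COMPARATORS:
                raise ValueError(f"unknown comparator {comp!r} in rule {self.diagnosis!r}")
            if not pd.notna(threshold) or threshold in (float("inf"), float("-inf")):
                raise ValueError(f"non-finite threshold in rule {self.diagnosis!r}")


#: Default scale-based rule set (clinical cut-offs).
DEFAULT_SCORE_RULES: tuple[ScoreDiagnosisRule, ...] = (
    ScoreDiagnosisRule("depression", (("HAMD", ">=", 7),)),
    ScoreDiagnosisRule("anxiety", (("HAMA", ">=", 10), ("PDSS", ">=", 8))),
    ScoreDiagnosisRule("bipolar", (("MDQ", ">=", 7), ("HCL32", ">=", 12))),
)


@dataclass
class DiagnosisLabels:
    """Per-subject diagnosis sets from one source."""

    source: str  # "self_reported" or "score_based"
    labels: dict[str, frozenset[str]]

    @property
    def vocabulary(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.labels.values():
            out |= s
        return frozenset(out)


def apply_score_diagnosis(
    scale_scores: pd.DataFrame,
    rules: tuple[ScoreDiagnosisRule, ...] = DEFAULT_SCORE_RULES,
) -> DiagnosisLabels:
    """Apply threshold rules to a subject x scale score table.

    A subject receives a diagnosis iff any clause of its rule holds; a
    missing scale value makes that clause evaluate false (logged). Every
    scale referenced by a rule must exist as a column.
    """
    referenced = {sc for rule in rules for sc, _, _ in rule.clauses}
    absent = referenced - set(scale_scores.columns)
    if absent:
        raise KeyError(f"rules reference scales absent from the table: {sorted(absent)}")
    n_missing = int(scale_scores[sorted(referenced)].isna().sum().sum())
    if n_missing:
        logger.warning("%d missing scale values treated as non-firing clauses", n_missing)
    labels: dict[str, frozenset[str]] = {}
    for subject, row in scale_scores.iterrows():
        dx: set[str] = set()
        for rule in rules:
            for scale_id, comp, threshold in rule.clauses:
                value = row[scale_id]
                if pd.notna(value) and _COMPARATORS[comp](value, threshold):
                    dx.add(rule.diagnosis)
                    break
        labels[str(subject)] = frozenset(dx)
    return DiagnosisLabels(source="score_based", labels=labels)


def compare_diagnoses(
    a: DiagnosisLabels,
    b: DiagnosisLabels,
    mode: str = "exact",
) -> dict:
    """Compare two diagnosis sources over the same subject universe.

    Parameters
    ----------
    a, b : DiagnosisLabels
        Same subject universe required.
    mode : {"exact", "shared"}
        ``exact``: disagreement is any set inequality over the shared
        vocabulary restriction of both sources. ``shared``: disagreement
        is a non-empty symmetric difference restricted to the shared
        vocabulary (identical here, kept as an explicit switch).

    Returns
    -------
    dict with ``inconsistency_rate``, per-subject ``agreement`` flags and
    per-diagnosis confusion counts (a-only / b-only / both).
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("diagnosis sources cover different subject universes")
    shared = a.vocabulary & b.vocabulary
    if not shared and (a.vocabulary or b.vocabulary):
        raise ValueError("disjoint diagnosis vocabularies: nothing comparable")
    agreement: dict[str, bool] = {}
    confusion = {dx: {"a_only": 0, "b_only": 0, "both": 0} for dx in sorted(shared)}
    for subject in a.labels:
        sa = a.labels[subject] & shared
        sb = b.labels[subject] & shared
        if mode == "exact":
            agreement[subject] = sa == sb
        elif mode == "shared":
            agreement[subject] = not (sa ^ sb)
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")
        for dx in shared:
            in_a, in_b = dx in sa, dx in sb
            if in_a and in_b:
                confusion[dx]["both"] += 1
            elif in_a:
                confusion[dx]["a_only"] += 1
            elif in_b:
                confusion[dx]["b_only"] += 1
    n = len(agreement)
    rate = sum(not v for v in agreement.values()) / n if n else 0.0
    return {
        "inconsistency_rate": rate,
        "agreement": agreement,
        "confusion": confusion,
        "n_subjects": n,
    }
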