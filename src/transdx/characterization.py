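"""Cluster characterization: what makes each cluster what it is.

Three complementary views: (1) diagnosis composition, emitted as a flow
table suitable for Sankey rendering; (2) per-cluster feature importance
from an L1-penalized one-vs-rest logistic regression, reporting features
whose coefficient exceeds a threshold (default beta > 0.2 on
standardized features); (3) category index scores: every item min-max
scaled to [0, 1] over the whole cohort, averaged within its category
per subject, then summarized per cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from transdx.cohort import CATEGORIES, Cohort
from transdx.diagnosis import DiagnosisLabels
from transdx.features import FeatureMatrix, _numeric_code
from transdx.profiling import ClusterAssignment

logger = logging.getLogger(__name__)

MIN_CLUSTER_SIZE_FOR_IMPORTANCE = 10


def diagnosis_composition(
    assignment: ClusterAssignment,
    labels: DiagnosisLabels | ClusterAssignment,
) -> pd.DataFrame:
    """Cross-tabulate clusters against diagnoses (or a second clustering).

    Returns a flow table (``source``, ``target``, ``count``) whose rows
    are ready for a Sankey diagram: one flow per (diagnosis, cluster)
    pair, with a ``none`` pseudo-label for subjects carrying no
    diagnosis. Passing a second ClusterAssignment instead of labels
    yields the cluster x cluster overlap table between two methods.
    """
    label_of = assignment.label_of()
    if isinstance(labels, ClusterAssignment):
        if set(labels.subject_ids) != set(assignment.subject_ids):
            raise ValueError("assignments cover different subject universes")
        other = labels.label_of()
        strata = {s: {f"{labels.method}{c}"} for s, c in other.items()}
    else:
        if set(labels.labels) != set(assignment.subject_ids):
            raise ValueError("labels and assignment cover different subject universes")
        strata = {s: (set(dx) if dx else {"none"}) for s, dx in labels.labels.items()}
    counts: dict[tuple[str, str], int] = {}
    for subject, stratum_set in strata.items():
        cluster = f"{assignment.method}{label_of[subject]}"
        for stratum in stratum_set:
            counts[(stratum, cluster)] = counts.get((stratum, cluster), 0) + 1
    rows = [
        {"source": src, "target": tgt, "count": c}
        for (src, tgt), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "count"])


def cluster_feature_importance(
    fm: FeatureMatrix,
    assignment: ClusterAssignment,
    beta_threshold: float = 0.2,
    penalty: float | None = None,
    seed: int = 0,
    absolute: bool = False,
) -> dict[int, list[tuple[str, float]]]:
    """Per-cluster important features from L1-penalized logistic regression.

    For each cluster a one-vs-rest (member / non-member) lasso-penalized
    logistic regression is fitted on all features; features with
    coefficient above ``beta_threshold`` (signed by default, absolute
    with ``absolute=True``) are reported sorted by descending
    coefficient. ``penalty`` is the inverse regularization strength C;
    when None it is chosen by 3-fold cross-validated log-likelihood.
    Clusters with fewer than 10 members are skipped with a warning.
    """
    if not fm.standardized:
        raise ValueError("feature matrix must be standardized")
    if list(fm.subject_ids) != list(assignment.subject_ids):
        raise ValueError("feature matrix and assignment cover different subjects")
    if assignment.n_clusters < 2:
        raise ValueError("feature importance needs at least 2 clusters")
    out: dict[int, list[tuple[str, float]]] = {}
    for cluster in range(assignment.n_clusters):
        y = (assignment.labels == cluster).astype(int)
        if y.sum() < MIN_CLUSTER_SIZE_FOR_IMPORTANCE:
            logger.warning(
                "cluster %d has %d members (< %d); importance skipped",
                cluster,
                int(y.sum()),
                MIN_CLUSTER_SIZE_FOR_IMPORTANCE,
            )
            continue
        if penalty is None:
            model = LogisticRegressionCV(
                Cs=np.logspace(-2, 2, 5),
                cv=3,
                l1_ratios=(1.0,),
                solver="liblinear",
                scoring="neg_log_loss",
                random_state=seed,
                use_legacy_attributes=False,
            )
        else:
            model = LogisticRegression(
                C=penalty, l1_ratio=1, solver="liblinear", random_state=seed
            )
        model.fit(fm.values, y)
        coefs = model.coef_.ravel()
        scores = np.abs(coefs) if absolute else coefs
        picked = [
            (fm.feature_names[i], float(coefs[i]))
            for i in np.argsort(-scores)
            if scores[i] > beta_threshold
        ]
        out[cluster] = picked
    return out


def _numeric_responses(cohort: Cohort) -> pd.DataFrame:
    """Item responses as numbers, with missing codes as NaN."""
    cols = {}
    for item in cohort.items:
        raw = cohort.responses[item.item_id]
        missing = set(item.missing_codes)
        cols[item.item_id] = [
            np.nan if (pd.isna(c) or c in missing) else _numeric_code(item, c) for c in raw
        ]
    return pd.DataFrame(cols, index=cohort.subject_ids)


def category_index_scores(
    cohort: Cohort, assignment: ClusterAssignment | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-subject category index scores and per-cluster summaries.

    Every item is min-max scaled to [0, 1] over the full cohort (so
    scores are comparable across clusters; items with max == min scale
    to 0 with a warning); a subject's category score is the mean of its
    scaled items in that category. Returns ``(subject_scores,
    cluster_summary)`` where the summary holds mean and quartiles of the
    member subjects' scores per cluster and category (None when no
    assignment is given).
    """
    numeric = _numeric_responses(cohort)
    lo, hi = numeric.min(axis=0), numeric.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        logger.warning(
            "%d items with max == min scaled to 0", int(degenerate.sum())
        )
    scaled = (numeric - lo) / span.replace(0, np.nan)
    scaled.loc[:, degenerate] = 0.0
    by_category = {}
    for cat in CATEGORIES:
        members = [it.item_id for it in cohort.items if it.category == cat]
        if members:
            by_category[cat] = scaled[members].mean(axis=1, skipna=True)
    subject_scores = pd.DataFrame(by_category, index=cohort.subject_ids)
    if assignment is None:
        return subject_scores, None
    label_of = assignment.label_of()
    # complete-case encoding may have dropped subjects: summarize the overlap
    common = [s for s in cohort.subject_ids if s in label_of]
    rows = []
    grouped = subject_scores.loc[common].groupby(
        pd.Series({s: label_of[s] for s in common})
    )
    for cluster, block in grouped:
        for cat in subject_scores.columns:
            q = block[cat].quantile([0.25, 0.5, 0.75])
            rows.append(
                {
                    "cluster": int(cluster),
                    "category": cat,
                    "mean": block[cat].mean(),
                    "q25": q[0.25],
                    "median": q[0.5],
                    "q75": q[0.75],
                }
            )
    return subject_scores, pd.DataFrame(rows)
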