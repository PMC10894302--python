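"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from transdx.cohort import Cohort, ItemDefinition
from transdx.features import FeatureMatrix


def make_cohort(
    responses: dict[str, list[str | None]],
    items: list[ItemDefinition],
    age: list[float] | None = None,
    sex: list[float] | None = None,
) -> Cohort:
    """Build a small in-memory cohort from per-item response lists."""
    n = len(next(iter(responses.values())))
    subject_ids = [f"P{i:03d}" for i in range(n)]
    frame = pd.DataFrame(responses, index=subject_ids, dtype=object).astype("string")
    cohort = Cohort(
        subject_ids=subject_ids,
        age=pd.Series(age if age is not None else [50.0] * n, index=subject_ids),
        sex=pd.Series(sex if sex is not None else [float(i % 2) for i in range(n)], index=subject_ids),
        responses=frame,
        items=items,
    )
    cohort.validate()
    return cohort


def make_feature_matrix(values: np.ndarray, standardized: bool = True) -> FeatureMatrix:
    """Wrap a raw numeric matrix as a FeatureMatrix (P000, P001, ... ids)."""
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    names = [f"f{j}" for j in range(d)]
    return FeatureMatrix(
        subject_ids=[f"P{i:03d}" for i in range(n)],
        feature_names=names,
        values=values,
        provenance={name: (name, "numeric") for name in names},
        standardized=standardized,
    )


def brute_force_knn_edges(
    values: np.ndarray, node_ids: list[str], k_nn: int, p: float = 2
) -> set[tuple[str, str]]:
    """Independent kNN-graph oracle: all-pairs Minkowski distances with
    plain Python sorting, ties at the cut broken by subject-id order."""
    n = len(node_ids)
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        d = np.sum(np.abs(values - values[i]) ** p, axis=1) ** (1.0 / p)
        dists = [(float(d[j]), node_ids[j], j) for j in range(n) if j != i]
        dists.sort(key=lambda t: (t[0], t[1]))
        for _, _, j in dists[:k_nn]:
            edges.add(tuple(sorted((node_ids[i], node_ids[j]))))
    return edges


def pairwise_silhouette(values: np.ndarray, labels: np.ndarray) -> float:
    """Independent mean-silhouette oracle from explicit pairwise distances;
    singleton-cluster points contribute 0."""
    n = len(labels)
    d = np.sqrt(((values[:, None, :] - values[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            scores.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


@pytest.fixture
def toy_items() -> list[ItemDefinition]:
    return [
        ItemDefinition(
            item_id="col",
            text="favorite color",
            category="A",
            value_kind="categorical",
            allowed_values=("a", "b", "c"),
            missing_codes=("-9",),
        ),
        ItemDefinition(
            item_id="yn",
            text="ever felt down",
            category="B",
            value_kind="binary",
            allowed_values=("0", "1"),
        ),
    ]


@pytest.fixture
def toy_cohort(toy_items) -> Cohort:
    return make_cohort(
        {"col": ["a", "b", "c"], "yn": ["0", "1", "1"]},
        toy_items,
        age=[40.0, 50.0, 60.0],
    )
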