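"""Numeric feature encoding and standardization.

Categorical items are one-hot encoded (one indicator per allowed code,
with indicator columns for "prefer not to answer"-style missing codes
dropped by default, mirroring the removal of ambiguous missing-value
variables). Binary, ordinal and continuous items each map to a single
numeric column, preserving the ordering that one-hot encoding would
discard. Age (numeric) and sex (binary indicator) are appended as
features. Subjects left with any absent value after encoding are
excluded (complete-case analysis) and the exclusion is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from transdx.cohort import Cohort, CohortValidationError, ItemDefinition

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Dense numeric feature matrix with per-feature provenance.

    ``provenance`` maps each feature name to ``(item_id, role)`` where the
    role is ``numeric``, ``indicator:<code>``, ``age`` or ``sex``.
    """

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    provenance: dict[str, tuple[str, str]]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.feature_names)} features"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.feature_names
        )


def _numeric_code(item: ItemDefinition, code: str) -> float:
    """Numeric value of a response code: its literal number if parseable,
    otherwise its rank in the item's ordered allowed values."""
    try:
        return float(code)
    except ValueError:
        return float(item.allowed_values.index(code))


def encode_features(cohort: Cohort, drop_missing_indicators: bool = True) -> FeatureMatrix:
    """Encode a cohort's coded responses into a numeric feature matrix.

    Parameters
    ----------
    cohort : Cohort
        Validated cohort.
    drop_missing_indicators : bool, default True
        Drop the one-hot indicator columns that correspond to missing
        codes of categorical items.

    Returns
    -------
    FeatureMatrix
        Unstandardized matrix; categorical items expand to one indicator
        column per allowed (and, unless dropped, missing) code; all other
        items contribute one numeric column; age and sex are appended.
    """
    n = cohort.n_subjects
    columns: list[np.ndarray] = []
    names: list[str] = []
    provenance: dict[str, tuple[str, str]] = {}

    for item in cohort.items:
        col = cohort.responses[item.item_id]
        observed = col[~(col.isna() | col.isin(set(item.missing_codes)))]
        if observed.empty:
            raise CohortValidationError(
                f"item {item.item_id!r} has zero observed non-missing values"
            )
        if item.value_kind == "categorical":
            codes = list(item.allowed_values)
            if not drop_missing_indicators:
                codes += list(item.missing_codes)
            for code in codes:
                name = f"{item.item_id}={code}"
                columns.append((col == code).to_numpy(dtype=float))
                names.append(name)
                provenance[name] = (item.item_id, f"indicator:{code}")
        else:
            mask_missing = col.isna() | col.isin(set(item.missing_codes))
            vals = np.array(
                [np.nan if m else _numeric_code(item, c) for c, m in zip(col, mask_missing)]
            )
            columns.append(vals)
            names.append(item.item_id)
            provenance[item.item_id] = (item.item_id, "numeric")

    columns.append(cohort.age.to_numpy(dtype=float))
    names.append("age")
    provenance["age"] = ("", "age")
    columns.append(cohort.sex.to_numpy(dtype=float))
    names.append("sex")
    provenance["sex"] = ("", "sex")

    values = np.column_stack(columns) if columns else np.empty((n, 0))
    keep = np.isfinite(values).all(axis=1)
    if not keep.all():
        logger.warning(
            "excluding %d of %d subjects with missing values after encoding",
            int((~keep).sum()),
            n,
        )
    return FeatureMatrix(
        subject_ids=[s for s, k in zip(cohort.subject_ids, keep) if k],
        feature_names=names,
        values=values[keep],
        provenance=provenance,
        standardized=False,
    )


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score every column: (x - mean) / sd with the population (n) sd.

    Constant columns are mapped to all zeros with a logged warning rather
    than NaN. Standardizing an already-standardized matrix is an error.
    """
    if fm.standardized:
        raise ValueError("feature matrix is already standardized")
    values = fm.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd (ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant feature columns set to 0: %s",
            int(constant.sum()),
            [fm.feature_names[i] for i in np.flatnonzero(constant)[:10]],
        )
    safe_sd = np.where(constant, 1.0, sd)
    z = (values - mean) / safe_sd
    z[:, constant] = 0.0
    return replace(fm, values=z, standardized=True)
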