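"""Cohort container and tabular I/O.

A cohort is a rectangular table of coded questionnaire responses (one row
per subject, one column per item) together with item metadata that assigns
every item to a symptom category A-H and declares its value kind and legal
codes. Files are UTF-8 CSV or TSV (delimiter picked by extension), first
row is the header, and the subject identifier column is ``subject_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("A", "B", "C", "D", "E", "F", "G", "H")
VALUE_KINDS = ("binary", "ordinal", "categorical", "continuous")

#: file-format schema version written into every header comment
SCHEMA_VERSION = "1"


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the item metadata contract."""


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table, skipping ``#`` header comments."""
    path = Path(path)
    return pd.read_csv(path, sep=_delimiter_for(path), comment="#", dtype=str)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a table with a schema-versioned header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# transdx table schema={SCHEMA_VERSION}\n")
        df.to_csv(fh, sep=_delimiter_for(path), index=index, float_format="%.10g")


@dataclass(frozen=True)
class ItemDefinition:
    """Metadata for one questionnaire item.

    Parameters
    ----------
    item_id : str
        Unique item identifier.
    text : str
        Question text (free form, informational).
    category : str
        Symptom category, one of A-H (A diagnostic screening, B mood,
        C anxiety, D general/drug addiction, E alcohol/cannabis use,
        F unusual experiences, G traumatic events, H harm behaviors).
    value_kind : str
        One of ``binary``, ``ordinal``, ``categorical``, ``continuous``.
    allowed_values : tuple of str
        Ordered legal response codes (for continuous items a descriptive
        range placeholder; any numeric string is accepted).
    missing_codes : tuple of str
        Codes meaning "prefer not to answer" / unknown.
    """

    item_id: str
    text: str
    category: str
    value_kind: str
    allowed_values: tuple[str, ...]
    missing_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CohortValidationError(
                f"item {self.item_id!r}: category {self.category!r} not in {CATEGORIES}"
            )
        if self.value_kind not in VALUE_KINDS:
            raise CohortValidationError(
                f"item {self.item_id!r}: value_kind {self.value_kind!r} not in {VALUE_KINDS}"
            )
        if not self.allowed_values:
            raise CohortValidationError(f"item {self.item_id!r}: allowed_values empty")
        if set(self.allowed_values) & set(self.missing_codes):
            raise CohortValidationError(
                f"item {self.item_id!r}: missing_codes overlap allowed_values"
            )


@dataclass
class Cohort:
    """Validated questionnaire cohort.

    ``responses`` is a string-coded DataFrame indexed by ``subject_id``
    with one column per item; empty cells (absent responses) are NaN.
    """

    subject_ids: list[str]
    age: pd.Series
    sex: pd.Series
    responses: pd.DataFrame
    items: list[ItemDefinition] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def validate(self) -> None:
        """Check the response table against the item metadata."""
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted(
                {s for s in self.subject_ids if self.subject_ids.count(s) > 1}
            )
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        item_ids = [it.item_id for it in self.items]
        if len(set(item_ids)) != len(item_ids):
            raise CohortValidationError("duplicate item ids in metadata")
        missing_meta = [c for c in self.responses.columns if c not in set(item_ids)]
        if missing_meta:
            raise CohortValidationError(
                f"response columns without item metadata: {missing_meta}"
            )
        if list(self.responses.index) != self.subject_ids:
            raise CohortValidationError("response table index != subject_ids")
        for it in self.items:
            if it.item_id not in self.responses.columns:
                raise CohortValidationError(f"item {it.item_id!r} has no response column")
            if it.value_kind == "continuous":
                continue  # any numeric code; checked at encoding
            legal = set(it.allowed_values) | set(it.missing_codes)
            col = self.responses[it.item_id]
            bad = col[~(col.isna() | col.isin(legal))]
            if len(bad):
                subj = bad.index[0]
                raise CohortValidationError(
                    f"unknown response code {bad.iloc[0]!r} for item {it.item_id!r}"
                    f" (subject {subj!r})"
                )


def _items_from_frame(df: pd.DataFrame) -> list[ItemDefinition]:
    required = {"item_id", "category", "value_kind", "allowed_values"}
    missing = required - set(df.columns)
    if missing:
        raise CohortValidationError(f"item metadata missing columns: {sorted(missing)}")
    items = []
    for _, row in df.iterrows():
        allowed = tuple(str(row["allowed_values"]).split("|"))
        raw_missing = row.get("missing_codes")
        missing_codes: tuple[str, ...] = ()
        if isinstance(raw_missing, str) and raw_missing:
            missing_codes = tuple(raw_missing.split("|"))
        items.append(
            ItemDefinition(
                item_id=str(row["item_id"]),
                text=str(row.get("text", "")),
                category=str(row["category"]),
                value_kind=str(row["value_kind"]),
                allowed_values=allowed,
                missing_codes=missing_codes,
            )
        )
    return items


def load_cohort(responses_path: str | Path, items_path: str | Path) -> Cohort:
    """Read and validate a cohort from a response table and item metadata.

    The response table must carry ``subject_id``, ``age`` and ``sex``
    columns; every remaining column must be described by the item table.
    Rows with malformed (empty) subject ids are rejected and counted in
    the log; duplicated subject ids are an error.
    """
    responses_path, items_path = Path(responses_path), Path(items_path)
    for p in (responses_path, items_path):
        if not p.exists():
            raise FileNotFoundError(p)
    raw = read_table(responses_path)
    if "subject_id" not in raw.columns:
        raise CohortValidationError("response table has no subject_id column")
    malformed = raw["subject_id"].isna() | (raw["subject_id"].str.strip() == "")
    if malformed.any():
        logger.warning("rejected %d rows with malformed subject ids", int(malformed.sum()))
        raw = raw[~malformed]
    if raw["subject_id"].duplicated().any():
        dupes = sorted(raw.loc[raw["subject_id"].duplicated(), "subject_id"].unique())
        raise CohortValidationError(f"duplicate subject ids: {dupes}")
    items = _items_from_frame(read_table(items_path))
    raw = raw.set_index("subject_id")
    for col in ("age", "sex"):
        if col not in raw.columns:
            raise CohortValidationError(f"response table has no {col} column")
    age = pd.to_numeric(raw["age"])
    sex = pd.to_numeric(raw["sex"])
    responses = raw.drop(columns=["age", "sex"])
    cohort = Cohort(
        subject_ids=list(raw.index),
        age=age,
        sex=sex,
        responses=responses,
        items=items,
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, responses_path: str | Path, items_path: str | Path) -> None:
    """Write a cohort back to a response table and an item-metadata table."""
    out = cohort.responses.copy()
    out.insert(0, "age", cohort.age)
    out.insert(1, "sex", cohort.sex)
    out.index.name = "subject_id"
    write_table(out.reset_index(), responses_path)
    rows = [
        {
            "item_id": it.item_id,
            "text": it.text,
            "category": it.category,
            "value_kind": it.value_kind,
            "allowed_values": "|".join(it.allowed_values),
            "missing_codes": "|".join(it.missing_codes),
        }
        for it in cohort.items
    ]
    write_table(pd.DataFrame(rows), items_path)
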