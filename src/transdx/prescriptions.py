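"""Prescription records and drug-name to drug-class mapping.

Prescriptions arrive as (subject, drug name) pairs plus a curated map
from drug name to drug class. The default class vocabulary is
AD (antidepressants), AP (antipsychotics), MS (mood stabilizers) and
SH (sedative-hypnotics); it is extensible. A subject is "labeled" iff it
appears in the prescription table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from transdx.cohort import read_table

logger = logging.getLogger(__name__)

DEFAULT_CLASS_VOCABULARY: tuple[str, ...] = ("AD", "AP", "MS", "SH")


@dataclass
class PrescriptionRecord:
    subject_id: str
    drug_names: tuple[str, ...]
    classes: frozenset[str]


def load_prescriptions(
    path: str | Path,
    class_map: dict[str, str],
    vocabulary: tuple[str, ...] = DEFAULT_CLASS_VOCABULARY,
) -> tuple[list[PrescriptionRecord], dict]:
    """Read a (subject_id, drug_name) table and map drugs to classes.

    Drug names are lower-cased and whitespace-trimmed before lookup and
    duplicates collapsed. Drugs absent from the map are collected into a
    rejection report (never silently dropped); subjects keep their mapped
    drugs. Returns ``(records, rejection_report)``.
    """
    if not class_map:
        raise ValueError("empty drug class map")
    norm_map = {str(k).strip().lower(): v for k, v in class_map.items()}
    bad_classes = set(norm_map.values()) - set(vocabulary)
    if bad_classes:
        raise ValueError(
            f"class map values outside vocabulary {vocabulary}: {sorted(bad_classes)}"
        )
    df = read_table(path)
    for col in ("subject_id", "drug_name"):
        if col not in df.columns:
            raise ValueError(f"prescription table has no {col} column")
    unmapped: dict[str, int] = {}
    per_subject: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        subject = str(row["subject_id"])
        drug = str(row["drug_name"]).strip().lower()
        per_subject.setdefault(subject, [])
        if drug not in per_subject[subject]:
            per_subject[subject].append(drug)
    records = []
    for subject, drugs in per_subject.items():
        classes = set()
        for drug in drugs:
            cls = norm_map.get(drug)
            if cls is None:
                unmapped[drug] = unmapped.get(drug, 0) + 1
            else:
                classes.add(cls)
        records.append(
            PrescriptionRecord(
                subject_id=subject,
                drug_names=tuple(drugs),
                classes=frozenset(classes),
            )
        )
    if unmapped:
        logger.warning("%d distinct drug names had no class mapping", len(unmapped))
    report = {"unmapped_drugs": unmapped, "n_subjects": len(records)}
    return records, report


def labeled_classes(records: list[PrescriptionRecord]) -> dict[str, frozenset[str]]:
    """Map each labeled subject to its prescribed class set."""
    return {r.subject_id: r.classes for r in records}
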