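"""Synthetic questionnaire cohorts with known latent structure.

The generator emulates the structure of a large mental-health
questionnaire cohort: ~140 mixed-type items spread over the eight
symptom categories A-H, a handful of latent symptom subgroups that
elevate category-specific response levels, clinical scale scores feeding
the score-based diagnosis rules, a self-reported diagnosis source with
controlled discordance, and a small labeled fraction (default 9%)
holding prescriptions from the classes {AD, AP, MS, SH} with
group-conditional probabilities.

Items are conditionally independent given the latent group: binary items
are Bernoulli with a group-and-category probability shift, ordinal and
categorical items discretize a unit-variance latent normal shifted by
the group's elevation (in sigma units, equal-width cut points), and
continuous items are the shifted normal itself. This is deliberately
simple — enough to exercise every pipeline stage with known ground
truth, not a psychometric item-response model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from transdx.cohort import CATEGORIES, Cohort, ItemDefinition, write_cohort, write_table
from transdx.diagnosis import DEFAULT_SCORE_RULES, ScoreDiagnosisRule
from transdx.prescriptions import DEFAULT_CLASS_VOCABULARY, PrescriptionRecord

logger = logging.getLogger(__name__)

MISSING_CODE = "-818"  # "prefer not to answer"

#: synthetic drug names per class, used when materializing prescription tables
SYNTHETIC_DRUGS: dict[str, tuple[str, ...]] = {
    "AD": ("fluoxetine", "sertraline", "citalopram"),
    "AP": ("olanzapine", "quetiapine", "risperidone"),
    "MS": ("lithium", "valproate", "lamotrigine"),
    "SH": ("zolpidem", "diazepam", "temazepam"),
}

#: drug name -> class map matching SYNTHETIC_DRUGS
SYNTHETIC_CLASS_MAP: dict[str, str] = {
    drug: cls for cls, drugs in SYNTHETIC_DRUGS.items() for drug in drugs
}


@dataclass
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    ``elevation`` and ``binary_shift`` are (n_groups x n_categories)
    arrays: the mean shift in sigma units applied to ordinal /
    categorical / continuous items, and the additive probability shift
    applied to binary items, of that category for members of that group.
    """

    n_subjects: int = 2000
    n_groups: int = 1
    group_weights: tuple[float, ...] = (1.0,)
    n_categories: int = 8
    n_items_per_category: int = 5
    item_kind_cycle: tuple[str, ...] = ("binary", "ordinal", "categorical", "continuous")
    elevation: np.ndarray | None = None
    binary_shift: np.ndarray | None = None
    binary_base_rate: float = 0.15
    ordinal_levels: int = 5
    missing_code_rate: float = 0.0
    labeled_fraction: float = 0.09
    class_probabilities: tuple[dict[str, float], ...] = ({"AD": 0.5, "AP": 0.1, "MS": 0.15, "SH": 0.2},)
    rules: tuple[ScoreDiagnosisRule, ...] = DEFAULT_SCORE_RULES
    self_report_discordance: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.elevation is None:
            self.elevation = np.zeros((self.n_groups, self.n_categories))
        if self.binary_shift is None:
            self.binary_shift = np.zeros((self.n_groups, self.n_categories))
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.binary_shift = np.asarray(self.binary_shift, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_groups > self.n_subjects:
            raise ValueError("n_groups exceeds n_subjects")
        if len(self.group_weights) != self.n_groups:
            raise ValueError("group_weights length != n_groups")
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group_weights must sum to 1")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")
        if len(self.class_probabilities) != self.n_groups:
            raise ValueError("class_probabilities length != n_groups")
        for probs in self.class_probabilities:
            for cls, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"class probability out of [0,1]: {cls}={p}")
        for shape_name, arr in (("elevation", self.elevation), ("binary_shift", self.binary_shift)):
            if arr.shape != (self.n_groups, self.n_categories):
                raise ValueError(
                    f"{shape_name} shape {arr.shape} != ({self.n_groups}, {self.n_categories})"
                )

    @property
    def categories(self) -> tuple[str, ...]:
        return CATEGORIES[: self.n_categories]


@dataclass
class GroundTruth:
    """Latent generating state; for evaluation only, never an input to
    the pipeline under test."""

    groups: np.ndarray  # per-subject latent group index
    class_probabilities: tuple[dict[str, float], ...]
    elevation: np.ndarray
    binary_shift: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": [int(x) for x in self.groups],
                "class_probabilities": list(self.class_probabilities),
                "elevation": self.elevation.tolist(),
                "binary_shift": self.binary_shift.tolist(),
            },
            sort_keys=True,
        )


def _item_definitions(cfg: SyntheticConfig) -> list[ItemDefinition]:
    items = []
    ord_codes = tuple(str(v) for v in range(cfg.ordinal_levels))
    cat_codes = ("a", "b", "c", "d")
    for cat in cfg.categories:
        for q in range(cfg.n_items_per_category):
            kind = cfg.item_kind_cycle[q % len(cfg.item_kind_cycle)]
            item_id = f"{cat}_q{q}"
            if kind == "binary":
                allowed: tuple[str, ...] = ("0", "1")
            elif kind == "ordinal":
                allowed = ord_codes
            elif kind == "categorical":
                allowed = cat_codes
            else:
                allowed = ("numeric",)
            missing = (MISSING_CODE,) if kind == "categorical" else ()
            items.append(
                ItemDefinition(
                    item_id=item_id,
                    text=f"synthetic item {q} of category {cat}",
                    category=cat,
                    value_kind=kind,
                    allowed_values=allowed,
                    missing_codes=missing,
                )
            )
    return items


def _discretize(z: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width cut points over [-2, 2] on the latent normal."""
    idx = np.floor((z + 2.0) / (4.0 / levels)).astype(int)
    return np.clip(idx, 0, levels - 1)


def generate_cohort(cfg: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the generating model; reproducible from seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    groups = rng.choice(cfg.n_groups, size=n, p=np.asarray(cfg.group_weights))
    subject_ids = [f"S{i:06d}" for i in range(n)]
    age = rng.integers(40, 70, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)

    items = _item_definitions(cfg)
    columns: dict[str, list[str]] = {}
    cat_index = {c: i for i, c in enumerate(cfg.categories)}
    cat_codes = ("a", "b", "c", "d")
    for item in items:
        ci = cat_index[item.category]
        if item.value_kind == "binary":
            p = np.clip(cfg.binary_base_rate + cfg.binary_shift[groups, ci], 0.01, 0.99)
            vals = (rng.random(n) < p).astype(int).astype(str)
        else:
            z = rng.normal(loc=cfg.elevation[groups, ci], scale=1.0, size=n)
            if item.value_kind == "ordinal":
                vals = _discretize(z, cfg.ordinal_levels).astype(str)
            elif item.value_kind == "categorical":
                lv = _discretize(z, len(cat_codes))
                vals = np.array([cat_codes[i] for i in lv], dtype=object)
            else:
                vals = np.array([f"{v:.4f}" for v in z], dtype=object)
        if item.missing_codes and cfg.missing_code_rate > 0:
            mask = rng.random(n) < cfg.missing_code_rate
            vals = np.where(mask, item.missing_codes[0], vals)
        columns[item.item_id] = list(vals)

    responses = pd.DataFrame(columns, index=subject_ids, dtype=str)
    cohort = Cohort(
        subject_ids=subject_ids,
        age=pd.Series(age, index=subject_ids),
        sex=pd.Series(sex, index=subject_ids),
        responses=responses,
        items=items,
    )
    cohort.validate()
    truth = GroundTruth(
        groups=groups,
        class_probabilities=cfg.class_probabilities,
        elevation=cfg.elevation.copy(),
        binary_shift=cfg.binary_shift.copy(),
    )
    return cohort, truth


def generate_scales(cohort: Cohort, truth: GroundTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Clinical scale scores (HAMD, HAMA, PDSS, MDQ, HCL32) whose means
    track each group's overall symptom elevation."""
    rng = np.random.default_rng(cfg.seed + 101)
    sev = np.clip(np.maximum(cfg.elevation, 0).mean(axis=1) / 4.0, 0, 1)[truth.groups]
    n = cohort.n_subjects

    def scale(base: float, gain: float, sd: float, cap: float) -> np.ndarray:
        return np.clip(np.round(rng.normal(base + gain * sev, sd)), 0, cap)

    return pd.DataFrame(
        {
            "HAMD": scale(3, 10, 2.5, 52),
            "HAMA": scale(5, 12, 3.0, 56),
            "PDSS": scale(2, 9, 2.0, 28),
            "MDQ": scale(3, 6, 2.0, 13),
            "HCL32": scale(6, 10, 4.0, 32),
        },
        index=cohort.subject_ids,
    )


def generate_self_report(
    score_labels: dict[str, frozenset[str]],
    cfg: SyntheticConfig,
    vocabulary: tuple[str, ...] = ("depression", "anxiety", "bipolar"),
) -> dict[str, frozenset[str]]:
    """Self-reported diagnoses as a perturbed copy of the score-based
    ones: with probability ``self_report_discordance`` a subject's set
    has one random diagnosis toggled."""
    rng = np.random.default_rng(cfg.seed + 202)
    out: dict[str, frozenset[str]] = {}
    for subject, labels in score_labels.items():
        labels = set(labels)
        if rng.random() < cfg.self_report_discordance:
            dx = vocabulary[rng.integers(len(vocabulary))]
            labels ^= {dx}
        out[subject] = frozenset(labels)
    return out


def generate_prescriptions(
    cohort: Cohort, truth: GroundTruth, cfg: SyntheticConfig
) -> list[PrescriptionRecord]:
    """Label a ~``labeled_fraction`` Bernoulli subset of subjects and give
    each labeled subject classes drawn with its group's probabilities.

    A labeled subject ending with zero classes is re-drawn once, then
    falls back to its group's modal class, so every labeled subject
    holds at least one class.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 303)
    records: list[PrescriptionRecord] = []
    n_fallback = 0
    vocab = DEFAULT_CLASS_VOCABULARY
    for i, subject in enumerate(cohort.subject_ids):
        if rng.random() >= cfg.labeled_fraction:
            continue
        probs = cfg.class_probabilities[truth.groups[i]]
        classes: set[str] = set()
        for _ in range(2):  # initial draw + one redraw
            classes = {cls for cls in vocab if rng.random() < probs.get(cls, 0.0)}
            if classes:
                break
        if not classes:
            modal = max(vocab, key=lambda c: (probs.get(c, 0.0), -vocab.index(c)))
            classes = {modal}
            n_fallback += 1
        drugs = tuple(SYNTHETIC_DRUGS[cls][rng.integers(3)] for cls in sorted(classes))
        records.append(
            PrescriptionRecord(
                subject_id=subject, drug_names=drugs, classes=frozenset(classes)
            )
        )
    if n_fallback:
        logger.info("%d labeled subjects received the modal-class fallback", n_fallback)
    return records


def scenario_library() -> dict[str, SyntheticConfig]:
    """Named generating presets.

    * ``separable-4`` — four equally weighted groups, each elevating a
      disjoint pair of categories by 8 sigma (binary probability +0.7),
      with group-distinct prescription profiles; for recovery tests.
    * ``ukbb-like`` — eight categories x 17 items (~138 features before
      expansion), five unequally weighted groups with moderate (2.5
      sigma) elevations, 9% labeled with an AD-dominant class skew and a
      0.33 self-report discordance; the realistic-workload preset.
    * ``flat-null`` — one group, zero elevation everywhere; for
      false-positive checks.
    """
    sep_elev = np.zeros((4, 8))
    sep_bin = np.zeros((4, 8))
    for g in range(4):
        sep_elev[g, 2 * g : 2 * g + 2] = 8.0
        sep_bin[g, 2 * g : 2 * g + 2] = 0.7
    separable = SyntheticConfig(
        name="separable-4",
        n_subjects=2000,
        n_groups=4,
        group_weights=(0.25, 0.25, 0.25, 0.25),
        n_items_per_category=4,
        elevation=sep_elev,
        binary_shift=sep_bin,
        labeled_fraction=0.09,
        class_probabilities=(
            {"AD": 0.75, "AP": 0.03, "MS": 0.08, "SH": 0.10},
            {"AD": 0.10, "AP": 0.70, "MS": 0.10, "SH": 0.10},
            {"AD": 0.10, "AP": 0.05, "MS": 0.70, "SH": 0.15},
            {"AD": 0.15, "AP": 0.05, "MS": 0.10, "SH": 0.70},
        ),
    )

    ukbb_elev = np.zeros((5, 8))
    ukbb_bin = np.zeros((5, 8))
    for g in range(1, 5):
        ukbb_elev[g, g - 1] = 2.5
        ukbb_elev[g, (g + 3) % 8] = 2.5
        ukbb_bin[g, g - 1] = 0.3
        ukbb_bin[g, (g + 3) % 8] = 0.3
    ukbb = SyntheticConfig(
        name="ukbb-like",
        n_subjects=10_000,
        n_groups=5,
        group_weights=(0.35, 0.25, 0.20, 0.12, 0.08),
        n_items_per_category=17,
        elevation=ukbb_elev,
        binary_shift=ukbb_bin,
        missing_code_rate=0.05,
        labeled_fraction=0.09,
        self_report_discordance=0.33,
        class_probabilities=(
            {"AD": 0.55, "AP": 0.02, "MS": 0.15, "SH": 0.08},
            {"AD": 0.80, "AP": 0.02, "MS": 0.05, "SH": 0.08},
            {"AD": 0.85, "AP": 0.03, "MS": 0.05, "SH": 0.12},
            {"AD": 0.75, "AP": 0.30, "MS": 0.20, "SH": 0.15},
            {"AD": 0.70, "AP": 0.05, "MS": 0.10, "SH": 0.35},
        ),
    )

    flat = SyntheticConfig(
        name="flat-null",
        n_subjects=2000,
        n_groups=1,
        group_weights=(1.0,),
        n_items_per_category=5,
        labeled_fraction=0.09,
        class_probabilities=({"AD": 0.5, "AP": 0.1, "MS": 0.15, "SH": 0.2},),
    )
    return {"separable-4": separable, "ukbb-like": ukbb, "flat-null": flat}


def scenario(name: str, n_subjects: int | None = None, seed: int | None = None) -> SyntheticConfig:
    """Fetch a preset by name, optionally overriding size and seed."""
    library = scenario_library()
    if name not in library:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(library)}")
    cfg = library[name]
    if n_subjects is not None:
        cfg = replace(cfg, n_subjects=n_subjects)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg


def write_synthetic_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write responses.tsv, items.tsv, prescriptions.tsv,
    scales.tsv, selfreport.tsv and truth.json under ``outdir``."""
    from transdx.diagnosis import apply_score_diagnosis

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(cfg)
    scales = generate_scales(cohort, truth, cfg)
    score_dx = apply_score_diagnosis(scales, cfg.rules)
    self_report = generate_self_report(score_dx.labels, cfg)
    prescriptions = generate_prescriptions(cohort, truth, cfg)

    paths = {
        "responses": outdir / "responses.tsv",
        "items": outdir / "items.tsv",
        "scales": outdir / "scales.tsv",
        "selfreport": outdir / "selfreport.tsv",
        "prescriptions": outdir / "prescriptions.tsv",
        "truth": outdir / "truth.json",
    }
    write_cohort(cohort, paths["responses"], paths["items"])
    scales_out = scales.copy()
    scales_out.index.name = "subject_id"
    write_table(scales_out.reset_index(), paths["scales"])
    sr = pd.DataFrame(
        {
            "subject_id": list(self_report),
            "diagnoses": [";".join(sorted(v)) for v in self_report.values()],
        }
    )
    write_table(sr, paths["selfreport"])
    rx_rows = [
        {"subject_id": r.subject_id, "drug_name": d}
        for r in prescriptions
        for d in r.drug_names
    ]
    write_table(pd.DataFrame(rx_rows, columns=["subject_id", "drug_name"]), paths["prescriptions"])
    paths["truth"].write_text(truth.to_json())
    return paths
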