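"""End-to-end pipeline driver.

Runs simulate (optional) -> load -> encode/standardize -> profile
(k-means with silhouette selection, kNN graph + Louvain resolution
sweep) -> characterize -> recommend (both engines) -> evaluate, writing
every artifact with stage provenance and the exact seed used, plus a
single JSON run report of quality metrics. A single global seed fans out
to per-stage seeds by fixed offsets so stages are individually
reproducible; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from transdx.cohort import load_cohort, read_table, write_table
from transdx.characterization import (
    category_index_scores,
    cluster_feature_importance,
    diagnosis_composition,
)
from transdx.diagnosis import DiagnosisLabels, apply_score_diagnosis, compare_diagnoses
from transdx.features import encode_features, standardize
from transdx.prescriptions import load_prescriptions
from transdx.profiling import (
    build_knn_graph,
    embed_2d,
    select_k_by_silhouette,
    sweep_resolution,
)
from transdx.recommendation import (
    cluster_based_recommend,
    cluster_class_probability,
    cluster_prescription_rate,
    evaluate_recommendations,
    network_based_recommend,
)
from transdx.synthetic import SYNTHETIC_CLASS_MAP, scenario, write_synthetic_dataset

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

# fixed per-stage seed offsets from the global seed
_SEED_OFFSETS = {"simulate": 0, "kmeans": 11, "louvain": 13, "embed": 17, "importance": 19}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "transdx_run"
    seed: int = 7
    # input: either a preset to simulate, or explicit table paths
    preset: str | None = "ukbb-like"
    n_subjects: int | None = None
    responses: str | None = None
    items: str | None = None
    scales: str | None = None
    selfreport: str | None = None
    prescriptions: str | None = None
    class_map: dict[str, str] = field(default_factory=lambda: dict(SYNTHETIC_CLASS_MAP))
    # stage parameters
    drop_missing_indicators: bool = True
    k_grid: list[int] = field(default_factory=lambda: list(range(2, 9)))
    resolution_grid: list[float] = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0])
    k_nn: int = 100
    p: float = 2.0
    beta_threshold: float = 0.2
    importance_penalty: float | None = 1.0
    min_labeled: int = 20
    rank_threshold: int = 3
    embed: bool = False
    write_graph: bool = False

    def stage_seed(self, stage: str) -> int:
        return self.seed + _SEED_OFFSETS[stage]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Runner:
    def __init__(self, cfg: RunConfig) -> None:
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_lines: list[str] = []
        self.report: dict = {"schema": SCHEMA_VERSION, "seed": cfg.seed, "stages": {}}

    def finish_stage(self, stage: str, outputs: list[Path], info: dict) -> None:
        checks = {p.name: _sha256(p) for p in outputs}
        self.log_lines.append(
            f"stage={stage} outputs=" + ",".join(f"{k}:{v[:12]}" for k, v in checks.items())
        )
        self.report["stages"][stage] = {**info, "checksums": checks}

    def write(self, df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = self.outdir / name
        write_table(df, path, index=index)
        return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the aggregated run report.

    Any stage failure raises ``RuntimeError`` naming the failing stage;
    artifacts written by earlier stages are retained.
    """
    r = _Runner(cfg)
    stage = "configure"
    try:
        cfg.to_yaml(r.outdir / "resolved_config.yaml")

        if cfg.preset is not None:
            stage = "simulate"
            scfg = scenario(cfg.preset, n_subjects=cfg.n_subjects, seed=cfg.stage_seed("simulate"))
            data_paths = write_synthetic_dataset(scfg, r.outdir / "data")
            cfg.responses = str(data_paths["responses"])
            cfg.items = str(data_paths["items"])
            cfg.scales = str(data_paths["scales"])
            cfg.selfreport = str(data_paths["selfreport"])
            cfg.prescriptions = str(data_paths["prescriptions"])
            r.finish_stage(stage, list(data_paths.values()), {"preset": cfg.preset, "n": scfg.n_subjects})

        stage = "load"
        if not (cfg.responses and cfg.items):
            raise ValueError("no input: set preset or responses+items paths")
        cohort = load_cohort(cfg.responses, cfg.items)
        truth_groups = None
        truth_path = r.outdir / "data" / "truth.json"
        if truth_path.exists():
            truth_groups = json.loads(truth_path.read_text())["groups"]
        r.finish_stage(stage, [], {"n_subjects": cohort.n_subjects, "n_items": len(cohort.items)})

        stage = "preprocess"
        fm = standardize(encode_features(cohort, cfg.drop_missing_indicators))
        info = {"n_subjects": fm.n_subjects, "n_features": len(fm.feature_names)}
        score_dx = None
        diag_report = None
        if cfg.scales:
            scales = read_table(Path(cfg.scales)).set_index("subject_id").apply(pd.to_numeric)
            score_dx = apply_score_diagnosis(scales)
        if score_dx is not None and cfg.selfreport:
            sr = read_table(Path(cfg.selfreport))
            self_dx = DiagnosisLabels(
                source="self_reported",
                labels={
                    str(row["subject_id"]): frozenset(
                        str(row["diagnoses"]).split(";")
                        if pd.notna(row["diagnoses"]) and str(row["diagnoses"])
                        else []
                    )
                    for _, row in sr.iterrows()
                },
            )
            diag_report = compare_diagnoses(self_dx, score_dx)
            info["diagnosis_inconsistency_rate"] = diag_report["inconsistency_rate"]
        r.finish_stage(stage, [], info)

        stage = "profile"
        km, k_table = select_k_by_silhouette(fm, cfg.k_grid, seed=cfg.stage_seed("kmeans"))
        graph = build_knn_graph(fm, k_nn=cfg.k_nn, p=cfg.p)
        lv, res_table = sweep_resolution(
            graph, fm, cfg.resolution_grid, seed=cfg.stage_seed("louvain")
        )
        outputs = [
            r.write(k_table, "kmeans_k_table.csv"),
            r.write(res_table, "louvain_resolution_table.csv"),
            r.write(pd.concat([km.to_frame(), lv.to_frame()]), "assignments.tsv"),
        ]
        if cfg.write_graph:
            edges = pd.DataFrame(graph.graph.edges(), columns=["node_a", "node_b"])
            outputs.append(r.write(edges, "graph_edges.tsv"))
        if cfg.embed:
            coords = embed_2d(fm, seed=cfg.stage_seed("embed"))
            coords.index.name = "subject_id"
            outputs.append(r.write(coords.reset_index(), "embedding.tsv"))
        profile_info = {
            "kmeans_k": km.parameters["k"],
            "kmeans_silhouette": km.quality["silhouette"],
            "louvain_n_communities": lv.n_clusters,
            "louvain_modularity": lv.quality["modularity"],
            "louvain_silhouette": lv.quality["silhouette"],
            "louvain_resolution": lv.parameters["resolution"],
        }
        if truth_groups is not None:
            from sklearn.metrics import adjusted_rand_score

            truth_of = dict(zip(cohort.subject_ids, truth_groups))
            t = [truth_of[s] for s in fm.subject_ids]
            profile_info["kmeans_ari_vs_truth"] = float(adjusted_rand_score(t, km.labels))
            profile_info["louvain_ari_vs_truth"] = float(adjusted_rand_score(t, lv.labels))
        r.finish_stage(stage, outputs, profile_info)

        stage = "characterize"
        comp_tables = []
        if score_dx is not None:
            score_dx_fm = DiagnosisLabels(
                source="score_based",
                labels={s: score_dx.labels[s] for s in fm.subject_ids},
            )
            for assignment in (km, lv):
                flows = diagnosis_composition(assignment, score_dx_fm)
                comp_tables.append(
                    r.write(flows, f"composition_{assignment.method}.csv")
                )
        overlap = diagnosis_composition(km, lv)
        outputs = comp_tables + [r.write(overlap, "overlap_km_lv.csv")]
        importance = cluster_feature_importance(
            fm,
            km,
            beta_threshold=cfg.beta_threshold,
            penalty=cfg.importance_penalty,
            seed=cfg.stage_seed("importance"),
        )
        imp_rows = [
            {"cluster": c, "feature": f, "beta": b}
            for c, feats in importance.items()
            for f, b in feats
        ]
        outputs.append(
            r.write(pd.DataFrame(imp_rows, columns=["cluster", "feature", "beta"]), "importance_kmeans.csv")
        )
        _, summary = category_index_scores(cohort, km)
        outputs.append(r.write(summary, "category_scores_kmeans.csv"))
        r.finish_stage(
            stage,
            outputs,
            {"n_important_features": {str(c): len(v) for c, v in importance.items()}},
        )

        stage = "recommend"
        rx_records, rx_report = load_prescriptions(Path(cfg.prescriptions), cfg.class_map)
        rx_records = [rec for rec in rx_records if rec.subject_id in set(fm.subject_ids)]
        rates = cluster_prescription_rate(km, rx_records)
        probs = cluster_class_probability(km, rx_records)
        labeled_ids = sorted(rec.subject_id for rec in rx_records)
        cluster_recs, network_recs = [], []
        for sid in labeled_ids:
            try:
                cluster_recs.append(
                    cluster_based_recommend(sid, km, probs, cfg.rank_threshold)
                )
            except ValueError:
                pass  # cluster without labeled members
            network_recs.append(
                network_based_recommend(
                    sid, graph, rx_records, cfg.min_labeled, cfg.rank_threshold
                )
            )
        rec_frame = pd.DataFrame(
            [
                {
                    "subject_id": rec.subject_id,
                    "engine": engine,
                    "recommended": ";".join(sorted(rec.recommended)),
                    "ranked": ";".join(f"{c}:{n}:{rank}" for c, n, _, rank in rec.ranked),
                    "rings": rec.rings_expanded,
                    "neighborhood_labeled": rec.neighborhood_labeled,
                    "flags": ";".join(rec.flags),
                }
                for engine, recs in (("cluster", cluster_recs), ("network", network_recs))
                for rec in recs
            ]
        )
        probs_out = probs.copy()
        probs_out.index.name = "cluster"
        outputs = [
            r.write(rates, "cluster_prescription_rates.csv"),
            r.write(probs_out.reset_index(), "cluster_class_probabilities.csv"),
            r.write(rec_frame, "recommendations.tsv"),
        ]
        r.finish_stage(
            stage,
            outputs,
            {
                "n_labeled": len(labeled_ids),
                "overall_prescription_rate": float(rates.iloc[-1]["rate"]),
                "unmapped_drugs": len(rx_report["unmapped_drugs"]),
            },
        )

        stage = "evaluate"
        evaluation = {}
        for engine, recs in (("cluster", cluster_recs), ("network", network_recs)):
            if recs:
                rep = evaluate_recommendations(recs, rx_records, km)
                rep.pop("per_subject")
                evaluation[engine] = rep
        eval_path = r.outdir / "evaluation.json"
        eval_path.write_text(json.dumps(evaluation, sort_keys=True, indent=1))
        r.finish_stage(stage, [eval_path], {k: v["hit_rate"] for k, v in evaluation.items()})

        if diag_report is not None:
            r.report["diagnosis_inconsistency_rate"] = diag_report["inconsistency_rate"]
        r.report["profile"] = profile_info
        r.report["evaluation"] = evaluation
        report_path = r.outdir / "report.json"
        report_path.write_text(json.dumps(r.report, sort_keys=True, indent=1))
        (r.outdir / "run.log").write_text("\n".join(r.log_lines) + "\n")
        return r.report
    except Exception as exc:
        (r.outdir / "run.log").write_text("\n".join(r.log_lines + [f"FAILED stage={stage}: {exc}"]) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
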