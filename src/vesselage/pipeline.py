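"""End-to-end orchestration: volumes + endpoint annotations -> masks ->
centerlines -> per-segment features -> modeling table -> cross-validated
models, with every intermediate persisted and a manifest recording seeds
and per-subject QC/exclusion outcomes."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centerline import (
    NoPathError,
    build_graph,
    path_qc,
    shortest_path,
    skeletonize_mask,
    smooth_resample,
    snap_endpoint,
)
from .cohort import (
    SEGMENT_LABELS,
    SubjectRecord,
    apply_exclusions,
    assemble_table,
    write_table,
)
from .image import BinaryMask, Volume3D, load_volume, save_mask
from .modeling import (
    FAMILIES,
    ModelSpec,
    metrics_frame,
    metrics_frame_numeric,
    run_cv,
    scatter_plot,
)
from .morphometry import distance_field, segment_features
from .segmentation import SeedSpec, mask_summary, region_growing

__all__ = ["PipelineConfig", "SubjectInput", "extract_subject", "run_pipeline", "demo"]


@dataclass(frozen=True)
class SubjectInput:
    subject_id: str
    volume: str  # path to NIfTI
    annotations: str  # path to endpoint JSON
    age: float


@dataclass
class PipelineConfig:
    subjects: list[SubjectInput]
    out_dir: str
    seed: int = 0
    # segmentation
    threshold: float | None = None
    threshold_percentile: float | None = 99.0
    connectivity: int = 26
    min_mask_voxels: int = 100
    # centerline
    step_mm: float = 0.5
    smoothing: float = 0.1
    # QC
    max_snap_mm: float = 5.0
    max_chord_ratio: float = 1.0
    # modeling
    families: tuple[str, ...] = FAMILIES
    k: int = 4
    search: bool = False
    n_iter: int = 20
    pad_definition: str = "soam_over_rl"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        subjects = [SubjectInput(subject_id=str(s["id"]), volume=s["volume"],
                                 annotations=s["annotations"], age=float(s["age"]))
                    for s in raw.pop("subjects")]
        seg = raw.pop("segmentation", {})
        cl = raw.pop("centerline", {})
        qc = raw.pop("qc", {})
        mdl = raw.pop("modeling", {})
        return cls(
            subjects=subjects,
            out_dir=raw.pop("out_dir"),
            seed=int(raw.pop("seed", 0)),
            threshold=seg.get("threshold"),
            threshold_percentile=seg.get("threshold_percentile",
                                         None if "threshold" in seg else 99.0),
            connectivity=int(seg.get("connectivity", 26)),
            min_mask_voxels=int(seg.get("min_mask_voxels", 100)),
            step_mm=float(cl.get("step_mm", 0.5)),
            smoothing=float(cl.get("smoothing", 0.1)),
            max_snap_mm=float(qc.get("max_snap_mm", 5.0)),
            max_chord_ratio=float(qc.get("max_chord_ratio", 1.0)),
            families=tuple(mdl.get("families", FAMILIES)),
            k=int(mdl.get("k", 4)),
            search=bool(mdl.get("search", False)),
            n_iter=int(mdl.get("n_iter", 20)),
            pad_definition=raw.pop("pad_definition", "soam_over_rl"),
        )


def _load_annotations(path) -> dict:
    ann = json.loads(Path(path).read_text())
    missing = [lab for lab in SEGMENT_LABELS if lab not in ann]
    if missing:
        raise ValueError(f"annotation file {path} is missing segments: {missing}")
    for lab in SEGMENT_LABELS:
        for key in ("endpoint_a", "endpoint_b"):
            if key not in ann[lab] or len(ann[lab][key]) != 3:
                raise ValueError(f"annotation {path}: segment {lab!r} lacks a valid {key!r}")
    return ann


def extract_subject(
    volume: Volume3D,
    annotations: dict,
    config: PipelineConfig,
    subject_id: str,
    age: float,
) -> tuple[SubjectRecord, BinaryMask, dict]:
    """Run segmentation -> skeleton -> paths -> features for one subject.

    Returns the subject record, the vessel mask, and a details dict
    (mask summary, per-segment QC and centerline polylines in mm).
    """
    seeds = [tuple(int(v) for v in annotations[lab]["endpoint_a"]) for lab in SEGMENT_LABELS]
    seed_spec = SeedSpec(
        seeds=seeds,
        threshold=config.threshold,
        threshold_percentile=None if config.threshold is not None else config.threshold_percentile,
        connectivity=config.connectivity,
    )
    mask = region_growing(volume, seed_spec)
    summary = mask_summary(mask)
    record = SubjectRecord(subject_id=subject_id, age=age)
    details: dict = {"mask_summary": summary, "segments": {}}
    if summary["voxel_count"] < config.min_mask_voxels:
        record.segmentation_ok = False
        return record, mask, details

    skeleton = skeletonize_mask(mask)
    graph = build_graph(skeleton)
    edt = distance_field(mask)
    for lab in SEGMENT_LABELS:
        seg_detail: dict = {}
        try:
            vox_a, d_a = snap_endpoint(np.asarray(annotations[lab]["endpoint_a"], dtype=int), skeleton)
            vox_b, d_b = snap_endpoint(np.asarray(annotations[lab]["endpoint_b"], dtype=int), skeleton)
            path = shortest_path(graph, tuple(vox_a), tuple(vox_b))
            qc = path_qc(path, (d_a, d_b), max_snap_mm=config.max_snap_mm,
                         max_chord_ratio=config.max_chord_ratio)
            poly = smooth_resample(path, step=config.step_mm, smoothing=config.smoothing)
            feats = segment_features(poly, mask, lab, pad_definition=config.pad_definition, edt=edt)
            record.features[lab] = feats
            record.qc_suspect[lab] = not qc.accepted
            seg_detail = {
                "path_length_mm": path.total_weight_mm,
                "chord_path_ratio": qc.chord_path_ratio,
                "snap_distances_mm": list(qc.snap_distances_mm),
                "qc_accepted": qc.accepted,
                "qc_reasons": list(qc.reasons),
                "polyline_mm": poly.points.tolist(),
            }
        except (NoPathError, ValueError, KeyError) as exc:
            record.features[lab] = None
            record.qc_suspect[lab] = True
            seg_detail = {"error": f"{type(exc).__name__}: {exc}"}
        details["segments"][lab] = seg_detail
    return record, mask, details


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Per-subject extraction failures become exclusions; configuration and
    I/O errors at the run level halt with the stage and subject named.
    """
    out = Path(config.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "centerlines").mkdir(exist_ok=True)
    (out / "plots").mkdir(exist_ok=True)

    records: list[SubjectRecord] = []
    subject_reports = []
    for sub in config.subjects:
        report: dict = {"subject_id": sub.subject_id}
        try:
            volume = load_volume(sub.volume)
            annotations = _load_annotations(sub.annotations)
            record, mask, details = extract_subject(
                volume, annotations, config, sub.subject_id, sub.age
            )
            save_mask(mask, out / "masks" / f"{sub.subject_id}.nii.gz")
            centerlines = {
                lab: d.get("polyline_mm")
                for lab, d in details["segments"].items()
                if "polyline_mm" in d
            }
            (out / "centerlines" / f"{sub.subject_id}.json").write_text(json.dumps(centerlines))
            report.update(
                status="processed",
                mask_summary=details["mask_summary"],
                segments={
                    lab: {k: v for k, v in d.items() if k != "polyline_mm"}
                    for lab, d in details["segments"].items()
                },
            )
            records.append(record)
        except Exception as exc:
            # corrupted input for this subject: record and continue
            report.update(status="failed", stage="extraction",
                          error=f"{type(exc).__name__}: {exc}")
            records.append(SubjectRecord(subject_id=sub.subject_id, age=sub.age,
                                         segmentation_ok=False))
        subject_reports.append(report)

    retained, exclusions = apply_exclusions(records)
    (out / "exclusions.json").write_text(
        json.dumps([asdict(e) for e in exclusions], indent=2)
    )
    table = assemble_table(retained)
    write_table(table, out / "cohort.csv")

    cv_summary = None
    if len(table) >= config.k:
        specs = [ModelSpec(family=f, seed=config.seed) for f in config.families]
        result = run_cv(table, specs, k=config.k, seed=config.seed,
                        search=config.search, n_iter=config.n_iter)
        metrics_frame_numeric(result).to_csv(out / "metrics.csv", index=False)
        metrics_frame(result).to_csv(out / "metrics_table.csv", index=False)
        imp_rows = []
        preds = []
        for family, res in result.per_model.items():
            if res.importances:
                imp_rows.extend(
                    {"model": family, "rank": i + 1, "feature": name, "importance": w}
                    for i, (name, w) in enumerate(res.importances)
                )
            p = res.predictions.copy()
            p.insert(0, "model", family)
            preds.append(p)
            if len(res.predictions):
                scatter_plot(
                    res.predictions["age"], res.predictions["predicted"],
                    out / "plots" / f"{family}_validation.png",
                    title=f"{family} (validation)",
                )
        pd.DataFrame(imp_rows).to_csv(out / "importances.csv", index=False)
        pd.concat(preds, ignore_index=True).to_csv(out / "predictions.csv", index=False)
        cv_summary = {
            f: {"mean": res.mean, "std": res.std, "errors": res.errors}
            for f, res in result.per_model.items()
        }

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_subjects_in": len(config.subjects),
        "n_retained": len(table),
        "n_excluded": len(exclusions),
        "exclusions": [asdict(e) for e in exclusions],
        "subjects": subject_reports,
        "cv": cv_summary,
        "config": {
            "threshold": config.threshold,
            "threshold_percentile": config.threshold_percentile,
            "connectivity": config.connectivity,
            "step_mm": config.step_mm,
            "smoothing": config.smoothing,
            "max_snap_mm": config.max_snap_mm,
            "max_chord_ratio": config.max_chord_ratio,
            "families": list(config.families),
            "k": config.k,
            "search": config.search,
            "pad_definition": config.pad_definition,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def demo(seed: int = 0, n_subjects: int = 12, out_dir: str | Path = "vesselage-demo") -> Path:
    """Generate a volumetric phantom cohort, run the full pipeline on it and
    print the aggregated metrics table."""
    from .phantom import AgeDrivenParams, simulate_volumetric_subject, write_subject

    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20.0, 83.0, size=n_subjects)
    subjects = []
    for i, age in enumerate(ages):
        params = AgeDrivenParams(age=float(age))
        subj = simulate_volumetric_subject(params, seed=seed + 1000 + i)
        paths = write_subject(subj, out / "inputs" / f"sub{i:03d}")
        subjects.append(SubjectInput(subject_id=f"sub{i:03d}", volume=paths["volume"],
                                     annotations=paths["endpoints"], age=float(age)))
    config = PipelineConfig(subjects=subjects, out_dir=str(out / "run"), seed=seed,
                            threshold=125.0, threshold_percentile=None)
    run_dir = run_pipeline(config)
    metrics_path = run_dir / "metrics_table.csv"
    if metrics_path.exists():
        print(pd.read_csv(metrics_path).to_string(index=False))
    return run_dir
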