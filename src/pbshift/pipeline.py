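"""End-to-end orchestration: generate → align → register → normalize →
strain → stats, with YAML config, logging and a provenance manifest.

A synthetic study run is fully reproducible from (config, seed): the
cohort generator, registration and statistics all draw their randomness
from the single master seed, and every effective parameter is echoed
into ``manifest.json`` alongside per-stage output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortstats, strain
from .normalize import SubjectRecord, derive_gravity, measure_geometry, reorient_field
from .register import (
    RegistrationParams,
    affine_skull_align,
    elastic_register,
    evaluate_against_truth,
)
from .synthcohort import (
    CohortSpec,
    PBSFieldSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    intracranial_mask,
    write_cohort,
)
from .volio import (
    ImageVolume,
    MaskVolume,
    read_atlas,
    read_field,
    read_mask,
    read_volume,
    resample_to_grid,
    write_field,
)

log = logging.getLogger("pbshift")

# ROI report set: hemisphere-resolved tissue classes and surgical targets;
# the three midbrain nuclei are pooled (few voxels each)
DEFAULT_ROIS: tuple[tuple[str, ...], ...] = (
    ("GM_L",), ("GM_R",), ("WM_L",), ("WM_R",), ("Vent_L",), ("Vent_R",),
    ("T_L",), ("T_R",), ("Cad_L",), ("Cad_R",), ("Put_L",), ("Put_R",),
    ("Pall_L",), ("Pall_R",), ("STN", "RN", "SN"), ("BStem",),
)

SURGICAL_ROIS: tuple[tuple[str, ...], ...] = (
    ("T_L",), ("T_R",), ("Cad_L",), ("Cad_R",), ("Put_L",), ("Put_R",),
    ("Pall_L",), ("Pall_R",), ("STN", "RN", "SN"),
)


@dataclass
class RunConfig:
    """Every knob of a study run; serializes to one YAML document."""

    seed: int = 0
    out_dir: str = "pbshift_run"
    n_subjects: int = 5
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    pbs_field: dict = field(default_factory=dict)  # PBSFieldSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    registration: dict = field(default_factory=dict)  # RegistrationParams
    run_affine_stage: bool = True
    use_truth_fields: bool = False  # skip registration, analyse truth
    estimate_normalization: bool = True
    rois: tuple = DEFAULT_ROIS
    log_level: str = "INFO"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(n_subjects=self.n_subjects, seed=self.seed,
                          **self.cohort)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(seed=self.seed, **self.phantom)

    def field_spec(self) -> PBSFieldSpec:
        return PBSFieldSpec(seed=self.seed, **self.pbs_field)

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(**self.registration)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["rois"] = [list(r) for r in self.rois]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "rois" in d:
            d["rois"] = tuple(tuple(r) for r in d["rois"])
        return cls(**d)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _register_subject(rec: SubjectRecord, config: RunConfig, manifest: dict):
    """Skull-restricted affine + elastic stage for one subject."""
    t0 = time.time()
    if config.run_affine_stage:
        aff = affine_skull_align(rec.prone, rec.supine, rec.skull)
        moving = resample_to_grid(
            rec.prone, rec.supine, np.linalg.inv(aff.matrix), "linear"
        )
        manifest.setdefault("affine", {})[rec.id] = aff.matrix.tolist()
    else:
        moving = rec.prone
    est, report = elastic_register(
        moving, rec.supine, rec.brain, config.registration_params()
    )
    rec.est_field = est
    log.info("%s: elastic registration %.1fs (folding=%s)",
             rec.id, time.time() - t0, report.folding_detected)
    if rec.truth_field is not None:
        report = evaluate_against_truth(est, rec.truth_field, rec.brain)
        log.info("%s: endpoint error %.4f ± %.4f mm", rec.id, report.mean,
                 report.sd)
    return report


def _normalize_subject(rec: SubjectRecord, template: ImageVolume,
                       template_brain: MaskVolume, config: RunConfig) -> None:
    from .normalize import normalize_to_template

    if config.estimate_normalization:
        rec.to_template = normalize_to_template(rec.supine, template)
    elif rec.to_template is None:
        raise ValueError(f"{rec.id}: no normalization transform available")
    src = rec.est_field if rec.est_field is not None else rec.truth_field
    rec.normalized_field = reorient_field(src, rec.to_template, template)
    from .volio import resample_mask

    inv = np.linalg.inv(rec.to_template)
    rec.brain_template = resample_mask(rec.brain, template, inv)
    rec.brain_template.data &= template_brain.data
    rec.apd, rec.mcb = measure_geometry(intracranial_mask(rec.skull),
                                        rec.to_template)
    rec.gravity_supine = derive_gravity(rec.pose_supine, "supine", rec.to_template)
    rec.gravity_prone = derive_gravity(rec.pose_prone, "prone", rec.to_template)


def _cohort_statistics(records: list[SubjectRecord], template_brain: MaskVolume,
                       atlas, config: RunConfig) -> dict:
    """ROI summaries, whole-brain tables, strain tables, correlations."""
    fields = [r.normalized_field for r in records]
    # common support: template brain ∩ every subject's mapped brain
    common = template_brain.data.copy()
    for r in records:
        if r.brain_template is not None:
            common &= r.brain_template.data
    common_mask = MaskVolume(common, template_brain.affine, role="brain")

    strains = [strain.compute_strain(f, common_mask) for f in fields]
    valid = np.logical_and.reduce([s.valid for s in strains])
    tables = cohortstats.brain_tables(
        fields, common_mask,
        strain_diagonals=[s.diagonals() for s in strains],
        strain_valid=valid,
    )

    roi_rows = []
    for roi in config.rois:
        try:
            s = cohortstats.roi_summary(fields, atlas, list(roi))
        except (KeyError, ValueError) as exc:
            log.warning("ROI %s skipped: %s", roi, exc)
            continue
        roi_rows.append({
            "roi": s.roi,
            "azimuth": s.mean.azimuth,
            "elevation": s.mean.elevation,
            "magnitude": s.mean.magnitude,
            "intersubject_variability_mm": s.variability_mm,
            "variability_azimuth_deg": s.variability_azimuth,
            "variability_elevation_deg": s.variability_elevation,
        })
    roi_table = pd.DataFrame(roi_rows)

    if len(records) >= 4:
        correlations = cohortstats.correlation_analysis(records)
    else:
        log.warning("fewer than 4 subjects: correlation grid skipped")
        correlations = pd.DataFrame(
            columns=["covariate", "response", "spearman_r", "p", "slope",
                     "slope_per"])
    return {
        "displacement_table": tables["displacement"],
        "strain_table": tables.get("strain"),
        "roi_table": roi_table,
        "correlations": correlations,
        "common_mask": common_mask,
    }


# ---------------------------------------------------------------------------
# entry points


def run_synthetic_study(config: RunConfig) -> dict:
    """Full synthetic study: cohort generation through cohort statistics.

    Returns a dict with the statistics tables, per-subject registration
    reports, and the path of the output directory; all intermediates and
    a provenance manifest are written under ``config.out_dir``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    t0 = time.time()
    records = generate_cohort(
        config.cohort_spec(), config.phantom_spec(), config.field_spec(),
        volumes=not config.use_truth_fields,
    )
    write_cohort(records, out / "cohort")
    manifest["stages"]["generate"] = {
        "seconds": time.time() - t0,
        "checksums": {r.id: _checksum(r.supine.data) for r in records},
    }
    log.info("generated %d subjects in %.1fs", len(records), time.time() - t0)

    reports = {}
    if not config.use_truth_fields:
        t0 = time.time()
        for rec in records:
            try:
                reports[rec.id] = _register_subject(rec, config, manifest)
            except Exception as exc:
                raise RuntimeError(f"stage 'register' failed for {rec.id}") from exc
        manifest["stages"]["register"] = {"seconds": time.time() - t0}

    template, _, template_brain, template_atlas = generate_phantom(
        config.phantom_spec()
    )
    t0 = time.time()
    for rec in records:
        try:
            _normalize_subject(rec, template, template_brain, config)
        except Exception as exc:
            raise RuntimeError(f"stage 'normalize' failed for {rec.id}") from exc
    manifest["stages"]["normalize"] = {"seconds": time.time() - t0}

    t0 = time.time()
    stats = _cohort_statistics(records, template_brain, template_atlas, config)
    manifest["stages"]["stats"] = {"seconds": time.time() - t0}

    _write_outputs(out, records, reports, stats, manifest)
    stats["registration_reports"] = reports
    stats["records"] = records
    stats["out_dir"] = str(out)
    return stats


def run_real_study(config: RunConfig, data_dir: str | Path) -> dict:
    """Same pipeline on an on-disk cohort (no synthesis stage).

    ``data_dir`` holds per-subject directories
    ``sub-XX/{supine,prone,skull,brain,atlas}.nii.gz`` with
    ``atlas_labels.tsv`` and optional ``meta.json`` (pose rotations) and
    ``truth_field.nii.gz``. Missing required files raise with the
    subject and file names.
    """
    logging.basicConfig(level=config.log_level)
    data_dir = Path(data_dir)
    sub_dirs = sorted(d for d in data_dir.glob("sub-*") if d.is_dir())
    if not sub_dirs:
        raise FileNotFoundError(f"no sub-* directories in {data_dir}")

    records = []
    for d in sub_dirs:
        required = ["supine.nii.gz", "skull.nii.gz", "brain.nii.gz",
                    "atlas.nii.gz", "atlas_labels.tsv"]
        if config.use_truth_fields:
            required.append("truth_field.nii.gz")
        else:
            required.append("prone.nii.gz")
        missing = [f for f in required if not (d / f).exists()]
        if missing:
            raise FileNotFoundError(f"{d.name}: missing {', '.join(missing)}")
        meta = {}
        if (d / "meta.json").exists():
            meta = json.loads((d / "meta.json").read_text())
        rec = SubjectRecord(
            id=d.name,
            supine=read_volume(d / "supine.nii.gz"),
            prone=(read_volume(d / "prone.nii.gz")
                   if (d / "prone.nii.gz").exists() else None),
            skull=read_mask(d / "skull.nii.gz", role="skull"),
            brain=read_mask(d / "brain.nii.gz", role="brain"),
            atlas=read_atlas(d / "atlas.nii.gz", d / "atlas_labels.tsv"),
            pose_supine=np.asarray(meta.get("pose_supine", np.eye(3).tolist())),
            pose_prone=np.asarray(meta.get("pose_prone", np.eye(3).tolist())),
            tilt_supine=meta.get("tilt_supine"),
            tilt_prone=meta.get("tilt_prone"),
            meta=meta,
        )
        if "to_template" in meta:
            rec.to_template = np.asarray(meta["to_template"])
        if (d / "truth_field.nii.gz").exists():
            rec.truth_field = read_field(d / "truth_field.nii.gz")
        records.append(rec)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    reports = {}
    if not config.use_truth_fields:
        for rec in records:
            try:
                reports[rec.id] = _register_subject(rec, config, manifest)
            except Exception as exc:
                raise RuntimeError(f"stage 'register' failed for {rec.id}") from exc

    template, _, template_brain, template_atlas = generate_phantom(
        config.phantom_spec()
    )
    for rec in records:
        try:
            _normalize_subject(rec, template, template_brain, config)
        except Exception as exc:
            raise RuntimeError(f"stage 'normalize' failed for {rec.id}") from exc

    stats = _cohort_statistics(records, template_brain, template_atlas, config)
    _write_outputs(out, records, reports, stats, manifest)
    stats["registration_reports"] = reports
    stats["records"] = records
    stats["out_dir"] = str(out)
    return stats


def _write_outputs(out: Path, records, reports, stats, manifest) -> None:
    for rec in records:
        d = out / "cohort" / rec.id
        d.mkdir(parents=True, exist_ok=True)
        if rec.est_field is not None:
            write_field(rec.est_field, d / "est_field.nii.gz")
        if rec.normalized_field is not None:
            write_field(rec.normalized_field, d / "normalized_field.nii.gz")

    stats["displacement_table"].to_csv(out / "table_displacement.tsv",
                                       sep="\t", index=False)
    if stats["strain_table"] is not None:
        stats["strain_table"].to_csv(out / "table_strain.tsv", sep="\t",
                                     index=False)
    stats["roi_table"].to_csv(out / "roi_summary.tsv", sep="\t", index=False)
    stats["correlations"].to_csv(out / "correlations.tsv", sep="\t",
                                 index=False)

    results = {
        "displacement": stats["displacement_table"].to_dict("records"),
        "strain": (stats["strain_table"].to_dict("records")
                   if stats["strain_table"] is not None else None),
        "roi": stats["roi_table"].to_dict("records"),
        "correlations": stats["correlations"].to_dict("records"),
        "registration": {
            sid: {"mean": r.mean, "sd": r.sd, "p5": r.p5, "p95": r.p95}
            for sid, r in reports.items()
        },
        "subjects": {
            r.id: {
                "apd": r.apd, "mcb": r.mcb,
                "gravity_supine": {"azimuth": r.gravity_supine.azimuth,
                                   "elevation": r.gravity_supine.elevation},
                "gravity_prone": {"azimuth": r.gravity_prone.azimuth,
                                  "elevation": r.gravity_prone.elevation},
            }
            for r in records
        },
    }
    (out / "results.json").write_text(json.dumps(results, indent=1))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
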