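"""Config-driven orchestration: simulate -> fit maps -> extract features ->
reduce -> model -> report.

Two entry points:

* :func:`analyze_cohort` — in-memory pipeline on a generated cohort,
  returning the feature table, reduced signature and model results for one
  classification task.  This is what tests and batch analyses call.
* :func:`run_pipeline` — staged, file-based run under an output directory
  (NIfTI volumes/maps, CSV tables, JSON models), resumable stage by stage
  (existing outputs are reused) and finished by a content-hash manifest, so
  identical config + seed reproduce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import modeling, phantom, selection
from .grid import Volume, VolumeGrid
from .maps import MAP_NAMES, compute_study_maps
from .modeling import BootstrapConfig, ModelResult
from .roi import SegmentationRecord

log = logging.getLogger("prostarad")


# --------------------------------------------------------------------------
# configuration


@dataclass
class SelectionConfig:
    k: int = 25
    delta: float = 0.5
    alpha: float = 0.6


@dataclass
class PipelineConfig:
    cohort: phantom.CohortSpec = field(default_factory=phantom.CohortSpec)
    task: str = "std3D"
    maps: tuple[str, ...] = MAP_NAMES
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    max_order: int = 10
    plateau_tol: float = 0.005
    out_dir: str = "prostarad_run"

    def __post_init__(self) -> None:
        if self.task not in feat.TASKS:
            raise ValueError(f"task must be one of {feat.TASKS}, got {self.task!r}")


def _dataclass_from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def load_config(path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("lesion_params", "ht_params"):
        if key in cohort_raw:
            cohort_raw[key] = phantom.TissueParams(**cohort_raw[key])
    if "aif" in cohort_raw:
        cohort_raw["aif"] = phantom.AifParams(**cohort_raw["aif"])
    for key in ("t2w_grid", "dwi_grid", "dce_grid"):
        if key in cohort_raw:
            g = cohort_raw[key]
            cohort_raw[key] = VolumeGrid(
                tuple(g["shape"]), tuple(g.get("spacing", (1, 1, 1))), tuple(g.get("origin", (0, 0, 0)))
            )
    for key in ("bvals", "bval_averages", "dce_times", "voi_axes_mm", "voi_axes_z_mm"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort = _dataclass_from_dict(phantom.CohortSpec, cohort_raw)
    return PipelineConfig(
        cohort=cohort,
        task=raw.get("task", "std3D"),
        maps=tuple(raw.get("maps", MAP_NAMES)),
        selection=_dataclass_from_dict(SelectionConfig, raw.get("selection", {})),
        bootstrap=_dataclass_from_dict(BootstrapConfig, raw.get("bootstrap", {})),
        max_order=int(raw.get("max_order", 10)),
        plateau_tol=float(raw.get("plateau_tol", 0.005)),
        out_dir=str(raw.get("out_dir", "prostarad_run")),
    )


# --------------------------------------------------------------------------
# in-memory pipeline


@dataclass
class TaskAnalysis:
    task: str
    table: pd.DataFrame
    reduced: selection.ReducedFeatureSet
    results: list[ModelResult]
    best_order: int
    final: ModelResult


def cohort_maps(
    cohort: phantom.SyntheticCohort, maps: tuple[str, ...] = MAP_NAMES
) -> dict[str, dict[str, Volume]]:
    """Fit the parameter maps of every study (resampled to the T2W grid).

    Compute once and pass to :func:`cohort_feature_table` when extracting
    several tasks from the same cohort — map fitting dominates the runtime.
    """
    return {
        st.subject_id: compute_study_maps(st, cohort.spec.aif, maps=maps)
        for st in cohort.studies
    }


def cohort_feature_table(
    cohort: phantom.SyntheticCohort,
    task: str,
    maps: tuple[str, ...] = MAP_NAMES,
    maps_by_subject: dict[str, dict[str, Volume]] | None = None,
) -> pd.DataFrame:
    """Fit all maps of every study and extract the task's feature table."""
    if maps_by_subject is None:
        maps_by_subject = cohort_maps(cohort, maps)
    return feat.extract_feature_table(maps_by_subject, cohort.segmentations, task)


def analyze_table(
    table: pd.DataFrame,
    task: str,
    sel_cfg: SelectionConfig,
    boot_cfg: BootstrapConfig,
    max_order: int = 10,
    plateau_tol: float = 0.005,
) -> TaskAnalysis:
    """Feature reduction + bootstrap forward modelling on a feature table."""
    reduced = selection.reduce_feature_set(table, sel_cfg.k, sel_cfg.delta, sel_cfg.alpha)
    X = table[reduced.features].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    results = modeling.forward_build_models(X, y, reduced.features, boot_cfg, max_order)
    best = modeling.choose_best_order(results, plateau_tol)
    best_feats = results[best - 1].features
    Xb = table[best_feats].to_numpy(dtype=float)
    final_cfg = dataclasses.replace(boot_cfg, seed=boot_cfg.seed + 1)
    final = modeling.finalize_model(Xb, y, best_feats, final_cfg)
    return TaskAnalysis(task, table, reduced, results, best, final)


def analyze_cohort(cohort: phantom.SyntheticCohort, cfg: PipelineConfig) -> TaskAnalysis:
    table = cohort_feature_table(cohort, cfg.task, cfg.maps)
    return analyze_table(
        table, cfg.task, cfg.selection, cfg.bootstrap, cfg.max_order, cfg.plateau_tol
    )


# --------------------------------------------------------------------------
# staged file-based pipeline


def _save_study(study: phantom.SyntheticStudy, cdir: Path) -> None:
    study.t2w.save(cdir / f"{study.subject_id}_T2W.nii")
    study.dwi.save(cdir / f"{study.subject_id}_DWI.nii")
    study.dce.save(cdir / f"{study.subject_id}_DCE.nii")
    for m in study.masks:
        m.mask.with_data(m.mask.data.astype(np.uint8)).save(cdir / "masks" / f"{m.seg_id}.nii")


def stage_simulate(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    cdir = run / "cohort"
    if (cdir / "manifest.csv").exists() and not force:
        log.info("simulate: reusing %s", cdir)
        return cdir
    (cdir / "masks").mkdir(parents=True, exist_ok=True)
    cohort = phantom.generate_cohort(cfg.cohort)
    for st in cohort.studies:
        _save_study(st, cdir)
    cohort.manifest.to_csv(cdir / "manifest.csv", index=False)
    meta = {
        "bvals": list(cfg.cohort.bvals),
        "dce_times": list(cfg.cohort.dce_times),
        "aif": dataclasses.asdict(cfg.cohort.aif),
    }
    (cdir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    log.info("simulate: wrote %d studies, %d segmentations", len(cohort.studies), len(cohort.manifest))
    return cdir


def _load_cohort_dir(cdir: Path) -> tuple[list[phantom.SyntheticStudy], pd.DataFrame, phantom.AifParams]:
    manifest = pd.read_csv(cdir / "manifest.csv")
    meta = json.loads((cdir / "meta.json").read_text())
    aif = phantom.AifParams(**meta["aif"])
    studies = []
    for sid in manifest["subject_id"].unique():
        masks = []
        for _, row in manifest[manifest["subject_id"] == sid].iterrows():
            mvol = Volume.from_nifti(cdir / "masks" / f"{row.seg_id}.nii")
            masks.append(
                SegmentationRecord(row.seg_id, sid, row.label, mvol.with_data(mvol.data.astype(bool)))
            )
        studies.append(
            phantom.SyntheticStudy(
                subject_id=sid,
                t2w=Volume.from_nifti(cdir / f"{sid}_T2W.nii"),
                dwi=Volume.from_nifti(cdir / f"{sid}_DWI.nii"),
                dce=Volume.from_nifti(cdir / f"{sid}_DCE.nii"),
                bvals=np.asarray(meta["bvals"], dtype=float),
                dce_times=np.asarray(meta["dce_times"], dtype=float),
                masks=masks,
            )
        )
    return studies, manifest, aif


def stage_fit_maps(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    mdir = run / "maps"
    if (mdir / "done.json").exists() and not force:
        log.info("fit-maps: reusing %s", mdir)
        return mdir
    mdir.mkdir(parents=True, exist_ok=True)
    studies, _, aif = _load_cohort_dir(run / "cohort")
    for st in studies:
        for name, vol in compute_study_maps(st, aif, maps=cfg.maps).items():
            vol.with_data(np.asarray(vol.data, dtype=np.float32)).save(
                mdir / f"{st.subject_id}_{name}.nii"
            )
        log.info("fit-maps: %s done", st.subject_id)
    (mdir / "done.json").write_text(json.dumps({"maps": list(cfg.maps)}))
    return mdir


def stage_extract_features(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    out = run / f"features_{cfg.task}.csv"
    if out.exists() and not force:
        log.info("extract-features: reusing %s", out)
        return out
    studies, _, _ = _load_cohort_dir(run / "cohort")
    computed = json.loads((run / "maps" / "done.json").read_text())["maps"]
    missing = [m for m in feat.required_maps(cfg.task) if m not in computed]
    if missing:
        raise RuntimeError(
            f"stage extract-features: task {cfg.task!r} needs maps {missing} "
            "that the fit-maps stage did not produce"
        )
    maps_by_subject = {
        st.subject_id: {
            name: Volume.from_nifti(run / "maps" / f"{st.subject_id}_{name}.nii")
            for name in computed
        }
        for st in studies
    }
    segs = [m for st in studies for m in st.masks]
    table = feat.extract_feature_table(maps_by_subject, segs, cfg.task)
    table.to_csv(out)
    log.info("extract-features: %d rows x %d features", len(table), table.shape[1] - 1)
    return out


def stage_select(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    out = run / f"reduced_{cfg.task}.csv"
    if out.exists() and not force:
        log.info("select: reusing %s", out)
        return out
    table = pd.read_csv(run / f"features_{cfg.task}.csv", index_col=0)
    reduced = selection.reduce_feature_set(
        table, cfg.selection.k, cfg.selection.delta, cfg.selection.alpha
    )
    reduced.to_frame().to_csv(out, index=False)
    log.info("select: kept %d features", len(reduced.features))
    return out


def stage_model(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    out = run / f"models_{cfg.task}.json"
    if out.exists() and not force:
        log.info("model: reusing %s", out)
        return out
    table = pd.read_csv(run / f"features_{cfg.task}.csv", index_col=0)
    ranked = pd.read_csv(run / f"reduced_{cfg.task}.csv")["feature"].tolist()
    X = table[ranked].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    results = modeling.forward_build_models(X, y, ranked, cfg.bootstrap, cfg.max_order)
    best = modeling.choose_best_order(results, cfg.plateau_tol)
    feats = results[best - 1].features
    final_cfg = dataclasses.replace(cfg.bootstrap, seed=cfg.bootstrap.seed + 1)
    final = modeling.finalize_model(
        table[feats].to_numpy(dtype=float), y, feats, final_cfg
    )
    payload = {
        "task": cfg.task,
        "best_order": best,
        "final": dataclasses.asdict(final),
        "orders": [dataclasses.asdict(r) for r in results],
    }
    out.write_text(json.dumps(payload, indent=1, sort_keys=True))
    modeling.results_table(results).to_csv(run / f"performance_{cfg.task}.csv", index=False)
    log.info("model: best order %d, auc632=%.3f", best, results[best - 1].auc632)
    return out


def stage_report(cfg: PipelineConfig, run: Path, force: bool = False) -> Path:
    out = run / "manifest.json"
    models = json.loads((run / f"models_{cfg.task}.json").read_text())
    report = {
        "task": cfg.task,
        "best_order": models["best_order"],
        "auc632": models["final"]["auc632"],
        "sens632": models["final"]["sens632"],
        "spec632": models["final"]["spec632"],
        "features": models["final"]["features"],
    }
    (run / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    skip = {"manifest.json", "config.yaml", "pipeline.log"}  # run metadata
    hashes = {}
    for p in sorted(run.rglob("*")):
        if p.is_file() and p.name not in skip:
            hashes[str(p.relative_to(run))] = hashlib.sha256(p.read_bytes()).hexdigest()
    out.write_text(json.dumps(hashes, indent=1, sort_keys=True))
    return out


STAGES = {
    "simulate": stage_simulate,
    "fit-maps": stage_fit_maps,
    "extract-features": stage_extract_features,
    "select": stage_select,
    "model": stage_model,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> Path:
    """Run every stage under ``cfg.out_dir``; existing outputs are reused."""
    run = Path(cfg.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.yaml").write_text(yaml.safe_dump(_config_to_dict(cfg), sort_keys=True))
    for name, fn in STAGES.items():
        try:
            fn(cfg, run, force=force)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return run


def _config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("t2w_grid", "dwi_grid", "dce_grid"):
        g = cfg.cohort.__getattribute__(key)
        d["cohort"][key] = {"shape": list(g.shape), "spacing": list(g.spacing), "origin": list(g.origin)}
    d["maps"] = list(cfg.maps)
    d["cohort"]["bval_averages"] = [int(v) for v in d["cohort"]["bval_averages"]]
    for key in ("bvals", "dce_times", "voi_axes_mm", "voi_axes_z_mm"):
        d["cohort"][key] = [float(v) for v in d["cohort"][key]]
    return d
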