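"""End-to-end orchestration: simulate -> shells -> features -> train -> evaluate.

Every stage writes open formats (NIfTI, CSV, JSON) into a run directory and
records the configuration hash it ran under in ``manifest.json``; rerunning
with an unchanged configuration skips stages whose outputs already exist,
and two runs with the same configuration and master seed produce identical
results tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import bootstrap_ci, youden_threshold
from .features.discretize import DiscretizationConfig
from .features.extract import extract_multi_voi, extract_multi_voi_firstorder
from .pipeline import FeatureTable, ModelSpec, run_nine_models, cross_validated_probabilities
from .shells import SHELL_DISTANCES_MM, build_voi_set
from .synthetic import PhantomSpec, generate_cohort, write_cohort
from .volume import CtVolume, VoxelMask

log = logging.getLogger("peristas")

STAGES = ("simulate", "shells", "features", "train", "evaluate")


@dataclass
class RunConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    out_dir: str = "peristas_run"
    n_pos: int = 12
    n_neg: int = 28
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    shell_distances: tuple[float, ...] = SHELL_DISTANCES_MM
    band_mm: float = 3.0
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    feature_mode: str = "firstorder"  # "full" (6,808 columns) or "firstorder"
    train_frac: float = 0.8
    n_boot: int = 1000
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("grid_shape", "spacing_mm"):
            d["phantom"][key] = list(d["phantom"][key])
        d["model"]["grid"] = [list(g) for g in d["model"]["grid"]]
        d["shell_distances"] = list(d["shell_distances"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        for key in ("grid_shape", "spacing_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        mo = dict(d.pop("model", {}))
        if "grid" in mo:
            mo["grid"] = tuple(tuple(g) for g in mo["grid"])
        dc = dict(d.pop("discretization", {}))
        if dc.get("resegment_range"):
            dc["resegment_range"] = tuple(dc["resegment_range"])
        if "shell_distances" in d:
            d["shell_distances"] = tuple(d["shell_distances"])
        return cls(
            phantom=PhantomSpec(**ph),
            model=ModelSpec(**mo),
            discretization=DiscretizationConfig(**dc),
            **d,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest_path(run_dir: Path) -> Path:
    return run_dir / "manifest.json"


def _load_manifest(run_dir: Path) -> dict:
    p = _manifest_path(run_dir)
    return json.loads(p.read_text()) if p.exists() else {"stages": {}}


def _stage_done(manifest: dict, stage: str, cfg_hash: str) -> bool:
    return manifest["stages"].get(stage, {}).get("config_hash") == cfg_hash


def _mark_stage(run_dir: Path, manifest: dict, stage: str, cfg_hash: str, outputs: list[str]) -> None:
    manifest["stages"][stage] = {"config_hash": cfg_hash, "outputs": outputs}
    _manifest_path(run_dir).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_full_pipeline(config: RunConfig, resume: bool = True) -> Path:
    """Execute all stages in order; returns the run directory.

    Stages whose outputs exist under an unchanged config hash are skipped.
    A stage failure raises with the stage name; completed outputs remain.
    """
    logging.basicConfig(level=config.log_level)
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(run_dir / "run.yaml")
    manifest = _load_manifest(run_dir)
    manifest["config_hash"] = cfg_hash
    manifest["seed"] = config.seed

    try:
        # ---- simulate ----------------------------------------------------
        cohort_dir = run_dir / "cohort"
        if not (resume and _stage_done(manifest, "simulate", cfg_hash)):
            log.info("stage simulate: %d+/%d- cases", config.n_pos, config.n_neg)
            cases = generate_cohort(config.n_pos, config.n_neg, config.phantom, config.seed)
            write_cohort(cases, cohort_dir)
            _mark_stage(run_dir, manifest, "simulate", cfg_hash, [str(cohort_dir / "manifest.csv")])

        cohort = pd.read_csv(cohort_dir / "manifest.csv")

        # ---- shells ------------------------------------------------------
        if not (resume and _stage_done(manifest, "shells", cfg_hash)):
            log.info("stage shells: %d cases", len(cohort))
            summaries = {}
            for cid in cohort["case_id"]:
                cdir = cohort_dir / cid
                core = VoxelMask.load(cdir / "tumor.nii.gz")
                lung = VoxelMask.load(cdir / "lung.nii.gz")
                vois = build_voi_set(core, lung, config.shell_distances, config.band_mm)
                vdir = run_dir / "vois" / cid
                vdir.mkdir(parents=True, exist_ok=True)
                for name, m in vois.members().items():
                    m.save(vdir / f"{name}.nii.gz")
                summaries[cid] = {
                    "voxel_counts": vois.voxel_counts(),
                    "volumes_mm3": vois.volumes_mm3(),
                }
            (run_dir / "voi_summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))
            _mark_stage(run_dir, manifest, "shells", cfg_hash, [str(run_dir / "voi_summary.json")])

        # ---- features ----------------------------------------------------
        feat_csv = run_dir / "features.csv"
        if not (resume and _stage_done(manifest, "features", cfg_hash)):
            log.info("stage features: mode=%s", config.feature_mode)
            extractor = extract_multi_voi if config.feature_mode == "full" else extract_multi_voi_firstorder
            rows, ids = [], []
            for cid in cohort["case_id"]:
                cdir = cohort_dir / cid
                image = CtVolume.load(cdir / "image.nii.gz")
                core = VoxelMask.load(cdir / "tumor.nii.gz")
                lung = VoxelMask.load(cdir / "lung.nii.gz")
                vois = build_voi_set(core, lung, config.shell_distances, config.band_mm)
                fv = extractor(image, vois, config.discretization)
                if fv.missing_vois:
                    log.warning("case %s: empty VOIs %s; excluded downstream", cid, fv.missing_vois)
                rows.append(fv.values)
                ids.append(cid)
                names = fv.names
            df = pd.DataFrame(rows, index=ids, columns=names)
            df.insert(0, "label", cohort.set_index("case_id").loc[ids, "label"].to_numpy())
            df.to_csv(feat_csv, index_label="case_id", float_format="%.10g")
            _mark_stage(run_dir, manifest, "features", cfg_hash, [str(feat_csv)])

        # ---- train -------------------------------------------------------
        results_csv = run_dir / "model_results.csv"
        df = pd.read_csv(feat_csv, index_col="case_id")
        table = FeatureTable(df.drop(columns="label"), df["label"].to_numpy())
        if not (resume and _stage_done(manifest, "train", cfg_hash)):
            log.info("stage train: nine models")
            results = run_nine_models(table, config.model, config.train_frac)
            results.to_csv(results_csv, index=False, float_format="%.10g")
            _mark_stage(run_dir, manifest, "train", cfg_hash, [str(results_csv)])

        # ---- evaluate ----------------------------------------------------
        report_json = run_dir / "evaluation.json"
        if not (resume and _stage_done(manifest, "evaluate", cfg_hash)):
            log.info("stage evaluate: eight-VOI model operating point")
            clean, _ = table.drop_incomplete_cases()
            probs, _, _ = cross_validated_probabilities(clean, config.model)
            cut, rep = youden_threshold(probs, clean.labels)
            lo, hi = bootstrap_ci(probs, clean.labels, config.n_boot, config.seed)
            rep.ci_low, rep.ci_high, rep.n_boot = lo, hi, config.n_boot
            report_json.write_text(json.dumps(rep.to_dict(), indent=2, sort_keys=True))
            _mark_stage(run_dir, manifest, "evaluate", cfg_hash, [str(report_json)])
    except Exception as exc:  # halt with stage context; partial outputs remain
        done = [s for s in STAGES if _stage_done(manifest, s, cfg_hash)]
        raise RuntimeError(f"pipeline halted after stages {done}: {exc}") from exc

    return run_dir
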