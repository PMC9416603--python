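"""End-to-end pipeline orchestration with structured config and manifests.

``run_all`` chains simulate -> preprocess -> train-extractor -> extract ->
select -> classify into one seeded, reproducible run directory.  Every
stage's outputs are written beside a resolved copy of the configuration and
a manifest with SHA-256 checksums, and all randomness derives from the
single global seed via documented per-stage offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import classify as clf
from . import synthio
from .cnn import DualStreamCNN, extract, save_model
from .preprocess import save_windows, segment_dataset, split
from .relieff import ReliefF, save_weights, select

log = logging.getLogger("gaitfuse")

# fixed per-stage seed offsets from the global seed
STAGE_SEEDS = {"simulate": 0, "split": 1, "train": 2, "relieff": 3, "cv": 4}


@dataclass
class SimulateConfig:
    subjects: int = 6
    modes: list = field(default_factory=lambda: [m.name for m in
                                                 synthio.MotionMode])
    reps: int = 4
    duration: float = 12.0


@dataclass
class PreprocessConfig:
    window: int = 600
    stride: int = 600
    trim: float = 0.25
    ratio: list = field(default_factory=lambda: [7, 1, 2])


@dataclass
class TrainConfigSection:
    epochs: int = 30
    batch_size: int = 64
    lr: float = 0.001
    tap: str = "fc32"


@dataclass
class SelectConfig:
    k: int = 10
    threshold: float = 0.1


@dataclass
class ClassifyConfig:
    folds: int = 5
    classifiers: list = field(default_factory=lambda: list(clf.CLASSIFIERS))
    conditions: list = field(default_factory=lambda: ["IEDL"])
    per_subject: bool = True


@dataclass
class PipelineConfig:
    seed: int = 42
    outdir: str = "runs/run0"
    verbosity: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfigSection = field(default_factory=TrainConfigSection)
    select: SelectConfig = field(default_factory=SelectConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {"simulate": SimulateConfig, "preprocess": PreprocessConfig,
                    "train": TrainConfigSection, "select": SelectConfig,
                    "classify": ClassifyConfig}
        kwargs = {}
        for key, value in d.items():
            if key in sections:
                cls = sections[key]
                allowed = {f.name for f in fields(cls)}
                unknown = set(value) - allowed
                if unknown:
                    raise ValueError(
                        f"unknown keys {sorted(unknown)} in config section "
                        f"{key!r}; allowed: {sorted(allowed)}")
                kwargs[key] = cls(**value)
            elif key in {"seed", "outdir", "verbosity"}:
                kwargs[key] = value
            else:
                raise ValueError(
                    f"unknown config section {key!r}; allowed: "
                    f"{sorted(sections) + ['seed', 'outdir', 'verbosity']}")
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as f:
            return PipelineConfig.from_dict(yaml.safe_load(f) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> Path:
    """Run the full pipeline; returns the run directory.

    Stage failures abort with a stage-named error; outputs of completed
    stages are preserved in the run directory.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=False)

    outputs: list[Path] = [out / "config.yaml"]
    stage = "simulate"
    try:
        log.info("stage %s: %d subjects x %s x %d reps, %.1f s, seed %d",
                 stage, cfg.simulate.subjects, cfg.simulate.modes,
                 cfg.simulate.reps, cfg.simulate.duration,
                 cfg.seed + STAGE_SEEDS["simulate"])
        profiles = synthio.default_profiles(cfg.simulate.subjects)
        bundles = synthio.generate_dataset(
            profiles, cfg.simulate.modes, cfg.simulate.reps,
            cfg.simulate.duration, cfg.seed + STAGE_SEEDS["simulate"])
        data_dir = out / "data"
        synthio.write_dataset(bundles, data_dir)
        outputs += sorted(data_dir.glob("*"))

        stage = "preprocess"
        ws = segment_dataset(bundles, cfg.preprocess.window,
                             cfg.preprocess.stride, cfg.preprocess.trim)
        ws = split(ws, tuple(cfg.preprocess.ratio),
                   seed=cfg.seed + STAGE_SEEDS["split"])
        log.info("stage %s: %d window pairs", stage, len(ws))
        save_windows(ws, out / "windows.h5")
        outputs.append(out / "windows.h5")

        stage = "train-extractor"
        tr, va = ws.split_subset("train"), ws.split_subset("val")
        model = DualStreamCNN(epochs=cfg.train.epochs,
                              batch_size=cfg.train.batch_size,
                              lr=cfg.train.lr, tap=cfg.train.tap,
                              random_state=cfg.seed + STAGE_SEEDS["train"])
        model.fit(tr.as_matrix(), tr.labels,
                  validation_data=(va.as_matrix(), va.labels) if len(va)
                  else None)
        save_model(model, out / "extractor.npz")
        outputs.append(out / "extractor.npz")
        log.info("stage %s: final train accuracy %.3f", stage,
                 model.history_["accuracy"][-1])

        stage = "extract"
        eval_ws = ws.split_subset("train", "test")
        fm = extract(model, eval_ws)
        fm.to_csv(out / "features_raw.csv")
        outputs.append(out / "features_raw.csv")

        stage = "select"
        sel = ReliefF(n_neighbors=cfg.select.k,
                      threshold=cfg.select.threshold,
                      random_state=cfg.seed + STAGE_SEEDS["relieff"])
        sel.fit(fm.values, fm.labels)
        fm_sel = select(fm, sel)
        save_weights(fm.feature_names, sel, out / "weights.csv")
        fm_sel.to_csv(out / "features_selected.csv")
        coords = clf.visualization_coords(fm, sel)
        coords.to_csv(out / "features_3d.csv", index=False)
        outputs += [out / "weights.csv", out / "features_selected.csv",
                    out / "features_3d.csv"]
        log.info("stage %s: %d/%d features kept", stage,
                 len(fm_sel.feature_names), len(fm.feature_names))

        stage = "classify"
        cv = clf.CVConfig(folds=cfg.classify.folds,
                          seed=cfg.seed + STAGE_SEEDS["cv"])
        reports = []
        for kind in cfg.classify.classifiers:
            rep = clf.cross_validate(fm_sel.values, fm_sel.labels, kind, cv,
                                     condition="IEDL")
            log.info("stage %s: IEDL %s mean accuracy %.3f", stage, kind,
                     rep.mean_accuracy)
            reports.append(rep)
        extra = [c for c in cfg.classify.conditions if c != "IEDL"]
        if extra:
            reports += clf.run_comparison(ws, extra, cv=cv,
                                          epochs=cfg.train.epochs,
                                          seed=cfg.seed + STAGE_SEEDS["train"])
        clf.save_reports(reports, out / "reports.json")
        clf.reports_table(reports).to_csv(out / "comparison.csv")
        outputs += [out / "reports.json", out / "comparison.csv"]

        if cfg.classify.per_subject and cfg.simulate.subjects >= 2:
            table = clf.per_subject_eval(
                ws, epochs=cfg.train.epochs,
                seed=cfg.seed + STAGE_SEEDS["train"], cv=cv,
                split_seed=cfg.seed + STAGE_SEEDS["split"])
            table.to_csv(out / "per_subject.csv")
            outputs.append(out / "per_subject.csv")
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {str(p.relative_to(out)): _sha256(p) for p in outputs
                if p.is_file()}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return out
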