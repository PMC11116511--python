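"""End-to-end orchestration: phantoms -> FSNet -> ROI -> SDNet -> reports.

A run directory receives the generated cohorts, both model checkpoints
(`.npz` weights + JSON sidecar with config and history), per-stage reports
and a manifest with every artifact path, the derived stage seeds and the
config hash.  One global seed deterministically derives all stage seeds.

The ablation harness shares the (identical) segmentation stage and ROI
extraction across presets and retrains only the classifier, mirroring the
image-only / mask-only / image+mask / image+mask+attention design.
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

from .core import ROISample
from .fsnet import (FSNet, SegModelConfig, SegTrainConfig, SliceBatch,
                    build_fsnet, predict_slices, train_fsnet)
from .io import load_mask, load_volume
from .metrics import (ClassificationReport, classification_table,
                      evaluate_classifier, segmentation_report)
from .phantom import PhantomSpec, generate_cohort
from .roi import extract_roi
from .sdnet import (SDNet, SDNetConfig, SDTrainConfig, build_sdnet,
                    predict_sex, train_sdnet)

log = logging.getLogger("sdetnet")

#: preset -> (channels, use_agam)
ABLATION_PRESETS = {
    "image_only": (("image",), False),
    "mask_only": (("mask",), False),
    "image_mask": (("image", "mask"), False),
    "image_mask_agam": (("image", "mask"), True),
}


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seg_counts: tuple[int, int, int] = (30, 10, 10)
    cls_counts: tuple[int, int, int] = (120, 40, 100)
    seg_model: SegModelConfig = field(default_factory=SegModelConfig)
    seg_train: SegTrainConfig = field(default_factory=SegTrainConfig)
    roi_size: tuple[int, int, int] = (122, 128, 128)
    binarize_mask: bool = True
    keep_largest_component: bool = False
    sdnet: SDNetConfig = field(default_factory=SDNetConfig)
    sd_train: SDTrainConfig = field(default_factory=SDTrainConfig)
    preset: str = "image_mask_agam"
    seed: int = 0
    out_dir: str = "runs/run0"

    def __post_init__(self) -> None:
        if self.preset not in ABLATION_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from "
                             f"{sorted(ABLATION_PRESETS)}")
        channels, use_agam = ABLATION_PRESETS[self.preset]
        self.sdnet = dataclasses.replace(
            self.sdnet, input_channels=len(channels), use_agam=use_agam)

    @property
    def channels(self) -> tuple[str, ...]:
        return ABLATION_PRESETS[self.preset][0]

    @classmethod
    def tiny(cls, seed: int = 0, out_dir: str = "runs/tiny",
             dimorphism_factor: float = 1.6,
             preset: str = "image_mask_agam") -> "PipelineConfig":
        """Desk-scale profile: 32-cubed phantoms and small networks.

        Sized so a full run finishes in about a minute on one CPU while
        leaving the study design intact (balanced sexes, held-out test set,
        stage-wise training identical to the full profile).
        """
        return cls(
            phantom=PhantomSpec.tiny(dimorphism_factor=dimorphism_factor),
            seg_counts=(8, 2, 2),
            cls_counts=(60, 12, 40),
            seg_model=SegModelConfig(backbone="tiny", input_size=(32, 32)),
            seg_train=SegTrainConfig(epochs=35, batch_size=16, initial_lr=1e-3,
                                     plateau_patience=8, seed=seed),
            roi_size=(24, 24, 24),
            sdnet=SDNetConfig(channels=(4, 8, 16)),
            sd_train=SDTrainConfig(epochs=24, initial_lr=1e-3,
                                   plateau_patience=8, seed=seed),
            preset=preset,
            seed=seed,
            out_dir=out_dir,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "phantom" in raw:
            kw["phantom"] = PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.pop("phantom").items()})
        for key, typ in (("seg_model", SegModelConfig),
                         ("seg_train", SegTrainConfig),
                         ("sdnet", SDNetConfig),
                         ("sd_train", SDTrainConfig)):
            if key in raw:
                kw[key] = typ(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop(key).items()})
        for k, v in raw.items():
            kw[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    run_dir: Path
    seg_report: pd.DataFrame
    cls_report: ClassificationReport
    seg_history: dict
    sd_history: dict
    test_labels: np.ndarray
    test_probs: np.ndarray


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(6)
    names = ["phantom_seg", "phantom_cls", "fsnet_init", "fsnet_train",
             "sdnet_init", "sdnet_train"]
    return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def _counts_to_ratios(counts: tuple[int, int, int]) -> tuple[float, float, float]:
    total = sum(counts)
    return tuple(c / total for c in counts)


def save_checkpoint(model: FSNet | SDNet, path: Path, sidecar: dict) -> None:
    np.savez(path, **model.state_dict())
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_fsnet_checkpoint(path: str | Path) -> FSNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    cfg = sidecar["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    model = build_fsnet(SegModelConfig(**cfg))
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model


def load_sdnet_checkpoint(path: str | Path) -> SDNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    cfg = sidecar["config"]
    cfg["channels"] = tuple(cfg["channels"])
    model = build_sdnet(SDNetConfig(**cfg))
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model


def _slices_from_manifest(manifest: pd.DataFrame, split: str) -> SliceBatch:
    if (manifest["split"] == split).sum() == 0:
        raise ValueError(f"manifest contains no subjects in the {split!r} "
                         "split; enlarge the cohort or adjust the ratios")
    imgs, msks, prov = [], [], []
    for _, row in manifest[manifest["split"] == split].iterrows():
        vol = load_volume(row["volume_path"])
        msk = load_mask(row["mask_path"])
        for z in range(vol.data.shape[0]):
            imgs.append(vol.data[z])
            msks.append(msk.data[z].astype(np.float32))
            prov.append((row["subject_id"], z))
    return SliceBatch(np.stack(imgs), np.stack(msks), prov)


def _train_segmentation(config: PipelineConfig, seeds: dict,
                        run_dir: Path) -> tuple[FSNet, dict, pd.DataFrame]:
    spec = dataclasses.replace(config.phantom, seed=seeds["phantom_seg"])
    n = sum(config.seg_counts)
    manifest = generate_cohort(spec, n // 2, n - n // 2, run_dir / "seg_cohort",
                               split_ratios=_counts_to_ratios(config.seg_counts))
    train = _slices_from_manifest(manifest, "train")
    val = _slices_from_manifest(manifest, "val")
    model = build_fsnet(config.seg_model, seed=seeds["fsnet_init"])
    tcfg = dataclasses.replace(config.seg_train, seed=seeds["fsnet_train"])
    model, history = train_fsnet(model, train, val, tcfg)

    pairs = []
    for _, row in manifest[manifest["split"] == "test"].iterrows():
        vol = load_volume(row["volume_path"])
        gt = load_mask(row["mask_path"])
        _, pred = predict_slices(model, vol)
        pairs.append((gt, pred))
    seg_report = segmentation_report(pairs)
    return model, history, seg_report


def _extract_cohort_rois(config: PipelineConfig, seeds: dict, run_dir: Path,
                         seg_model: FSNet) -> dict[str, list[ROISample]]:
    spec = dataclasses.replace(config.phantom, seed=seeds["phantom_cls"])
    n = sum(config.cls_counts)
    manifest = generate_cohort(spec, n // 2, n - n // 2, run_dir / "cls_cohort",
                               split_ratios=_counts_to_ratios(config.cls_counts))
    rois: dict[str, list[ROISample]] = {"train": [], "val": [], "test": []}
    for _, row in manifest.iterrows():
        vol = load_volume(row["volume_path"])
        _, pred = predict_slices(seg_model, vol)
        roi = extract_roi(vol, pred, config.roi_size,
                          binarize_mask=config.binarize_mask,
                          label=int(row["sex"]),
                          keep_largest_component=config.keep_largest_component)
        rois[row["split"]].append(roi)
    return rois


def _train_classifier(config: PipelineConfig, seeds: dict,
                      rois: dict[str, list[ROISample]]
                      ) -> tuple[SDNet, dict, ClassificationReport,
                                 np.ndarray, np.ndarray]:
    model = build_sdnet(config.sdnet, seed=seeds["sdnet_init"])
    tcfg = dataclasses.replace(config.sd_train, seed=seeds["sdnet_train"])
    model, history = train_sdnet(model, rois["train"], rois["val"], tcfg,
                                 channels=config.channels)
    labels = np.array([r.label for r in rois["test"]])
    probs = np.array([predict_sex(model, r, config.channels)
                      for r in rois["test"]])
    report = evaluate_classifier(labels, probs)
    return model, history, report, labels, probs


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage and write models, predictions and reports."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"config_hash": config.config_hash(), "seeds": seeds,
                      "stages": {}, "artifacts": {}}
    with open(run_dir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)

    stage = "segmentation"
    try:
        t0 = time.perf_counter()
        seg_model, seg_history, seg_report = _train_segmentation(
            config, seeds, run_dir)
        save_checkpoint(seg_model, run_dir / "fsnet.npz",
                        {"config": dataclasses.asdict(config.seg_model),
                         "history": seg_history})
        seg_report.to_csv(run_dir / "seg_report.csv", index=False)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
        log.info("segmentation stage done: mean F1 %.3f",
                 seg_report["f1"].mean())

        stage = "roi_extraction"
        t0 = time.perf_counter()
        rois = _extract_cohort_rois(config, seeds, run_dir, seg_model)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}

        stage = "classification"
        t0 = time.perf_counter()
        sd_model, sd_history, cls_report, labels, probs = _train_classifier(
            config, seeds, rois)
        save_checkpoint(sd_model, run_dir / "sdnet.npz",
                        {"config": dataclasses.asdict(config.sdnet),
                         "history": sd_history})
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    pd.DataFrame({"label": labels, "prob": probs}).to_csv(
        run_dir / "predictions.csv", index=False)
    classification_table({config.preset: cls_report}).to_csv(
        run_dir / "classification_report.csv", index=False)
    manifest["artifacts"] = {
        "fsnet": "fsnet.npz", "sdnet": "sdnet.npz",
        "seg_report": "seg_report.csv",
        "classification_report": "classification_report.csv",
        "predictions": "predictions.csv",
        "seg_cohort": "seg_cohort/manifest.csv",
        "cls_cohort": "cls_cohort/manifest.csv",
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("classification: AUC %.3f ACC %.3f", cls_report.auc,
             cls_report.acc)
    return RunResult(run_dir, seg_report, cls_report, seg_history, sd_history,
                     labels, probs)


@dataclass
class AblationResult:
    reports: dict[str, ClassificationReport]
    seg_report: pd.DataFrame
    run_dir: Path


def run_ablation(config: PipelineConfig,
                 presets: tuple[str, ...] = tuple(ABLATION_PRESETS),
                 ) -> AblationResult:
    """Retrain the classifier under each preset on a shared stage-1 output."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    seeds = _stage_seeds(config.seed)
    seg_model, seg_history, seg_report = _train_segmentation(config, seeds,
                                                             run_dir)
    rois = _extract_cohort_rois(config, seeds, run_dir, seg_model)
    reports = {}
    for preset in presets:
        pcfg = dataclasses.replace(config, preset=preset,
                                   out_dir=str(run_dir / preset))
        _, _, report, _, _ = _train_classifier(pcfg, seeds, rois)
        reports[preset] = report
        log.info("preset %s: AUC %.3f ACC %.3f", preset, report.auc,
                 report.acc)
    classification_table(reports).to_csv(run_dir / "ablation_report.csv",
                                         index=False)
    seg_report.to_csv(run_dir / "seg_report.csv", index=False)
    return AblationResult(reports, seg_report, run_dir)


def report(run_dir: str | Path) -> pd.DataFrame:
    """Consolidate a completed run into one metrics table."""
    run_dir = Path(run_dir)
    for name in ("classification_report.csv", "ablation_report.csv"):
        path = run_dir / name
        if path.exists():
            df = pd.read_csv(path)
            break
    else:
        raise FileNotFoundError(
            f"no classification outputs in {run_dir}: the classification "
            "stage did not complete")
    seg_path = run_dir / "seg_report.csv"
    if seg_path.exists():
        seg = pd.read_csv(seg_path)
        for col in ("ji", "f1", "pr", "rc"):
            df[f"seg_{col.upper()}_mean"] = seg[col].mean()
    df.to_csv(run_dir / "report.csv", index=False)
    return df


def _setup_logging(run_dir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler())
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == (run_dir / "run.log")
               for h in log.handlers):
        fh = logging.FileHandler(run_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)
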