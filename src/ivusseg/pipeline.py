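"""End-to-end orchestration: simulate → split → train → predict → assess → evaluate.

Each stage is an idempotent function writing its outputs (plus a run
manifest with the config hash, the seed and package versions) under the run
directory, so a pipeline can be resumed or re-run stage by stage with
identical results.  A single global seed fans out to per-stage seeds
derived from a hash of the stage name, making every stage independently
reproducible.
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

import ivusseg
from ivusseg.clinical import classify_narrowed, clinical_report, lumen_area
from ivusseg.masks import LabelMask, read_mask, write_mask, write_palette_json
from ivusseg.metrics import (
    aggregate,
    image_level_classification,
    lumen_area_correlation,
    plot_area_agreement,
    write_report,
)
from ivusseg.phantom import SimConfig, generate_dataset
from ivusseg.unet import (
    NetConfig,
    TrainConfig,
    UNet,
    frames_from_sequences,
    make_split,
    predict,
    train,
)

log = logging.getLogger("ivusseg.pipeline")


class MissingArtifactError(FileNotFoundError):
    """A stage's upstream output is absent."""


@dataclass
class RunConfig:
    """Full pipeline configuration with the clinical thresholds made explicit."""

    sim: SimConfig = field(default_factory=SimConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    test_n_patients: int = 2
    aggregation_mode: str = "pooled"
    narrowed_mm2: float = 4.0
    severe_quadrants: int = 2
    strut_tol_px: float = 5.0
    out_dir: str = "runs/default"
    seed: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.net.validate()
        self.train.validate()
        if self.narrowed_mm2 <= 0 or self.strut_tol_px <= 0:
            raise ValueError("thresholds must be positive")
        if self.test_n_patients < 1:
            raise ValueError("test_n_patients must be >= 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            if "sim" in d:
                d["sim"] = SimConfig(**d["sim"])
            if "net" in d:
                d["net"] = NetConfig(**d["net"])
            if "train" in d:
                tr = dict(d["train"])
                d["train"] = TrainConfig(**tr)
            return cls(**d)
        except TypeError as exc:
            raise ValueError(f"config schema violation: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: hash of stage name mixed with the global seed (< 2^31)."""
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _write_run_manifest(out: Path, config: RunConfig, stage: str) -> None:
    doc = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"ivusseg": ivusseg.__version__, "numpy": np.__version__},
        "config": config.to_dict(),
    }
    (out / f"run_{stage}.json").write_text(json.dumps(doc, indent=2, default=str) + "\n")


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"{what} not found: {path} (run the producing stage first)")
    return path


def cmd_simulate(config: RunConfig) -> Path:
    """Generate the synthetic dataset under <out>/dataset."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.sim, rng_seed=derive_seed(config.seed, "simulate"))
    data_dir = out / "dataset"
    seqs, manifest = generate_dataset(sim, data_dir)
    write_palette_json(data_dir / "palette.json")
    n_frames = sum(len(s) for s in seqs)
    calc = sum(gt.has_calcification for s in seqs for _, _, gt in s.frames)
    stent = sum(gt.has_stent for s in seqs for _, _, gt in s.frames)
    log.info(
        "simulate: %d patients, %d frames (%.1f%% calcified, %.1f%% stented) -> %s",
        len(seqs), n_frames, 100 * calc / n_frames, 100 * stent / n_frames, data_dir,
    )
    _write_run_manifest(out, config, "simulate")
    return data_dir


def _load_dataset(config: RunConfig):
    """Re-generate the dataset in memory from the simulate-stage seed.

    Regeneration is bit-identical to what ``cmd_simulate`` wrote (same
    config and derived seed), so downstream stages need no image parsing.
    """
    from ivusseg.phantom import generate_sequences

    sim = dataclasses.replace(config.sim, rng_seed=derive_seed(config.seed, "simulate"))
    return generate_sequences(sim)


def _split(config: RunConfig, seqs):
    rng = np.random.default_rng(derive_seed(config.seed, "split"))
    return make_split(seqs, config.test_n_patients, rng, config.train.validation_fraction)


def cmd_split(config: RunConfig) -> Path:
    """Write the patient-level split plan as JSON."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs = _load_dataset(config)
    plan = _split(config, seqs)
    doc = {
        "train_patients": plan.train_patients,
        "test_patients": plan.test_patients,
        "validation_frames": [list(v) for v in plan.validation_frames],
    }
    path = out / "split.json"
    path.write_text(json.dumps(doc, indent=2) + "\n")
    log.info("split: %d train / %d test patients, %d validation frames",
             len(plan.train_patients), len(plan.test_patients), len(plan.validation_frames))
    _write_run_manifest(out, config, "split")
    return path


def cmd_train(config: RunConfig) -> Path:
    """Train the U-Net on the training patients; checkpoint best val loss."""
    config.validate()
    out = Path(config.out_dir)
    _require(out / "split.json", "split plan")
    seqs = _load_dataset(config)
    plan = _split(config, seqs)
    tr = frames_from_sequences(seqs, plan.train_patients, exclude_frames=plan.validation_frames)
    va = frames_from_sequences(seqs, plan.train_patients, only_frames=plan.validation_frames)
    model = UNet(config.net, rng_seed=derive_seed(config.seed, "init"))
    tc = dataclasses.replace(config.train, rng_seed=derive_seed(config.seed, "train"))
    hist = train(model, tr, tc, va)
    ckpt = out / "checkpoint.npz"
    model.save(ckpt)
    hist.write_csv(out / "history.csv")
    log.info("train: %d epochs, best val loss %.4f at epoch %d",
             len(hist.epochs), min(hist.val_loss), hist.best_epoch)
    _write_run_manifest(out, config, "train")
    return ckpt


def cmd_predict(config: RunConfig, checkpoint: str | Path | None = None) -> Path:
    """Segment the held-out test patients' frames; write predicted masks."""
    config.validate()
    out = Path(config.out_dir)
    ckpt = _require(Path(checkpoint) if checkpoint else out / "checkpoint.npz", "model checkpoint")
    model = UNet.load(ckpt)
    seqs = _load_dataset(config)
    plan = _split(config, seqs)
    pred_dir = out / "predictions"
    pred_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in seqs:
        if seq.patient_id not in plan.test_patients:
            continue
        for k, (frame, _mask, _gt) in enumerate(seq.frames):
            pm, _probs = predict(model, frame.image, pixel_spacing=config.sim.pixel_spacing)
            path = pred_dir / f"{seq.patient_id}_pred_{k:04d}.png"
            write_mask(pm, path)
            rows.append({"patient_id": seq.patient_id, "frame_index": k, "pred_path": path.name})
    pd.DataFrame(rows).to_csv(pred_dir / "predictions.csv", index=False)
    log.info("predict: %d test frames -> %s", len(rows), pred_dir)
    _write_run_manifest(out, config, "predict")
    return pred_dir


def _test_pairs(config: RunConfig, pred_dir: Path):
    """(pred, truth) mask pairs for the test patients, reading predictions back."""
    seqs = _load_dataset(config)
    plan = _split(config, seqs)
    idx = pd.read_csv(_require(pred_dir / "predictions.csv", "prediction index"))
    pairs, ids = [], []
    by_id = {s.patient_id: s for s in seqs}
    for row in idx.itertuples():
        seq = by_id[row.patient_id]
        _frame, truth, _gt = seq.frames[row.frame_index]
        pred = read_mask(pred_dir / row.pred_path, pixel_spacing=config.sim.pixel_spacing)
        pairs.append((pred, truth))
        ids.append(f"{row.patient_id}/{row.frame_index:04d}")
    return pairs, ids


def cmd_assess(config: RunConfig, predictions: str | Path | None = None) -> Path:
    """Per-frame clinical report (lumen area, flags, struts) on test frames."""
    config.validate()
    out = Path(config.out_dir)
    pred_dir = Path(predictions) if predictions else out / "predictions"
    pairs, ids = _test_pairs(config, pred_dir)
    path = out / "clinical_report.csv"
    clinical_report(
        ids,
        [t for _, t in pairs],
        [p for p, _ in pairs],
        strut_tol_px=config.strut_tol_px,
        path=path,
    )
    log.info("assess: %d frames -> %s", len(ids), path)
    _write_run_manifest(out, config, "assess")
    return path


def cmd_evaluate(config: RunConfig, predictions: str | Path | None = None) -> Path:
    """Segmentation + image-level metrics on the held-out test patients."""
    config.validate()
    out = Path(config.out_dir)
    pred_dir = Path(predictions) if predictions else out / "predictions"
    pairs, _ids = _test_pairs(config, pred_dir)
    report = aggregate(pairs, config.aggregation_mode)
    write_report(report, out / "segmentation_metrics.csv")

    def narrowed_rule(mask: LabelMask) -> bool:
        return classify_narrowed(lumen_area(mask), config.narrowed_mm2)

    def severe_rule(mask: LabelMask) -> bool:
        from ivusseg.clinical import calcification_arc

        _, q, _ = calcification_arc(mask)
        return q > config.severe_quadrants

    nar = image_level_classification(pairs, narrowed_rule)
    sev = image_level_classification(pairs, severe_rule)
    truth_areas = [lumen_area(t) for _, t in pairs]
    pred_areas = [lumen_area(p) for p, _ in pairs]
    try:
        corr = lumen_area_correlation(truth_areas, pred_areas)
        corr_doc = {"rho": corr.rho, "r_squared": corr.r_squared, "p_value": corr.p_value}
        plot_area_agreement(truth_areas, pred_areas, out / "lumen_area_scatter.png", corr)
    except ValueError as exc:  # degenerate predictions (e.g. constant areas)
        log.warning("lumen-area correlation undefined: %s", exc)
        corr_doc = {"rho": None, "r_squared": None, "p_value": None}
    doc = {
        "aggregation_mode": report.aggregation_mode,
        "iou_per_class": report.iou_per_class,
        "dice_per_class": report.dice_per_class,
        "mean_iou": report.mean_iou,
        "mean_dice": report.mean_dice,
        "narrowed_lumen": dict(zip(("accuracy", "recall", "precision"), nar)),
        "severe_calcification": dict(zip(("accuracy", "recall", "precision"), sev)),
        "lumen_area_correlation": corr_doc,
        "n_test_frames": len(pairs),
    }
    path = out / "metrics.json"
    path.write_text(json.dumps(doc, indent=2) + "\n")
    log.info("evaluate: mean IoU %.3f (mode %s), narrowed acc %.3f, rho %s",
             report.mean_iou, report.aggregation_mode, nar[0], corr_doc["rho"])
    _write_run_manifest(out, config, "evaluate")
    return path


def run_all(config: RunConfig) -> Path:
    """Run every stage in order; returns the metrics JSON path."""
    cmd_simulate(config)
    cmd_split(config)
    cmd_train(config)
    cmd_predict(config)
    cmd_assess(config)
    return cmd_evaluate(config)
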