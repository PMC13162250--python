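"""One-command orchestration of the full study on synthetic data.

``run_experiment`` chains every stage — power-series onset detection,
dataset synthesis, CNN training, evaluation at full and reduced power,
Grad-CAM chromaticity cluster analysis, and dark-field morphology — and
returns a single JSON-serialisable report.  Every stage draws its seed from
the master seed through a fixed SeedSequence spawn order, so a report is
reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluate, morphology, saliency_chroma
from .classifier import (ArchitectureSpec, TrainConfig, build_network, predict,
                         train, GRADCAM_LAYER)
from .constants import CLASSES
from .preprocess import resize_image
from .spectra_physics import ClampingModel, detect_onset, generate_power_series
from .synth_scene import (DatasetConfig, SlideConfig, build_image_dataset,
                          render_darkfield_slide)

__all__ = ["ExperimentConfig", "run_experiment", "save_report"]


@dataclass
class ExperimentConfig:
    """Master configuration; ``profile`` selects full or desk-scale runs."""

    seed: int = 0
    profile: str = "small"             # "full" | "small"
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    epochs: int | None = None          # None: 60 full / 30 small
    run_gradcam: bool = True
    run_morphology: bool = True
    run_onset: bool = True
    morphology_particles: int = 120
    onset_powers: tuple[float, float, float] = (0.20, 1.00, 0.05)
    out_dir: str | None = None

    def architecture(self) -> ArchitectureSpec:
        if self.profile == "small":
            return ArchitectureSpec.small()
        if self.profile == "full":
            return ArchitectureSpec()
        if self.profile == "tiny":   # smoke-test scale
            return ArchitectureSpec(input_side=32, block_filters=(4, 8, 16, 32))
        raise ValueError(f"unknown profile {self.profile!r}")


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _evaluate_split(model, manifest, split: str) -> dict:
    rows = manifest.select(split)
    x = np.stack([manifest.images[i] for i in rows["image_id"]])
    y = [CLASSES.index(lbl) for lbl in rows["label"]]
    probs = predict(model, x)
    cm = evaluate.confusion_matrix(probs.predicted_index, y)
    metrics = evaluate.classification_metrics(cm, probs.probabilities,
                                              probs.predicted_index)
    return {"confusion_counts": cm.counts.tolist(),
            "confusion_percent": np.round(cm.percentages, 2).tolist(),
            **metrics.to_dict(),
            "_predicted": probs.predicted_index,
            "_true": np.asarray(y), "_x": x}


def _chroma_analysis(model, test_eval: dict, patch_side: int | None = None) -> dict:
    """Grad-CAM patches and chromaticity clusters on correctly classified
    test images.

    ``patch_side`` defaults to input/8 — 64 px at the full 512 profile, and
    the same image fraction for scaled-down profiles."""
    points, labels = [], []
    band_mass: dict[str, list[float]] = {c: [] for c in CLASSES}
    correct = np.flatnonzero(test_eval["_predicted"] == test_eval["_true"])
    for i in correct:
        img = test_eval["_x"][i]
        cls = CLASSES[int(test_eval["_true"][i])]
        heat = saliency_chroma.gradcam(model, img, layer=GRADCAM_LAYER)
        # fraction of heatmap mass inside the filament band (central quarter
        # of rows: the stripe sits at the segment centre)
        side = heat.shape[0]
        band = slice(side // 2 - side // 8, side // 2 + side // 8)
        total = heat.sum()
        if total > 0:
            band_mass[cls].append(float(heat[band].sum() / total))
        ps = patch_side if patch_side is not None else max(8, side // 8)
        for patch, _ in saliency_chroma.extract_patches(img, heat, k=3,
                                                        patch_side=ps):
            rg = saliency_chroma.patch_chromaticity(patch, n_pixels=30)
            points.append(rg)
            labels.extend([cls] * len(rg))
    if not points:
        return {"skipped": "no correctly classified test images"}
    pts = np.concatenate(points, axis=0)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return {"skipped": "fewer than two classes correctly classified"}
    sil = saliency_chroma.silhouette_stats(pts, labels)
    maha = saliency_chroma.mahalanobis_distances(pts, labels)
    off = maha.values[np.triu_indices_from(maha.values, k=1)]
    pairs = [(maha.index[i], maha.columns[j])
             for i, j in zip(*np.triu_indices_from(maha.values, k=1))]
    closest = pairs[int(np.argmin(off))]
    return {"silhouette": sil.to_dict(),
            "mahalanobis": maha.round(4).to_dict(),
            "closest_pair": list(closest),
            "n_points": int(len(pts)),
            "heatmap_band_mass": {c: (float(np.mean(v)) if v else None)
                                  for c, v in band_mass.items()}}


def _morphology_analysis(n_particles: int, seeds: list[int]) -> dict:
    out = {}
    slide_cfg = SlideConfig()
    for cls, seed in zip(("chalk", "pollen", "salt"), seeds):
        img, truth = render_darkfield_slide(cls, n_particles, slide_cfg, seed=seed)
        table = morphology.segment_particles(img, slide_cfg.pixel_scale_um)
        out[cls] = {
            "n_true": int(len(truth)), "n_detected": int(len(table)),
            "mean_d_eq_um": float(table["d_eq_um"].mean()),
            "true_mean_d_eq_um": float(truth["d_eq_um"].mean()),
            "mean_circularity": float(table["circularity"].mean()),
            "mean_eccentricity": float(table["eccentricity"].mean()),
        }
    stats = morphology.sampler_stats(342, 10.0, 9.0)
    out["air_sampler"] = {"volume_m3": stats.volume_m3,
                          "concentration_m3": stats.concentration_m3}
    return out


def run_experiment(config: ExperimentConfig | None = None) -> dict:
    """Execute the full synthetic study; returns the experiment report."""
    config = config or ExperimentConfig()
    seeds = _stage_seeds(config.seed)
    arch = config.architecture()
    report: dict = {"config": {"seed": config.seed, "profile": config.profile,
                               "input_side": arch.input_side,
                               "block_filters": list(arch.block_filters)}}

    if config.run_onset:
        lo, hi, step = config.onset_powers
        powers = np.round(np.arange(lo, hi + step / 2, step), 10)
        series = generate_power_series(powers, ClampingModel())
        onset = detect_onset(series)
        report["onset"] = {"detected_power_fraction": onset,
                           "detected_percent": None if onset is None else 100.0 * onset,
                           "n_powers": int(len(powers))}

    side = arch.input_side

    def transform(segment: np.ndarray) -> np.ndarray:
        return resize_image(segment, side) / np.float32(255.0)

    manifest = build_image_dataset(config.dataset, seed=seeds[0],
                                   transform=transform)
    report["dataset"] = {split: {cls: int(((manifest.records["split"] == split)
                                           & (manifest.records["label"] == cls)).sum())
                                 for cls in CLASSES}
                         for split in ("train", "val", "test", "robustness")}

    model = build_network(arch, seed=seeds[1])
    epochs = config.epochs if config.epochs is not None else (
        30 if config.profile == "small" else 60)
    cfg = TrainConfig(epochs=epochs, seed=seeds[2])
    history = train(model, manifest, cfg)
    report["training"] = {"iterations": len(history["train_loss"]),
                          "val_loss": history["val_loss"],
                          "val_accuracy": history["val_accuracy"],
                          "best_val_accuracy": history["best_val_accuracy"],
                          "lr_per_epoch": history["lr_per_epoch"]}

    test_eval = _evaluate_split(model, manifest, "test")
    robust_eval = _evaluate_split(model, manifest, "robustness")
    report["test"] = {k: v for k, v in test_eval.items() if not k.startswith("_")}
    report["robustness"] = {k: v for k, v in robust_eval.items()
                            if not k.startswith("_")}

    if config.run_gradcam:
        report["chromaticity"] = _chroma_analysis(model, test_eval)

    if config.run_morphology:
        report["morphology"] = _morphology_analysis(config.morphology_particles,
                                                    seeds[3:6])

    report = _jsonable(report)
    if config.out_dir is not None:
        save_report(report, Path(config.out_dir))
        model.save(Path(config.out_dir) / "model",
                   meta=_jsonable(dataclasses.asdict(arch)))
    return report


def save_report(report: dict, out_dir: Path) -> Path:
    import pandas as pd
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2))
    for split in ("test", "robustness"):
        if split in report:
            pd.DataFrame(report[split]["confusion_counts"], index=list(CLASSES),
                         columns=list(CLASSES)).to_csv(
                out_dir / f"confusion_{split}.csv")
            pd.DataFrame({k: v for k, v in report[split].items()
                          if k.startswith("per_class")}).to_csv(
                out_dir / f"metrics_{split}.csv")
    return path
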