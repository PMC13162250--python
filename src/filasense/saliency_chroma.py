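"""Grad-CAM saliency and chromaticity cluster analysis.

Grad-CAM weights a convolutional layer's activation channels by the
spatially averaged gradient of the target-class pre-softmax score, sums,
rectifies, upsamples, and max-normalises — highlighting the image regions
that drove the prediction.  The colour analysis then takes the three most
intense 64x64 heatmap patches per image, the 30 brightest pixels per patch
(brightness = R+G+B), and maps each to brightness-normalised chromaticity
(r, g) = (R, G)/(R+G+B).  Cluster separation of the per-class chromaticity
clouds is quantified with silhouette statistics and pooled-covariance
Mahalanobis distances between class centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Sequential
from .preprocess import resize_image

__all__ = ["gradcam", "extract_patches", "patch_chromaticity",
           "silhouette_stats", "mahalanobis_distances", "SilhouetteReport"]

log = logging.getLogger(__name__)


def gradcam(model: Sequential, image: np.ndarray, target_class: int | None = None,
            layer: str = "relu3_2") -> np.ndarray:
    """Grad-CAM heatmap in [0, 1] at the input's spatial size.

    ``layer`` must name a ReLU output (default: the second ReLU of the third
    convolutional block).  ``target_class`` defaults to the predicted class.
    """
    if "relu" not in layer:
        raise ValueError(f"{layer!r} is not a rectified-linear activation")
    if layer not in model.layer_names():
        raise ValueError(f"model has no layer {layer!r}")
    x = np.asarray(image, dtype=np.float32)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    if x.ndim == 3:
        x = x[None]
    logits, act = model.forward(x, mode="grad", tap=layer)
    if target_class is None:
        target_class = int(logits[0].argmax())
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.backward(dlogits, stop_at=layer)   # d score / d activation
    weights = grad.mean(axis=(1, 2))                # (1, C) spatial average
    cam = np.maximum((act * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    cam = resize_image(cam, x.shape[1], anti_alias=False)
    if cam.max() > 0:
        cam = cam / cam.max()
    return cam.astype(np.float32)


def extract_patches(image: np.ndarray, heatmap: np.ndarray, k: int = 3,
                    patch_side: int = 64) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Greedy selection of the ``k`` most intense non-overlapping patches.

    Repeatedly takes the heatmap argmax (row-major first on ties), centres a
    ``patch_side`` window there (re-centred inside the frame at borders), and
    suppresses the covered area.  Candidates whose window would overlap an
    already selected one are skipped.  Returns [(patch, (row0, col0)), ...];
    fewer than ``k`` if the frame cannot fit more disjoint windows.
    """
    img = np.asarray(image)
    if heatmap.shape != img.shape[:2]:
        raise ValueError("heatmap and image sizes differ")
    h, w = heatmap.shape
    half = patch_side // 2
    heat = heatmap.astype(float).copy()
    out: list[tuple[np.ndarray, tuple[int, int]]] = []
    taken: list[tuple[int, int]] = []
    while len(out) < k and np.isfinite(heat).any() and heat.max() > -np.inf:
        flat = int(np.argmax(heat))
        r, c = divmod(flat, w)
        if heat[r, c] == -np.inf:
            break
        r0 = int(np.clip(r - half, 0, h - patch_side))
        c0 = int(np.clip(c - half, 0, w - patch_side))
        overlap = any(abs(r0 - tr) < patch_side and abs(c0 - tc) < patch_side
                      for tr, tc in taken)
        if overlap:
            heat[r, c] = -np.inf
            continue
        out.append((img[r0:r0 + patch_side, c0:c0 + patch_side].copy(), (r0, c0)))
        taken.append((r0, c0))
        heat[r0:r0 + patch_side, c0:c0 + patch_side] = -np.inf
    if len(out) < k:
        log.info("only %d of %d disjoint patches fit", len(out), k)
    return out


def patch_chromaticity(patch: np.ndarray, n_pixels: int = 30) -> np.ndarray:
    """(r, g) chromaticity of the ``n_pixels`` brightest patch pixels.

    Brightness is R+G+B; zero-brightness pixels are excluded (an all-black
    patch yields an empty array, logged).  Ties resolve in row-major order.
    """
    p = np.asarray(patch, dtype=float).reshape(-1, patch.shape[-1])
    s = p.sum(axis=1)
    valid = s > 0
    if not valid.any():
        log.info("all-black patch: no chromaticity points")
        return np.empty((0, 2))
    order = np.argsort(-s, kind="stable")
    order = order[valid[order]][:n_pixels]
    sel = p[order]
    tot = sel.sum(axis=1, keepdims=True)
    rg = sel[:, :2] / tot
    return rg


@dataclass
class SilhouetteReport:
    per_class: pd.DataFrame   # mean, median, iqr, frac_positive, n per class
    weighted_mean: float      # = sum n_i mean_i / sum n_i (the global mean)
    ci95: tuple[float, float]
    n_total: int

    def to_dict(self) -> dict:
        return {"per_class": self.per_class.to_dict(orient="index"),
                "weighted_mean": self.weighted_mean,
                "ci95": list(self.ci95), "n_total": self.n_total}


def silhouette_stats(points: np.ndarray, labels) -> SilhouetteReport:
    """Per-point silhouettes in (r, g) space and their per-class summaries.

    Silhouette s(i) = (b - a)/max(a, b) with Euclidean distances; the
    weighted mean over classes equals the global mean, and its 95% CI is the
    normal approximation ``mean +- 1.96 * sd / sqrt(n)`` with the pooled
    (global) standard deviation.
    """
    from sklearn.metrics import silhouette_samples

    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two classes")
    sil = silhouette_samples(pts, labels)
    rows = {}
    for cls in uniq:
        s = sil[labels == cls]
        q1, q3 = np.percentile(s, [25, 75])
        rows[str(cls)] = {"mean": float(s.mean()), "median": float(np.median(s)),
                          "iqr": float(q3 - q1),
                          "frac_positive": float((s > 0).mean()),
                          "n": int(len(s))}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    wmean = float(sil.mean())
    se = float(sil.std(ddof=1) / np.sqrt(len(sil)))
    return SilhouetteReport(per_class, wmean,
                            (wmean - 1.96 * se, wmean + 1.96 * se), len(sil))


def mahalanobis_distances(points: np.ndarray, labels) -> pd.DataFrame:
    """Pairwise Mahalanobis distances between class centroids.

    D(i, j) = sqrt((mu_i - mu_j)^T S^-1 (mu_i - mu_j)) with S the pooled
    within-class covariance; ridge-regularised if near-singular, rejected if
    singular after regularisation.
    """
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = [str(u) for u in np.unique(labels)]
    mus = {}
    k = len(uniq)
    n = len(pts)
    s = np.zeros((pts.shape[1], pts.shape[1]))
    for cls in uniq:
        sel = pts[labels.astype(str) == cls]
        mu = sel.mean(axis=0)
        mus[cls] = mu
        d = sel - mu
        s += d.T @ d
    dof = max(n - k, 1)
    s /= dof
    if np.linalg.cond(s) > 1e10:
        s = s + 1e-8 * np.trace(s) / s.shape[0] * np.eye(s.shape[0])
    try:
        s_inv = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("pooled covariance singular") from exc
    mat = np.zeros((k, k))
    for i, a in enumerate(uniq):
        for j, b in enumerate(uniq):
            d = mus[a] - mus[b]
            mat[i, j] = float(np.sqrt(max(0.0, d @ s_inv @ d)))
    return pd.DataFrame(mat, index=uniq, columns=uniq)
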