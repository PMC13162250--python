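"""Synthetic inputs for the filament particle-sensing study.

Everything the downstream pipeline consumes is generated here:

* parametric emission spectra for the four particle classes — calcium-line
  dominated for chalk, a broad green band for pollen, the sodium D doublet
  for salt, and the filament-only continuum for blank frames;
* camera-rendered 1920x1200 RGB frames: a horizontal filament stripe plus
  Poisson-many Gaussian emission blobs whose colours come from rendering a
  per-event spectrum draw through a parametric RGB camera model;
* curated datasets with the study's per-class counts and splits;
* dark-field slide images of deposited particles with class-specific size
  and shape distributions, with per-particle ground truth.

All randomness flows through explicit seeds; identical seeds give identical
bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CLASSES
from .spectra_physics import ClampingModel, EmissionSpectrum, default_wavelength_grid

__all__ = [
    "ClassSpectrumParams", "CameraModel", "SceneConfig", "LabeledImage",
    "EmissionEvent", "DatasetConfig", "DatasetManifest", "SlideConfig",
    "DEFAULT_SPECTRA", "make_emission_spectrum", "spectrum_to_rgb",
    "render_frame", "build_image_dataset", "render_darkfield_slide",
]

log = logging.getLogger(__name__)

_FWHM = 2.3548200450309493  # fwhm = _FWHM * sigma


def _gauss(x: np.ndarray, center: float, fwhm: float, amp: float) -> np.ndarray:
    sig = fwhm / _FWHM
    return amp * np.exp(-0.5 * ((x - center) / sig) ** 2)


# --------------------------------------------------------------------- spectra
@dataclass(frozen=True)
class ClassSpectrumParams:
    """Parametric emission model for one particle class.

    ``lines`` are (center_nm, fwhm_nm, amplitude) Gaussian emission lines;
    ``continuum`` an optional broad Gaussian band; amplitudes are peak
    heights in arbitrary units.
    """

    class_label: str
    lines: tuple[tuple[float, float, float], ...] = ()
    continuum: tuple[float, float, float] | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        for c, w, a in self.lines + ((self.continuum,) if self.continuum else ()):
            if w <= 0 or a < 0:
                raise ValueError("line fwhm must be > 0 and amplitudes >= 0")


#: Default class signatures.  Line positions follow the elemental physics
#: (Ca II H/K and Ca I resonance lines plus CaO orange bands for chalk, the
#: Na D doublet for salt, a broad green organic-fluorophore band for pollen);
#: amplitudes are artifact parameters chosen so the rendered chromaticities
#: fall in distinct pink / green / orange regions with blank near neutral.
DEFAULT_SPECTRA: dict[str, ClassSpectrumParams] = {
    "blank": ClassSpectrumParams("blank", continuum=(440.0, 110.0, 0.5)),
    "chalk": ClassSpectrumParams("chalk", lines=(
        (393.4, 2.0, 0.75), (396.9, 2.0, 0.53), (422.7, 2.5, 1.5),
        (554.0, 6.0, 0.8), (603.0, 8.0, 0.48), (616.0, 10.0, 0.8),
        (649.0, 8.0, 0.4))),
    "pollen": ClassSpectrumParams("pollen", continuum=(525.0, 60.0, 1.0)),
    "salt": ClassSpectrumParams("salt", lines=(
        (589.0, 3.0, 1.0), (589.6, 3.0, 0.5), (568.3, 5.0, 0.12))),
}


def make_emission_spectrum(class_label: str, power_fraction: float,
                           params: ClassSpectrumParams | None = None,
                           seed: int | None = None,
                           wavelength_nm: np.ndarray | None = None,
                           clamping: ClampingModel | None = None) -> EmissionSpectrum:
    """Class emission spectrum at a laser power fraction.

    Lines and continuum are summed, scaled by the clamped intensity law
    (normalised so full power has scale 1), and additive Gaussian noise is
    clipped at zero.  Blank returns the filament-only continuum, which the
    downstream reference subtraction removes.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    if not 0.0 < power_fraction <= 1.0:
        raise ValueError("power fraction must lie in (0, 1]")
    params = params or DEFAULT_SPECTRA[class_label]
    if params.class_label != class_label:
        raise ValueError("params do not match the requested class")
    wl = default_wavelength_grid() if wavelength_nm is None else np.asarray(wavelength_nm, float)
    clamping = clamping or ClampingModel()
    inten = np.zeros_like(wl)
    for c, w, a in params.lines:
        inten += _gauss(wl, c, w, a)
    if params.continuum is not None:
        c, w, a = params.continuum
        inten += _gauss(wl, c, w, a)
    scale = clamping.intensity_scale(power_fraction) / clamping.intensity_scale(1.0)
    inten *= scale
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0.0, params.noise_sd, size=wl.shape)
    return EmissionSpectrum(wl, inten)


# ---------------------------------------------------------------------- camera
@dataclass(frozen=True)
class CameraModel:
    """Parametric RGB spectral responses: Gaussian per channel.

    Channel order (R, G, B); each response is (center_nm, fwhm_nm, gain).
    """

    red: tuple[float, float, float] = (600.0, 80.0, 1.0)
    green: tuple[float, float, float] = (540.0, 80.0, 1.0)
    blue: tuple[float, float, float] = (460.0, 80.0, 1.0)
    exposure: float = 1.0

    def __post_init__(self) -> None:
        for c, w, g in (self.red, self.green, self.blue):
            if w <= 0 or g <= 0:
                raise ValueError("response fwhm and gain must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")

    def responses(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """(3, n) response curves on the given grid."""
        return np.stack([_gauss(wavelength_nm, c, w, g)
                         for c, w, g in (self.red, self.green, self.blue)])


def spectrum_to_rgb(spectrum: EmissionSpectrum,
                    camera: CameraModel | None = None) -> np.ndarray:
    """Linear, unclipped RGB triple: per-channel trapezoidal integral of
    intensity times the channel response, scaled by exposure."""
    camera = camera or CameraModel()
    resp = camera.responses(spectrum.wavelength_nm)
    rgb = np.trapezoid(resp * spectrum.intensity, spectrum.wavelength_nm, axis=1)
    return camera.exposure * rgb


# ----------------------------------------------------------------------- scene
@dataclass(frozen=True)
class EmissionEvent:
    x: float
    y: float
    sigma: float
    color: tuple[float, float, float]
    peak: float


#: Mean emission-event counts per frame observed in the filament region.
DEFAULT_EVENT_MEANS = {"blank": 0.0, "chalk": 5.0, "pollen": 1.0, "salt": 3.0}


@dataclass(frozen=True)
class SceneConfig:
    """Camera-frame geometry and event statistics.

    The filament appears as a horizontal stripe (the image of a ~3 mm
    channel); emission events are isotropic Gaussian blobs scattered along
    it.  ``power_fraction`` scales stripe and event brightness through the
    clamped intensity law.
    """

    width: int = 1920
    height: int = 1200
    stripe_row: int = 600
    stripe_thickness: float = 12.0
    stripe_length: int = 1400
    stripe_color: tuple[float, float, float] = (1.0, 0.97, 0.93)
    stripe_peak: float = 60.0
    event_means: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MEANS))
    event_sigma_mean: float = 16.0
    event_sigma_sd: float = 3.0
    event_sigma_min: float = 9.0
    event_sigma_max: float = 26.0
    event_peak: float = 235.0
    event_band_sd: float = 18.0
    background: float = 16.0
    noise_sd: float = 1.2
    power_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.power_fraction <= 1.0:
            raise ValueError("power_fraction must lie in (0, 1]")
        if self.event_means.get("blank", 0.0) != 0.0:
            raise ValueError("blank frames must have zero mean event count")
        if self.event_peak <= 0 or self.stripe_peak <= 0:
            raise ValueError("brightness scales must be positive")
        if self.event_sigma_max * 6 > min(self.width, self.height):
            raise ValueError("event radius exceeds the frame")


@dataclass
class LabeledImage:
    pixels: np.ndarray           # (H, W, 3) uint8
    label: str
    power_fraction: float
    seed: int | None
    events: list[EmissionEvent] = field(default_factory=list)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size=None) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def render_frame(class_label: str, scene: SceneConfig | None = None,
                 camera: CameraModel | None = None,
                 params: ClassSpectrumParams | None = None,
                 seed: int | None = None,
                 clamping: ClampingModel | None = None) -> LabeledImage:
    """Render one camera frame for a class.

    Background Gaussian noise + filament stripe + a Poisson-drawn number of
    emission blobs.  Each blob's colour is the camera rendering of a
    per-event draw from the class spectrum (line amplitudes jittered
    log-normally); its brightness follows the clamped intensity law at the
    scene's power fraction.  Deterministic for a fixed seed.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    scene = scene or SceneConfig()
    camera = camera or CameraModel()
    clamping = clamping or ClampingModel()
    base_params = params or DEFAULT_SPECTRA[class_label]
    rng = np.random.default_rng(seed)
    h, w = scene.height, scene.width

    img = np.full((h, w, 3), scene.background, dtype=np.float32)
    if scene.noise_sd > 0:
        noise = rng.standard_normal(size=img.shape, dtype=np.float32)
        noise *= np.float32(scene.noise_sd)
        img += noise

    rel = clamping.intensity_scale(scene.power_fraction) / clamping.intensity_scale(1.0)

    # filament stripe: Gaussian vertical profile, near-neutral colour
    # (only the +-5 sigma row band is touched)
    x0 = (w - scene.stripe_length) // 2
    sig_v = scene.stripe_thickness / _FWHM
    r0 = max(0, int(scene.stripe_row - 5 * sig_v))
    r1 = min(h, int(np.ceil(scene.stripe_row + 5 * sig_v)) + 1)
    rows = np.arange(r0, r1, dtype=np.float32)
    profile = np.exp(-0.5 * ((rows - scene.stripe_row) / sig_v) ** 2)
    stripe_rgb = np.asarray(scene.stripe_color, dtype=np.float32)
    stripe_rgb = stripe_rgb / stripe_rgb.max()
    img[r0:r1, x0:x0 + scene.stripe_length, :] += (
        scene.stripe_peak * rel * profile[:, None, None] * stripe_rgb[None, None, :])

    # emission events
    events: list[EmissionEvent] = []
    n_events = int(rng.poisson(scene.event_means.get(class_label, 0.0)))
    for _ in range(n_events):
        ex = float(rng.uniform(x0, x0 + scene.stripe_length))
        ey = float(rng.normal(scene.stripe_row, scene.event_band_sd))
        sigma = float(_truncnorm(rng, scene.event_sigma_mean, scene.event_sigma_sd,
                                 scene.event_sigma_min, scene.event_sigma_max))
        if 6 * sigma > min(h, w):
            raise ValueError("event radius exceeds the frame")
        jitter = rng.lognormal(0.0, 0.2, size=len(base_params.lines) + 1)
        lines = tuple((c, fw, a * j) for (c, fw, a), j in zip(base_params.lines, jitter))
        cont = base_params.continuum
        if cont is not None:
            cont = (cont[0], cont[1], cont[2] * float(jitter[-1]))
        spec_params = replace(base_params, lines=lines, continuum=cont)
        spec = make_emission_spectrum(class_label, scene.power_fraction, spec_params,
                                      seed=int(rng.integers(2 ** 31)), clamping=clamping)
        rgb = spectrum_to_rgb(spec, camera)
        if rgb.max() <= 0:
            continue
        color = rgb / rgb.max()
        peak = float(scene.event_peak * rel * rng.lognormal(0.0, 0.15))
        _add_blob(img, ex, ey, sigma, color * peak)
        events.append(EmissionEvent(ex, ey, sigma, tuple(color), peak))

    np.clip(img, np.float32(0.0), np.float32(255.0), out=img)
    pixels = img.astype(np.uint8)
    return LabeledImage(pixels, class_label, scene.power_fraction, seed, events)


def _add_blob(img: np.ndarray, x: float, y: float, sigma: float, rgb: np.ndarray) -> None:
    h, w = img.shape[:2]
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=np.float32) - y
    xx = np.arange(x0, x1, dtype=np.float32) - x
    blob = np.exp(-0.5 * ((yy[:, None] ** 2 + xx[None, :] ** 2) / sigma ** 2))
    img[y0:y1, x0:x1, :] += blob[:, :, None] * np.asarray(rgb, dtype=np.float32)


# --------------------------------------------------------------------- dataset
#: Study composition: curated per-class counts (sum 226), their stratified
#: 180/46 train/val split, an additional 26-image held-out test set, and a
#: 107-image reduced-power robustness set.
DEFAULT_CURATED = {"blank": 71, "chalk": 59, "pollen": 63, "salt": 33}
DEFAULT_TRAIN = {"blank": 57, "chalk": 47, "pollen": 50, "salt": 26}
DEFAULT_VAL = {"blank": 14, "chalk": 12, "pollen": 13, "salt": 7}
DEFAULT_TEST = {"blank": 8, "chalk": 7, "pollen": 7, "salt": 4}
DEFAULT_ROBUSTNESS = {"blank": 25, "chalk": 28, "pollen": 27, "salt": 27}


@dataclass
class DatasetConfig:
    """Counts, power levels, and scene/camera parameters for dataset builds.

    Manifested images are 960x960 crop segments of rendered frames (two per
    frame); a non-blank segment is curated in only if it contains at least
    one emission event.
    """

    curated: dict = field(default_factory=lambda: dict(DEFAULT_CURATED))
    train: dict = field(default_factory=lambda: dict(DEFAULT_TRAIN))
    val: dict = field(default_factory=lambda: dict(DEFAULT_VAL))
    test: dict = field(default_factory=lambda: dict(DEFAULT_TEST))
    robustness: dict = field(default_factory=lambda: dict(DEFAULT_ROBUSTNESS))
    power: float = 1.0
    robustness_power: float = 0.85
    scene: SceneConfig = field(default_factory=SceneConfig)
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        for cls in CLASSES:
            if self.train.get(cls, 0) + self.val.get(cls, 0) != self.curated.get(cls, 0):
                raise ValueError(f"train+val must equal curated for {cls}")
            for d in (self.curated, self.test, self.robustness):
                if d.get(cls, 0) < 0:
                    raise ValueError("counts must be non-negative")


@dataclass
class DatasetManifest:
    """Records of generated segment images and their split assignment."""

    records: pd.DataFrame      # columns: image_id, label, split, power_fraction,
    #                                     frame_seed, segment, path
    master_seed: int
    images: list[np.ndarray] | None = None

    def counts(self) -> pd.Series:
        return self.records.groupby(["split", "label"]).size()

    def select(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]


def _segment_geometry(h: int, w: int) -> tuple[int, int, int]:
    """(row0, row1, seg_side) of the two square crop segments.

    Each frame splits into a left and right square of side w/2, vertically
    centred to retain the filament stripe — 960x960 from rows [120, 1080)
    for the default 1920x1200 frame, scaling with smaller scene sizes."""
    side = w // 2
    if side > h:
        raise ValueError("frame too short for square segments")
    r0 = (h - side) // 2
    return r0, r0 + side, side


def _segment_views(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r0, r1, side = _segment_geometry(*frame.shape[:2])
    return frame[r0:r1, 0:side], frame[r0:r1, side:2 * side]


def _segment_has_event(events: list[EmissionEvent], side_name: str,
                       h: int, w: int) -> bool:
    r0, r1, side = _segment_geometry(h, w)
    lo, hi = (0, side) if side_name == "left" else (side, 2 * side)
    return any(r0 <= e.y < r1 and lo <= e.x < hi for e in events)


def build_image_dataset(config: DatasetConfig | None = None, seed: int = 0,
                        out_dir: str | Path | None = None,
                        transform=None, keep_images: bool = True) -> DatasetManifest:
    """Generate the curated dataset and its splits.

    Frames are rendered class by class with per-frame seeds derived from the
    master seed; each frame contributes up to two curated segments.  Splits
    are disjoint by construction (train, then val, then test in generation
    order; robustness rendered separately at the reduced power).  With
    ``out_dir`` the segments are written as 8-bit PNGs in class folders plus
    a ``manifest.csv``; ``transform`` (e.g. resize) is applied to each stored
    segment array.
    """
    config = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    images: list[np.ndarray] = []

    def class_split_plan(cls: str) -> list[str]:
        return (["train"] * config.train.get(cls, 0)
                + ["val"] * config.val.get(cls, 0)
                + ["test"] * config.test.get(cls, 0))

    for cls in CLASSES:
        plans = [(class_split_plan(cls), config.power),
                 (["robustness"] * config.robustness.get(cls, 0), config.robustness_power)]
        for plan, power in plans:
            scene = replace(config.scene, power_fraction=power)
            quota = len(plan)
            got = 0
            guard = 0
            while got < quota:
                guard += 1
                if guard > 40 * max(quota, 1):
                    raise RuntimeError(f"curation stalled for class {cls}")
                frame_seed = int(rng.integers(2 ** 31))
                frame = render_frame(cls, scene, config.camera, seed=frame_seed)
                segs = _segment_views(frame.pixels)
                for side, seg in zip(("left", "right"), segs):
                    if got >= quota:
                        break
                    if cls != "blank" and not _segment_has_event(
                            frame.events, side, scene.height, scene.width):
                        continue
                    arr = np.ascontiguousarray(seg)
                    if transform is not None:
                        arr = transform(arr)
                    rows.append({"image_id": len(rows), "label": cls,
                                 "split": plan[got], "power_fraction": power,
                                 "frame_seed": frame_seed, "segment": side,
                                 "path": ""})
                    images.append(arr if keep_images or out_dir else None)
                    got += 1

    records = pd.DataFrame(rows, columns=["image_id", "label", "split",
                                          "power_fraction", "frame_seed",
                                          "segment", "path"])
    manifest = DatasetManifest(records, master_seed=seed,
                               images=images if keep_images else None)
    if out_dir is not None:
        _materialize(manifest, images, Path(out_dir))
    return manifest


def _materialize(manifest: DatasetManifest, images: list[np.ndarray],
                 out_dir: Path) -> None:
    import imageio.v3 as iio
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for row, arr in zip(manifest.records.itertuples(), images):
        cls_dir = out_dir / row.split / row.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{row.image_id:05d}_{row.segment}.png"
        data = arr
        if data.dtype != np.uint8:
            data = np.clip(data * 255.0 if data.max() <= 1.0 else data,
                           0, 255).astype(np.uint8)
        iio.imwrite(path, data)
        paths.append(str(path.relative_to(out_dir)))
    manifest.records["path"] = paths
    manifest.records.to_csv(out_dir / "manifest.csv", index=False)


# ------------------------------------------------------------------ dark field
#: Per-class particle diameter distributions (mean, sd, lo, hi) in microns and
#: target (circularity, eccentricity).
DEFAULT_SIZES = {
    "chalk": (9.4, 4.1, 3.0, 28.0),
    "pollen": (20.7, 3.8, 4.6, 30.7),
    "salt": (21.8, 6.8, 12.0, 37.0),
}
DEFAULT_SHAPES = {
    "chalk": (0.74, 0.60),
    "pollen": (0.86, 0.55),
    "salt": (0.70, 0.66),
}


@dataclass(frozen=True)
class SlideConfig:
    """Dark-field slide rendering parameters (microscope scale 0.192 um/px)."""

    pixel_scale_um: float = 0.192
    sizes: dict = field(default_factory=lambda: dict(DEFAULT_SIZES))
    shapes: dict = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    background: float = 6.0
    noise_sd: float = 2.0
    brightness: float = 210.0
    image_px: int | None = None
    circ_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel scale must be positive")


def _polygon_props(xy: np.ndarray) -> tuple[float, float, float, float]:
    """(area, perimeter, circularity, eccentricity) of a closed polygon via
    the shoelace formula and Green's-theorem second moments."""
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    per = float(np.hypot(x1 - x, y1 - y).sum())
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    ixx = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    iyy = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    a = abs(area)
    cov = np.array([[iyy / area - cx * cx, ixy / area - cx * cy],
                    [ixy / area - cx * cy, ixx / area - cy * cy]])
    ev = np.linalg.eigvalsh(cov)
    lam2, lam1 = float(ev[0]), float(ev[1])
    ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1))) if lam1 > 0 else 0.0
    circ = 4.0 * np.pi * a / per ** 2
    return a, per, float(circ), ecc


def _make_particle_polygon(radius_px: float, ecc_target: float, circ_target: float,
                           rng: np.random.Generator, n_vertices: int = 180
                           ) -> tuple[np.ndarray, float, float]:
    """Rough-ellipse polygon with the requested area and shape statistics.

    Starts from an ellipse whose moment eccentricity equals ``ecc_target``,
    then adds low-order cosine boundary roughness whose amplitude is solved
    by bisection so the polygon circularity 4*pi*A/P^2 hits ``circ_target``.
    Returns (vertices, circularity, eccentricity) with the polygon rescaled
    to area pi*radius_px^2 (so the equivalent diameter is exact).
    """
    q = float(np.sqrt(max(1e-6, 1.0 - ecc_target ** 2)))  # minor/major ratio
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a_ax, b_ax = radius_px / np.sqrt(q), radius_px * np.sqrt(q)
    r_ell = a_ax * b_ax / np.sqrt((b_ax * np.cos(theta)) ** 2 + (a_ax * np.sin(theta)) ** 2)
    # modes start at 3: an m=2 component changes the second-moment ellipse
    # itself and would bias the eccentricity away from the target
    modes = np.arange(3, 10)
    coeff = rng.standard_normal(len(modes)) / modes
    phase = rng.uniform(0.0, 2.0 * np.pi, len(modes))
    rough = np.sum(coeff[:, None] * np.cos(modes[:, None] * theta[None, :]
                                           + phase[:, None]), axis=0)

    def poly(eps: float) -> np.ndarray:
        r = r_ell * np.clip(1.0 + eps * rough, 0.2, None)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    def circ(eps: float) -> float:
        return _polygon_props(poly(eps))[2]

    target = float(np.clip(circ_target + rng.normal(0.0, 0.02), 0.3, 0.99))
    lo, hi = 0.0, 0.5
    if circ(hi) > target:          # even max roughness too smooth: take max
        eps = hi
    elif circ(lo) < target:        # smooth ellipse already rougher than target
        eps = lo
    else:
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if circ(mid) > target:
                lo = mid
            else:
                hi = mid
        eps = 0.5 * (lo + hi)
    xy = poly(eps)
    area, _, c, e = _polygon_props(xy)
    xy = xy * np.sqrt(np.pi * radius_px ** 2 / abs(area))
    rot = rng.uniform(0.0, np.pi)
    rotm = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
    return xy @ rotm.T, c, e


def render_darkfield_slide(class_label: str, n_particles: int,
                           slide: SlideConfig | None = None,
                           seed: int | None = None
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Bright particles on a dark background plus per-particle ground truth.

    Diameters are truncated-normal draws from the class distribution; shapes
    are rough ellipses hitting the class circularity/eccentricity targets.
    The ground-truth table lists centroid (px), equivalent diameter (um),
    circularity and eccentricity of each drawn polygon.
    """
    if class_label not in DEFAULT_SIZES:
        raise ValueError(f"no dark-field model for class {class_label!r}")
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    slide = slide or SlideConfig()
    rng = np.random.default_rng(seed)
    mean, sd, lo, hi = slide.sizes[class_label]
    circ_t, ecc_t = slide.shapes[class_label]
    scale = slide.pixel_scale_um

    max_r_px = hi / 2.0 / scale
    if slide.image_px is not None:
        side = slide.image_px
    else:
        side = int(np.ceil(np.sqrt(max(n_particles, 1)) * max_r_px * 3.2)) + 64
        side = max(side, 256)

    img = np.full((side, side), slide.background, dtype=np.float32)
    if slide.noise_sd > 0:
        img += rng.normal(0.0, slide.noise_sd, size=img.shape).astype(np.float32)

    from skimage.draw import polygon as draw_polygon

    rows = []
    placed: list[tuple[float, float, float]] = []   # (cy, cx, clearance radius)
    for pid in range(n_particles):
        # size and shape are drawn once; only the position is re-drawn on
        # overlap, so crowding cannot bias the size distribution
        while True:
            d_um = float(_truncnorm(rng, mean, sd, lo, hi))
            r_px = d_um / 2.0 / scale
            if 2 * r_px * 1.6 < side:
                break
            log.info("particle of %.1f um larger than slide; resampled", d_um)
        xy, circ, ecc = _make_particle_polygon(r_px, ecc_t, circ_t, rng)
        clearance = float(np.hypot(xy[:, 0], xy[:, 1]).max()) + 2.0
        for _ in range(400):
            cy = float(rng.uniform(clearance + 2, side - clearance - 2))
            cx = float(rng.uniform(clearance + 2, side - clearance - 2))
            if all(np.hypot(cy - py, cx - px) > clearance + pr
                   for py, px, pr in placed):
                break
        else:
            raise RuntimeError("could not place particle; slide too crowded")
        placed.append((cy, cx, clearance))
        rr, cc = draw_polygon(xy[:, 1] + cy, xy[:, 0] + cx, shape=img.shape)
        img[rr, cc] = slide.brightness + rng.normal(0.0, slide.noise_sd, size=rr.shape)
        rows.append({"particle_id": pid, "centroid_y_px": cy, "centroid_x_px": cx,
                     "d_eq_um": d_um, "circularity": circ, "eccentricity": ecc})

    table = pd.DataFrame(rows, columns=["particle_id", "centroid_y_px",
                                        "centroid_x_px", "d_eq_um",
                                        "circularity", "eccentricity"])
    return np.clip(img, 0, 255).astype(np.uint8), table
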