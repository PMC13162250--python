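"""Phenomenological power-dependent spectral model for a femtosecond filament.

A filament forms when an intense ultrashort pulse balances Kerr self-focusing
against plasma defocusing.  Two spectral signatures mark the transition as
pulse energy rises: supercontinuum broadening (emission growing beyond
~550 nm) and intensity clamping (the total emission saturating).  This module
provides

* :class:`ClampingModel` — a saturating intensity law plus a broadening law
  that switches on at an onset power fraction (default 0.85);
* spectral preprocessing (dark / filament-reference subtraction);
* a supra-550 nm band-fraction statistic and an onset detector built on it;
* diffraction-limited peak-intensity arithmetic for the focused pulse.

No nonlinear propagation is simulated; the model is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EmissionSpectrum", "PowerSeries", "ClampingModel", "LaserParams",
    "default_wavelength_grid", "process_spectrum", "supra550_fraction",
    "detect_onset", "peak_intensity", "generate_power_series",
]


def default_wavelength_grid() -> np.ndarray:
    """350-800 nm on a 1 nm step."""
    return np.arange(350.0, 801.0, 1.0)


@dataclass
class EmissionSpectrum:
    """Wavelength-sampled emission intensity in arbitrary units.

    ``wavelength_nm`` must be strictly increasing; intensities are clipped
    non-negative on construction.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.clip(np.asarray(self.intensity, dtype=float), 0.0, None)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if self.wavelength_nm.ndim != 1 or len(self.wavelength_nm) < 2:
            raise ValueError("need a 1-D grid with at least two samples")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def total(self) -> float:
        """Trapezoidal integral over the full grid."""
        return float(np.trapezoid(self.intensity, self.wavelength_nm))


@dataclass
class PowerSeries:
    """Spectra recorded at strictly increasing power fractions in (0, 1]."""

    powers: np.ndarray
    spectra: list[EmissionSpectrum]

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if len(self.powers) != len(self.spectra):
            raise ValueError("powers and spectra must align")
        if not np.all(np.diff(self.powers) > 0):
            raise ValueError("power fractions must be strictly increasing")
        if np.any(self.powers <= 0) or np.any(self.powers > 1 + 1e-9):
            raise ValueError("power fractions must lie in (0, 1]")
        self.powers = np.minimum(self.powers, 1.0)


@dataclass
class ClampingModel:
    """Saturating intensity law with continuum broadening past an onset.

    The emitted intensity scale is linear in power fraction ``p`` below the
    onset ``p0`` and saturates exponentially above it (clamping)::

        s(p) = slope*p                                         p <= p0
        s(p) = slope*(p0 + w*(1 - exp(-(p - p0)/w)))           p >  p0

    with ``w = sat_width``, so s is strictly increasing, C1, and approaches
    the plateau ``slope*(p0 + sat_width)`` as p -> 1.  The supra-550 nm
    continuum wing has Gaussian half-width ``broaden(p)``::

        broaden(p) = wing_width_nm                             p <  p0
        broaden(p) = wing_width_nm + broaden_jump_nm
                     + broaden_rate_nm*(p - p0)                p >= p0

    The discontinuous jump at onset makes the broadening detectable at the
    onset grid point itself, mirroring the step-like appearance of the
    supercontinuum once full filamentation is reached.
    """

    onset_fraction: float = 0.85
    slope: float = 1.0
    sat_width: float = 0.05
    wing_width_nm: float = 18.0
    broaden_jump_nm: float = 45.0
    broaden_rate_nm: float = 160.0
    core_center_nm: float = 440.0
    core_fwhm_nm: float = 110.0
    wing_amplitude: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.onset_fraction < 1.0:
            raise ValueError("onset_fraction must lie in (0, 1)")

    def intensity_scale(self, p) -> np.ndarray | float:
        p = np.asarray(p, dtype=float)
        pre = self.slope * p
        post = self.slope * (self.onset_fraction + self.sat_width *
                             (1.0 - np.exp(-(p - self.onset_fraction) / self.sat_width)))
        out = np.where(p <= self.onset_fraction, pre, post)
        return float(out) if out.ndim == 0 else out

    @property
    def plateau(self) -> float:
        return self.slope * (self.onset_fraction + self.sat_width)

    def broaden_width(self, p: float) -> float:
        # float-tolerant: a power grid built by accumulation may represent the
        # onset point as p0 - 1 ulp
        if p < self.onset_fraction - 1e-9:
            return self.wing_width_nm
        return (self.wing_width_nm + self.broaden_jump_nm
                + self.broaden_rate_nm * (p - self.onset_fraction))

    def spectrum(self, p: float, wavelength_nm: np.ndarray | None = None,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None) -> EmissionSpectrum:
        """Model emission spectrum at power fraction ``p``."""
        if not 0.0 < p <= 1.0 + 1e-9:
            raise ValueError("power fraction must lie in (0, 1]")
        p = min(p, 1.0)
        wl = default_wavelength_grid() if wavelength_nm is None else np.asarray(wavelength_nm)
        sig_core = self.core_fwhm_nm / 2.3548200450309493
        core = np.exp(-0.5 * ((wl - self.core_center_nm) / sig_core) ** 2)
        w = self.broaden_width(p)
        wing = self.wing_amplitude * np.exp(-0.5 * ((wl - 550.0) / w) ** 2)
        wing[wl < 550.0] = 0.0  # one-sided supercontinuum wing
        intensity = self.intensity_scale(p) * (core + wing)
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            intensity = intensity + rng.normal(0.0, noise_sd, size=wl.shape)
        return EmissionSpectrum(wl, intensity)


@dataclass
class LaserParams:
    """Focused femtosecond pulse parameters (defaults: 190 fs, 1030 nm,
    8.9 mm 1/e^2 input beam, f = 100 mm, pulse energy in mJ)."""

    wavelength_nm: float = 1030.0
    pulse_fs: float = 190.0
    energy_mj: float = 1.0
    beam_diameter_mm: float = 8.9
    focal_length_mm: float = 100.0
    energy_range_mj: tuple[float, float] = (0.2, 1.0)

    def __post_init__(self) -> None:
        for v in (self.wavelength_nm, self.pulse_fs, self.energy_mj,
                  self.beam_diameter_mm, self.focal_length_mm):
            if v <= 0:
                raise ValueError("laser parameters must be positive")
        lo, hi = self.energy_range_mj
        if not lo <= self.energy_mj <= hi:
            raise ValueError(f"pulse energy outside configured range [{lo}, {hi}] mJ")


def process_spectrum(raw: EmissionSpectrum, dark: EmissionSpectrum,
                     reference: EmissionSpectrum) -> EmissionSpectrum:
    """raw - dark - filament-only reference, clipped at zero.

    All three spectra must share one wavelength grid.
    """
    if not (np.array_equal(raw.wavelength_nm, dark.wavelength_nm)
            and np.array_equal(raw.wavelength_nm, reference.wavelength_nm)):
        raise ValueError("wavelength grids differ")
    out = np.clip(raw.intensity - dark.intensity - reference.intensity, 0.0, None)
    return EmissionSpectrum(raw.wavelength_nm.copy(), out)


def supra550_fraction(spectrum: EmissionSpectrum, cut_nm: float = 550.0) -> float:
    """Fraction of trapezoid-integrated intensity beyond ``cut_nm``.

    Returns 0 for an identically zero spectrum.  The grid must span the cut;
    if the cut falls between samples, the spectrum is linearly interpolated
    there so the band edge is exact.
    """
    wl, inten = spectrum.wavelength_nm, spectrum.intensity
    if not (wl[0] <= cut_nm <= wl[-1]):
        raise ValueError("grid does not span the cut wavelength")
    total = np.trapezoid(inten, wl)
    if total <= 0:
        return 0.0
    if cut_nm in wl:
        mask = wl >= cut_nm
        supra = np.trapezoid(inten[mask], wl[mask])
    else:
        i_cut = float(np.interp(cut_nm, wl, inten))
        mask = wl > cut_nm
        supra = np.trapezoid(np.concatenate([[i_cut], inten[mask]]),
                             np.concatenate([[cut_nm], wl[mask]]))
    return float(supra / total)


def detect_onset(series: PowerSeries, baseline_k: float = 3.0,
                 n_baseline: int = 3) -> float | None:
    """Detect the filamentation onset power from continuum broadening.

    The supra-550 nm fraction is computed for every spectrum; the lowest
    ``n_baseline`` powers define a pre-onset baseline, and the onset is the
    smallest power whose fraction exceeds ``baseline mean + k * baseline sd``
    (plus a tiny absolute guard against float jitter).  Returns ``None`` when
    no point exceeds the threshold.
    """
    if len(series.powers) < n_baseline + 1:
        raise ValueError(f"need at least {n_baseline + 1} power points")
    frac = np.array([supra550_fraction(s) for s in series.spectra])
    base = frac[:n_baseline]
    thresh = base.mean() + baseline_k * base.std(ddof=0) + 1e-9
    for p, f in zip(series.powers[n_baseline:], frac[n_baseline:]):
        if f > thresh:
            return float(p)
    return None


def peak_intensity(laser: LaserParams) -> float:
    """Diffraction-limited peak intensity in W/cm^2.

    Convention (documented, not fitted to any printed number): Gaussian
    temporal peak power ``P = 0.94 E / tau``; focused 1/e^2 waist radius
    ``w0 = 2 lambda f / (pi D)`` for an input 1/e^2 beam *diameter* D; peak
    on-axis intensity of a Gaussian beam ``I = 2 P / (pi w0^2)``.  Strictly
    linear in pulse energy.
    """
    e_j = laser.energy_mj * 1e-3
    tau_s = laser.pulse_fs * 1e-15
    lam_m = laser.wavelength_nm * 1e-9
    f_m = laser.focal_length_mm * 1e-3
    d_m = laser.beam_diameter_mm * 1e-3
    p_pk = 0.94 * e_j / tau_s
    w0 = 2.0 * lam_m * f_m / (np.pi * d_m)
    i_w_m2 = 2.0 * p_pk / (np.pi * w0 ** 2)
    return float(i_w_m2 * 1e-4)  # W/m^2 -> W/cm^2


def generate_power_series(powers, model: ClampingModel | None = None,
                          noise_sd: float = 0.0,
                          seed: int | None = None) -> PowerSeries:
    """Render model spectra for an increasing grid of power fractions."""
    model = model or ClampingModel()
    rng = np.random.default_rng(seed)
    powers = np.asarray(powers, dtype=float)
    spectra = [model.spectrum(float(p), noise_sd=noise_sd, rng=rng) for p in powers]
    return PowerSeries(powers, spectra)
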