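"""Synthetic LC-DAD run generator with known ground truth.

Each analyte contributes a unit-area Gaussian peak (optionally
exponentially modified, for tailing) scaled so that its *integrated area*
at the analyte's detection wavelength equals the configured linear
response ``slope * C + intercept`` — calibrations in this method are
area-based, so the simulator anchors areas, not heights.  Across the
wavelength axis the peak is modulated by the analyte's band-model UV
spectrum, normalised to 1 at the detection wavelength.

On top of the peaks the run carries a linear baseline drift shared by all
wavelengths, i.i.d. Gaussian detector noise per point, and an optional
per-peak multiplicative area perturbation (``area_noise_rsd``) that models
injection-to-injection and integration variability.  Every random draw
flows from the config seed, so a run is bit-reproducible.

The response intercepts are deliberately kept in the simulated areas even
though single-marker quantification assumes pure proportionality: this
exposes the intercept-induced bias of the single-marker approximation to
the validation suite instead of hiding it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import exponnorm, norm

from .identify import SpectrumUV
from .signal import Chromatogram

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class AnalyteSpec:
    """Chromatographic and spectral constants for one analyte."""

    name: str
    retention_time: float  # minutes (Gaussian center)
    peak_width_sigma: float  # minutes
    response_slope: float  # area (mAU*min) per ug/mL
    uv_bands: tuple[tuple[float, float, float], ...]  # (center nm, width nm, rel. height)
    detection_wavelength: float  # nm
    response_intercept: float = 0.0  # area (mAU*min)
    tailing_tau: float = 0.0  # minutes; 0 = pure Gaussian

    def __post_init__(self) -> None:
        if self.peak_width_sigma <= 0:
            raise ValueError(f"{self.name}: peak_width_sigma must be positive")
        if self.response_slope <= 0:
            raise ValueError(f"{self.name}: response_slope must be positive")
        if not self.uv_bands or any(h <= 0 for _, _, h in self.uv_bands):
            raise ValueError(f"{self.name}: uv_bands must be non-empty with positive heights")
        if self.tailing_tau < 0:
            raise ValueError(f"{self.name}: tailing_tau must be non-negative")

    def spectrum_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Band-model UV profile, normalised to 1 at the detection wavelength."""
        wl = np.asarray(wavelengths, dtype=float)
        s = np.zeros_like(wl)
        for center, width, height in self.uv_bands:
            s += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
        ref = 0.0
        for center, width, height in self.uv_bands:
            ref += height * math.exp(-0.5 * ((self.detection_wavelength - center) / width) ** 2)
        if ref <= 0:
            raise ValueError(f"{self.name}: no absorbance at its detection wavelength")
        return s / ref

    def peak_shape(self, time: np.ndarray) -> np.ndarray:
        """Unit-area peak shape on the given time grid."""
        if self.tailing_tau > 0:
            k = self.tailing_tau / self.peak_width_sigma
            return exponnorm.pdf(time, k, loc=self.retention_time, scale=self.peak_width_sigma)
        return norm.pdf(time, loc=self.retention_time, scale=self.peak_width_sigma)

    def area_for(self, concentration: float) -> float:
        """Noiseless response: area = slope * C + intercept (zero at C = 0)."""
        if concentration == 0:
            return 0.0
        return self.response_slope * concentration + self.response_intercept


@dataclass
class RunConfig:
    """Everything needed to generate one simulated LC-DAD run."""

    analytes: list[AnalyteSpec]
    dead_time_marker: AnalyteSpec
    run_length: float  # minutes
    sampling_rate: float  # points per minute
    wavelength_grid: np.ndarray  # nm
    baseline_drift: float  # mAU per minute
    noise_sd: float  # mAU, additive per point
    seed: int
    area_noise_rsd: float = 0.0  # relative per-peak area variability
    marker_concentration: float = 20.0  # ug/mL of the dead-time marker
    detector_gain: float = 1.0  # common multiplier on all absorbances

    def __post_init__(self) -> None:
        self.wavelength_grid = np.sort(np.asarray(self.wavelength_grid, dtype=float))
        if self.seed is None:
            raise ValueError("seed is required")
        if self.noise_sd < 0 or self.area_noise_rsd < 0:
            raise ValueError("noise levels must be non-negative")
        t0 = self.dead_time_marker.retention_time
        sigmas = [a.peak_width_sigma for a in self.analytes] + [
            self.dead_time_marker.peak_width_sigma
        ]
        for a in self.analytes:
            if a.retention_time <= t0:
                raise ValueError(f"{a.name}: retention time must exceed the dead time")
            if self.run_length < a.retention_time + 5 * a.peak_width_sigma:
                raise ValueError(f"{a.name}: run too short for this retention time")
        if self.sampling_rate * 4.0 * min(sigmas) < 10:
            raise ValueError("sampling rate gives fewer than 10 points across the narrowest peak")

    def time_grid(self) -> np.ndarray:
        n = int(round(self.run_length * self.sampling_rate)) + 1
        return np.arange(n) / self.sampling_rate

    def analyte(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    def noiseless(self) -> "RunConfig":
        """Copy of this config with every noise source switched off."""
        return replace(self, noise_sd=0.0, area_noise_rsd=0.0)


@dataclass
class PeakTruth:
    """Ground truth for one simulated peak."""

    concentration: float  # ug/mL
    apex_time: float  # minutes
    area: float  # realized area in the data (mAU*min)
    nominal_area: float  # slope * C + intercept, before area noise/gain


@dataclass
class SimulatedRun:
    """A simulated DAD data matrix plus its generating truth."""

    config: RunConfig
    dad_matrix: np.ndarray  # time x wavelength, mAU
    ground_truth: dict[str, PeakTruth]
    warnings: list[str] = field(default_factory=list)

    @property
    def time(self) -> np.ndarray:
        return self.config.time_grid()

    @property
    def wavelengths(self) -> np.ndarray:
        return self.config.wavelength_grid


def simulate_run(config: RunConfig, concentrations: Mapping[str, float]) -> SimulatedRun:
    """Generate one run at the given per-analyte concentrations (ug/mL).

    Analytes absent from ``concentrations`` (or at 0) contribute no peak.
    The dead-time marker is always injected at the configured marker
    concentration.  Peaks closer than twice the sum of their widths are
    flagged in ``warnings`` — the method assumes baseline resolution.
    """
    unknown = set(concentrations) - {a.name for a in config.analytes}
    if unknown:
        raise KeyError(f"unknown analytes: {sorted(unknown)}")
    if any(c < 0 for c in concentrations.values()):
        raise ValueError("concentrations must be non-negative")

    rng = np.random.default_rng(config.seed)
    t = config.time_grid()
    wl = config.wavelength_grid
    dad = np.zeros((t.size, wl.size))
    truth: dict[str, PeakTruth] = {}
    flags: list[str] = []

    injected: list[tuple[AnalyteSpec, float]] = [
        (config.dead_time_marker, config.marker_concentration)
    ]
    for a in config.analytes:
        injected.append((a, float(concentrations.get(a.name, 0.0))))

    for spec, conc in injected:
        nominal = spec.area_for(conc)
        # one area-noise draw per configured analyte, taken regardless of
        # concentration so the noise stream is stable across scenarios
        factor = 1.0 + rng.normal(0.0, config.area_noise_rsd) if config.area_noise_rsd > 0 else 1.0
        if nominal == 0.0:
            continue
        area = nominal * factor
        shape = spec.peak_shape(t)
        dad += np.outer(area * shape, spec.spectrum_profile(wl))
        apex = float(t[int(np.argmax(shape))]) if spec.tailing_tau > 0 else spec.retention_time
        truth[spec.name] = PeakTruth(
            concentration=conc,
            apex_time=apex,
            area=area * config.detector_gain,
            nominal_area=nominal,
        )

    present = [s for s, c in injected if c > 0]
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            if abs(a.retention_time - b.retention_time) < 2 * (
                a.peak_width_sigma + b.peak_width_sigma
            ):
                msg = f"peaks overlap: {a.name} and {b.name}"
                flags.append(msg)
                warnings.warn(msg)

    dad += config.baseline_drift * t[:, None]
    dad *= config.detector_gain
    if config.noise_sd > 0:
        dad += rng.normal(0.0, config.noise_sd, dad.shape)
    return SimulatedRun(config=config, dad_matrix=dad, ground_truth=truth, warnings=flags)


def extract_trace(run: SimulatedRun, wavelength: float) -> Chromatogram:
    """Single-wavelength chromatogram (nearest grid column, snap recorded)."""
    wl = run.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]")
    j = int(np.argmin(np.abs(wl - wavelength)))
    meta = {"run_seed": run.config.seed}
    if wl[j] != wavelength:
        meta["snapped_from"] = wavelength
    return Chromatogram(
        time=run.time, absorbance=run.dad_matrix[:, j].copy(), wavelength=float(wl[j]), meta=meta
    )


def extract_apex_spectrum(run: SimulatedRun, apex_time: float) -> SpectrumUV:
    """Baseline-subtracted UV spectrum at the time slice nearest the apex.

    The local baseline per wavelength is the average of the mean signal in
    two flanking windows (0.3-0.6 min on either side of the apex), which
    removes linear drift exactly and keeps the subtraction linear in the
    data, so apex spectra of the same analyte at different concentrations
    stay strictly proportional.  A spectrum with no real signal is flagged
    via a warning.
    """
    t = run.time
    if apex_time < t[0] or apex_time > t[-1]:
        raise ValueError("apex_time outside the run")
    i = int(np.argmin(np.abs(t - apex_time)))

    def anchor(side: int) -> np.ndarray:
        lo_t = apex_time + side * 0.3
        hi_t = apex_time + side * 0.6
        lo_t, hi_t = min(lo_t, hi_t), max(lo_t, hi_t)
        mask = (t >= lo_t) & (t <= hi_t)
        if mask.sum() < 3:  # near run edge: fall back to nearest points
            edge = 0 if side < 0 else t.size - 1
            return run.dad_matrix[edge, :]
        return np.mean(run.dad_matrix[mask, :], axis=0)

    baseline = 0.5 * (anchor(-1) + anchor(+1))
    spec = run.dad_matrix[i, :] - baseline
    noise_scale = max(run.config.noise_sd, 1e-12)
    if float(np.max(np.abs(spec))) < 5 * noise_scale:
        warnings.warn(f"apex spectrum at {apex_time:.3f} min has no significant signal")
    return SpectrumUV(wavelength=run.wavelengths.copy(), absorbance=spec)


def expected_height(spec: AnalyteSpec, concentration: float) -> float:
    """Apex height (mAU) implied by the Gaussian area-height relation."""
    return spec.area_for(concentration) / (spec.peak_width_sigma * _SQRT_2PI)
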