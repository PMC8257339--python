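"""Double-indicator qualitative identification.

A chromatographic peak is identified only when two independent indicators
agree:

1. its dead-time-corrected relative retention time
   ``RRT = (t_x - t_0) / (t_i - t_0)`` matches a library value within a
   relative tolerance (``t_0`` is the unretained-marker elution time and
   ``t_i`` the internal reference's), and
2. its apex UV spectrum matches the library spectrum by the angle-cosine
   similarity ``C = sum(x_k y_k) / sqrt(sum(x_k^2) sum(y_k^2))`` — on both
   the raw spectrum and its first derivative with respect to wavelength.
   Derivative spectra magnify shape differences between otherwise similar
   chromophores, which is what makes the spectral indicator selective.

RRT is invariant under any affine rescaling of the time axis, so it
transfers across instruments, columns and flow rates far better than the
raw retention time does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .signal import PeakRecord

#: default indicator thresholds (overridable per call)
RRT_TOL_PCT = 5.0
RAW_SIM_MIN = 0.99
DERIV_SIM_MIN = 0.90


@dataclass
class SpectrumUV:
    """A baseline-subtracted UV absorbance spectrum on a uniform nm grid."""

    wavelength: np.ndarray  # nm, uniform, increasing
    absorbance: np.ndarray  # mAU
    analyte: str | None = None

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance must have the same length")
        if self.wavelength.size < 20:
            raise ValueError("spectrum needs at least 20 points")
        steps = np.diff(self.wavelength)
        if np.any(steps <= 0) or np.max(np.abs(steps - steps.mean())) > 1e-9:
            raise ValueError("wavelength grid must be uniform and increasing")

    @property
    def step(self) -> float:
        return float(self.wavelength[1] - self.wavelength[0])


@dataclass
class IdentificationResult:
    """Outcome of the double-indicator test for one peak."""

    candidate: str
    rrt: float
    rrt_reference: float
    raw_similarity: float
    deriv_similarity: float
    rrt_pass: bool
    spectrum_pass: bool
    identified: bool
    ambiguous: bool = False


def _resample_common(s1: SpectrumUV, s2: SpectrumUV, step: float = 1.0):
    """Linear-interpolate both spectra onto a shared grid over their overlap."""
    lo = max(s1.wavelength[0], s2.wavelength[0])
    hi = min(s1.wavelength[-1], s2.wavelength[-1])
    span1 = s1.wavelength[-1] - s1.wavelength[0]
    span2 = s2.wavelength[-1] - s2.wavelength[0]
    if hi - lo < 0.8 * min(span1, span2):
        raise ValueError("spectra overlap by less than 80% of their range")
    grid = np.arange(lo, hi + step / 2, step)
    a = np.interp(grid, s1.wavelength, s1.absorbance)
    b = np.interp(grid, s2.wavelength, s2.absorbance)
    return a, b


def cosine_similarity(s1: SpectrumUV, s2: SpectrumUV) -> float:
    """Angle cosine between two spectra after resampling to a common grid.

    Returns a value in [-1, 1]; 1 for proportional spectra (the measure is
    scale-invariant), near 0 for spectra with disjoint bands.  All-zero
    spectra have no defined angle and are rejected.
    """
    a, b = _resample_common(s1, s2)
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero spectrum")
    return float(np.clip(np.dot(a, b) / np.sqrt(na * nb), -1.0, 1.0))


def first_derivative(s: SpectrumUV) -> SpectrumUV:
    """First-derivative spectrum dA/d(lambda), Savitzky-Golay (window 7, order 2).

    Spectra shorter than the filter window fall back to central differences
    (with a warning); endpoints are handled by the filter's polynomial fit
    or one-sided differences respectively.
    """
    if s.wavelength.size >= 7:
        d = savgol_filter(s.absorbance, 7, 2, deriv=1, delta=s.step, mode="interp")
    else:
        warnings.warn("spectrum shorter than 7 points: using central differences")
        d = np.gradient(s.absorbance, s.wavelength)
    return SpectrumUV(wavelength=s.wavelength.copy(), absorbance=d, analyte=s.analyte)


def relative_retention_time(t_x: float, t_i: float, t_0: float) -> float:
    """Dead-time-corrected relative retention ``(t_x - t_0)/(t_i - t_0)``.

    ``t_0`` is the unretained marker, ``t_i`` the internal reference and
    ``t_x`` the peak under test.  The reference itself maps to 1 and the
    marker to 0.  Report to three decimals.
    """
    if t_i <= t_0:
        raise ValueError("reference must elute after the dead-time marker")
    if t_x < t_0:
        raise ValueError("peak elutes before the dead-time marker")
    return (t_x - t_0) / (t_i - t_0)


def identify_peak(
    peak: PeakRecord,
    apex_spectrum: SpectrumUV,
    library: list[tuple[str, float, SpectrumUV]],
    t_i: float,
    t_0: float,
    rrt_tol_pct: float = RRT_TOL_PCT,
    raw_sim_min: float = RAW_SIM_MIN,
    deriv_sim_min: float = DERIV_SIM_MIN,
) -> IdentificationResult:
    """Double-indicator identification against a reference library.

    The library is a list of ``(analyte, reference RRT, reference
    spectrum)``.  The candidate is the entry whose reference RRT is
    relatively closest to the peak's RRT; if more than one falls inside
    the RRT window the result is flagged ambiguous and spectral similarity
    breaks the tie.  ``identified`` requires both the RRT and the
    (raw AND derivative) spectral indicators to pass.
    """
    if not library:
        raise ValueError("library must not be empty")
    if not (0 < rrt_tol_pct < 100):
        raise ValueError("rrt_tol_pct out of range")

    rrt = relative_retention_time(peak.apex_time, t_i, t_0)
    in_window = [
        (name, ref_rrt, ref_spec)
        for name, ref_rrt, ref_spec in library
        if abs(rrt - ref_rrt) / ref_rrt <= rrt_tol_pct / 100.0
    ]
    ambiguous = len(in_window) > 1
    candidates = in_window if in_window else library

    def score(entry):
        name, ref_rrt, ref_spec = entry
        if ambiguous:  # spectrum as tie-breaker inside the RRT window
            return -cosine_similarity(apex_spectrum, ref_spec)
        return abs(rrt - ref_rrt) / ref_rrt

    name, ref_rrt, ref_spec = min(candidates, key=score)
    raw_sim = cosine_similarity(apex_spectrum, ref_spec)
    deriv_sim = cosine_similarity(first_derivative(apex_spectrum), first_derivative(ref_spec))
    rrt_pass = abs(rrt - ref_rrt) / ref_rrt <= rrt_tol_pct / 100.0
    spectrum_pass = raw_sim >= raw_sim_min and deriv_sim >= deriv_sim_min
    return IdentificationResult(
        candidate=name,
        rrt=rrt,
        rrt_reference=ref_rrt,
        raw_similarity=raw_sim,
        deriv_similarity=deriv_sim,
        rrt_pass=rrt_pass,
        spectrum_pass=spectrum_pass,
        identified=rrt_pass and spectrum_pass,
        ambiguous=ambiguous,
    )
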