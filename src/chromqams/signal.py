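"""Single-wavelength chromatogram processing.

Peak detection, boundary placement and trapezoidal integration on a
baseline-corrected trace, plus the supporting pieces: Savitzky-Golay
smoothing, asymmetric-least-squares baseline estimation, a pharmacopoeial
signal-to-noise ratio (height over twice the blank noise standard
deviation) and the half-height-width resolution formula
``Rs = 1.18 * (t2 - t1) / (w1/2,1 + w1/2,2)``.

All times are minutes, absorbances mAU, areas mAU*min.  The time grid is
treated as exact and must be uniform; no re-interpolation is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.signal import find_peaks, savgol_filter
from scipy.sparse.linalg import spsolve

_HALF_HEIGHT_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # w1/2 = 2.355 sigma
_BOUNDARY_FRACTION = 0.01  # integration stops where signal < 1% of peak height


@dataclass
class Chromatogram:
    """A single-wavelength absorbance trace on a uniform time grid."""

    time: np.ndarray  # minutes, strictly increasing, uniform
    absorbance: np.ndarray  # mAU
    wavelength: float | None = None  # nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have the same length")
        if self.time.size < 50:
            raise ValueError("chromatogram needs at least 50 points")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.max(np.abs(steps - steps.mean())) > 1e-6:
            raise ValueError("time axis must be uniform to within 1e-6 min")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class PeakRecord:
    """One detected chromatographic peak (baseline-corrected quantities)."""

    apex_time: float  # minutes
    start_time: float
    end_time: float
    height: float  # mAU above local baseline
    area: float  # mAU*min
    snr: float  # height / (2 * blank noise sd); inf when noiseless
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.start_time < self.apex_time < self.end_time):
            raise ValueError("peak boundaries must bracket the apex")
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")


def smooth(chrom: Chromatogram, window_points: int = 7, poly_order: int = 2) -> Chromatogram:
    """Savitzky-Golay smooth; endpoints by local polynomial extension."""
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    if window_points >= chrom.time.size:
        raise ValueError("window_points must be smaller than the trace")
    y = savgol_filter(chrom.absorbance, window_points, poly_order, mode="interp")
    return replace(chrom, absorbance=y, meta={**chrom.meta, "smoothed": (window_points, poly_order)})


def estimate_baseline(
    chrom: Chromatogram,
    lam: float = 1e8,
    p: float = 1e-4,
    niter: int = 20,
) -> Chromatogram:
    """Asymmetric-least-squares baseline (Eilers-Boelens style).

    Minimises a penalised least-squares criterion in which points above the
    current baseline carry weight ``p`` and points below carry ``1 - p``;
    ``lam`` controls stiffness.  With a drift-only trace the estimate
    reproduces the drift line; peaks are ignored because they only ever sit
    above the baseline.  Because the asymmetric fit settles on the lower
    noise envelope, the estimate is recentred afterwards by the median
    residual over near-baseline points, so peak areas carry no
    noise-dependent offset.
    """
    y = chrom.absorbance
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    penalty = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(niter):
        wmat = sparse.diags(w, 0)
        z = spsolve((wmat + penalty).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    sd = _noise_sd_robust(y)
    resid = y - z
    near = resid < 5.0 * sd + 1e-12
    if near.sum() > 10:
        z = z + np.median(resid[near])
    tol = max(5.0 * sd, 0.01 * float(np.ptp(y)) if np.ptp(y) > 0 else 0.0) + 1e-12
    low_frac = float(np.mean(np.abs(y - z) <= tol))
    meta = {**chrom.meta, "baseline": "asls"}
    if low_frac < 0.2:
        warnings.warn("fewer than 20% of points look peak-free; baseline set to global minimum")
        z = np.full(n, y.min())
        meta["baseline"] = "flat-minimum"
    return replace(chrom, absorbance=z, meta=meta)


def correct_baseline(chrom: Chromatogram, **kwargs) -> Chromatogram:
    """Subtract the estimated baseline from the trace."""
    base = estimate_baseline(chrom, **kwargs)
    return replace(
        chrom,
        absorbance=chrom.absorbance - base.absorbance,
        meta={**chrom.meta, "baseline_corrected": True},
    )


def _noise_sd_robust(y: np.ndarray) -> float:
    """Robust noise sd from successive differences (peak-insensitive)."""
    diffs = np.abs(np.diff(y))
    mad = np.median(diffs)
    return float(1.4826 * mad / math.sqrt(2.0))


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = 5.0,
    min_width: float = 0.01,
) -> list[PeakRecord]:
    """Detect, bound and integrate peaks on a baseline-corrected trace.

    Apexes are local maxima whose height exceeds ``min_snr`` times the
    robust noise estimate.  Boundaries run outward from each apex to the
    first valley or the first point below 1% of the apex height, whichever
    comes first; areas are trapezoidal between the boundaries.  Returns
    peaks sorted by apex time (empty list when nothing qualifies).
    """
    y = chrom.absorbance
    t = chrom.time
    noise = _noise_sd_robust(y)
    # relative floor (0.1% of trace max) guards noiseless traces against
    # residual baseline wiggles registering as peaks
    floor = max(min_snr * noise, 1e-3 * float(np.max(np.abs(y))))
    idx, _ = find_peaks(y, height=floor, prominence=floor)
    records: list[PeakRecord] = []
    n = y.size
    for k, i in enumerate(idx):
        h = y[i]
        cut = _BOUNDARY_FRACTION * h
        left_bound = idx[k - 1] if k > 0 else 0
        right_bound = idx[k + 1] if k + 1 < len(idx) else n - 1
        lo = left_bound + int(np.argmin(y[left_bound : i + 1])) if i > left_bound else i
        below = np.nonzero(y[lo : i + 1] < cut)[0]
        if below.size:
            lo = lo + int(below[-1])
        hi = i + int(np.argmin(y[i : right_bound + 1])) if right_bound > i else i
        below = np.nonzero(y[i : hi + 1] < cut)[0]
        if below.size:
            hi = i + int(below[0])
        if t[hi] - t[lo] < min_width or lo == i or hi == i:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], t[lo : hi + 1]))
        if area <= 0:
            continue
        snr = float(h / (2.0 * noise)) if noise > 0 else math.inf
        records.append(
            PeakRecord(
                apex_time=float(t[i]),
                start_time=float(t[lo]),
                end_time=float(t[hi]),
                height=float(h),
                area=area,
                snr=snr,
            )
        )
    records.sort(key=lambda r: r.apex_time)
    return records


def signal_to_noise(
    peak: PeakRecord,
    chrom: Chromatogram,
    blank_window: tuple[float, float],
) -> float:
    """S/N = peak height / (2 x sd of the blank-window signal).

    The blank window (minutes) must not overlap the peak.  A perfectly
    quiet blank yields ``inf``.
    """
    lo, hi = blank_window
    if lo >= hi:
        raise ValueError("blank window must have positive width")
    if lo < peak.end_time and hi > peak.start_time:
        raise ValueError("blank window overlaps the peak")
    mask = (chrom.time >= lo) & (chrom.time <= hi)
    if mask.sum() < 10:
        raise ValueError("blank window contains too few points")
    seg = chrom.absorbance[mask]
    sd = float(np.std(seg - seg.mean(), ddof=1))
    if sd <= 1e-12 * peak.height:  # effectively noiseless blank
        return math.inf
    return peak.height / (2.0 * sd)


def _half_height_width(peak: PeakRecord, chrom: Chromatogram) -> float:
    """Full width at half height by linear interpolation around the apex."""
    t, y = chrom.time, chrom.absorbance
    i = int(np.argmin(np.abs(t - peak.apex_time)))
    half = y[i] / 2.0
    left = None
    for j in range(i, 0, -1):
        if y[j - 1] <= half <= y[j]:
            frac = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = t[j - 1] + frac * (t[j] - t[j - 1])
            break
        if t[j - 1] < peak.start_time - (peak.end_time - peak.start_time):
            break
    right = None
    for j in range(i, y.size - 1):
        if y[j + 1] <= half <= y[j]:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = t[j] + frac * (t[j + 1] - t[j])
            break
        if t[j + 1] > peak.end_time + (peak.end_time - peak.start_time):
            break
    if left is None or right is None:
        raise ValueError(
            f"cannot resolve half-height width for peak at {peak.apex_time:.3f} min"
        )
    return right - left


def resolution(peak1: PeakRecord, peak2: PeakRecord, chrom: Chromatogram) -> float:
    """Half-height resolution Rs = 1.18 (t2 - t1) / (w1 + w2).

    Uses full widths at half height measured on the trace (European
    Pharmacopoeia convention); Rs > 1.5 indicates baseline separation.
    """
    if peak1.apex_time > peak2.apex_time:
        raise ValueError("peak1 must elute before peak2")
    if peak1.apex_time == peak2.apex_time:
        return 0.0
    w1 = _half_height_width(peak1, chrom)
    w2 = _half_height_width(peak2, chrom)
    return 1.18 * (peak2.apex_time - peak1.apex_time) / (w1 + w2)


def label_peaks(
    peaks: list[PeakRecord],
    expected: dict[str, float],
    tol: float = 0.5,
) -> dict[str, PeakRecord]:
    """Assign analyte names to peaks by nearest expected retention time.

    ``expected`` maps name -> expected apex (minutes); a peak is assigned
    only if within ``tol`` minutes.  Missing analytes are simply absent
    from the result.
    """
    out: dict[str, PeakRecord] = {}
    for name, rt in expected.items():
        best = None
        for p in peaks:
            d = abs(p.apex_time - rt)
            if d <= tol and (best is None or d < abs(best.apex_time - rt)):
                best = p
        if best is not None:
            best.label = name
            out[name] = best
    return out
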