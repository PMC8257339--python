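"""Per-analyte linear calibration and detection/quantification limits.

Calibration follows the conventional external-standard design: replicate
injections at five or more concentration levels, ordinary least squares of
the *level-mean* peak areas on concentration, and the Pearson correlation
of those level means as the linearity figure r.  Weighted fits (1/x,
1/x^2) are available for heteroscedastic data but the default is
unweighted.

Detection and quantification limits use the signal-to-noise convention of
the signal module (S/N = height / 2*blank sd): LOD is the concentration
whose expected Gaussian peak height reaches S/N = 3, LOQ the one reaching
S/N = 10, with an optional replicate-precision constraint (RSD <= 10%) on
the LOQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class CalibrationCurve:
    """Fitted linear response of one analyte (area vs concentration)."""

    analyte: str
    slope: float  # area (mAU*min) per ug/mL
    intercept: float  # area
    r: float  # Pearson correlation of level means
    levels: list[tuple[float, float, float]]  # (conc, mean area, RSD% of replicates)
    lod: float | None = None  # ug/mL
    loq: float | None = None  # ug/mL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: calibration slope must be positive")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r outside [-1, 1]")

    @property
    def linear_range(self) -> tuple[float, float]:
        concs = [c for c, _, _ in self.levels]
        return (min(concs), max(concs))

    def predict_area(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def report_row(self) -> dict:
        """Reporting-precision view: slope/intercept/r to 4 decimals."""
        lo, hi = self.linear_range
        return {
            "analyte": self.analyte,
            "slope": round(self.slope, 4),
            "intercept": round(self.intercept, 4),
            "r": round(self.r, 4),
            "linear_range_low": lo,
            "linear_range_high": hi,
            "lod": self.lod,
            "loq": self.loq,
        }


def fit_calibration(
    points: Iterable[tuple[float, float]],
    analyte: str,
    weighting: str | None = None,
) -> CalibrationCurve:
    """OLS calibration on level means.

    ``points`` are (concentration, area) pairs; replicates at the same
    concentration are averaged before fitting.  ``weighting`` may be
    ``None`` (default), ``"1/x"`` or ``"1/x2"``.
    """
    pts = [(float(c), float(a)) for c, a in points]
    if not pts:
        raise ValueError("no calibration points")
    by_level: dict[float, list[float]] = {}
    for c, a in pts:
        by_level.setdefault(c, []).append(a)
    concs = np.array(sorted(by_level))
    if concs.size < 5:
        raise ValueError("calibration needs at least 5 distinct concentration levels")
    if np.ptp(concs) == 0:
        raise ValueError("zero concentration variance")
    means = np.array([np.mean(by_level[c]) for c in concs])
    rsds = []
    for c in concs:
        reps = np.asarray(by_level[c])
        if reps.size > 1 and reps.mean() != 0:
            rsds.append(100.0 * reps.std(ddof=1) / reps.mean())
        else:
            rsds.append(0.0)

    if weighting is None:
        w = np.ones_like(concs)
    elif weighting == "1/x":
        w = 1.0 / concs
    elif weighting == "1/x2":
        w = 1.0 / concs**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    slope, intercept = np.polyfit(concs, means, 1, w=np.sqrt(w))
    r = float(np.corrcoef(concs, means)[0, 1])
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        levels=[(float(c), float(m), float(s)) for c, m, s in zip(concs, means, rsds)],
    )


def lod_loq(
    curve: CalibrationCurve,
    blank_noise_sd: float,
    peak_sigma: float,
    rsd_at: Callable[[float], float] | None = None,
    max_rsd_pct: float = 10.0,
) -> tuple[float, float]:
    """Detection and quantification limits from the S/N convention.

    The expected height of a Gaussian peak of area ``slope * C`` is
    ``slope * C / (sigma * sqrt(2 pi))``; setting height / (2 * noise) to
    3 and 10 gives LOD and LOQ.  If ``rsd_at`` is supplied (replicate RSD%
    as a function of concentration) the LOQ is raised until the RSD
    constraint ``<= max_rsd_pct`` is met; otherwise LOQ/LOD = 10/3 exactly.
    """
    if blank_noise_sd <= 0:
        raise ValueError("blank noise sd must be positive")
    if peak_sigma <= 0:
        raise ValueError("peak sigma must be positive")
    area_per_conc = curve.slope / (peak_sigma * _SQRT_2PI)  # height per ug/mL
    lod = 3.0 * 2.0 * blank_noise_sd / area_per_conc
    loq = 10.0 * 2.0 * blank_noise_sd / area_per_conc
    if rsd_at is not None:
        for _ in range(64):
            if rsd_at(loq) <= max_rsd_pct:
                break
            loq *= 1.25
        else:
            raise ValueError("replicate RSD constraint not satisfiable")
    return lod, loq
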