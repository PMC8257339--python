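"""Single-marker quantification (QAMS) and the external-standard method.

QAMS quantifies every analyte in a run from one internal reference
standard.  The relative correction factor of analyte x against reference
i is the ratio of response factors

    RCF_x = f_x / f_i = (A_x / C_x) / (A_i / C_i),

and once RCF_x is established the unknown concentration follows from the
reference peak alone:

    C_x = C_i / RCF_x * A_x / A_i.

Two RCF estimators are provided: the canonical slope ratio of the two
calibration curves, and the literal per-level ratio averaged over paired
measurements (with its RSD%, which quantifies how far the proportional
model is violated — e.g. by calibration intercepts).  Note that the QAMS
working equation is intercept-free by construction; when the underlying
responses do carry intercepts the method acquires a concentration-
dependent bias, which this module surfaces rather than corrects.

The external-standard method (ESM) — inverting each analyte's own
calibration line — is implemented alongside, with a paired t-test to
compare the two methods on the same runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationCurve


@dataclass
class RCFEntry:
    rcf: float
    method: str  # "slope_ratio" | "paired_levels"
    rsd_by_factor: dict[str, float] = field(default_factory=dict)  # robustness RSD%


@dataclass
class RCFTable:
    """Relative correction factors of each analyte versus the reference."""

    reference_analyte: str
    entries: dict[str, RCFEntry]

    def __post_init__(self) -> None:
        ref = self.entries.get(self.reference_analyte)
        if ref is None or ref.rcf != 1.0:
            raise ValueError("reference analyte must be present with RCF exactly 1")
        if any(e.rcf <= 0 for e in self.entries.values()):
            raise ValueError("all RCFs must be positive")

    def rcf(self, analyte: str) -> float:
        return self.entries[analyte].rcf

    def report_rows(self) -> list[dict]:
        """Reporting-precision view (RCF to 3 decimals)."""
        rows = []
        for name, e in self.entries.items():
            row = {"analyte": name, "rcf": round(e.rcf, 3), "method": e.method}
            row.update({f"rsd_{k}": round(v, 1) for k, v in e.rsd_by_factor.items()})
            rows.append(row)
        return rows


@dataclass
class QuantResult:
    """Quantification of one analyte in one run, by both methods."""

    analyte: str
    concentration_qams: float  # ug/mL
    concentration_esm: float  # ug/mL
    nominal: float | None = None  # ug/mL, when known
    reference_area: float | None = None  # A_i used by QAMS
    reference_concentration: float | None = None  # C_i used by QAMS

    @property
    def accuracy_qams_pct(self) -> float | None:
        return 100.0 * self.concentration_qams / self.nominal if self.nominal else None

    @property
    def accuracy_esm_pct(self) -> float | None:
        return 100.0 * self.concentration_esm / self.nominal if self.nominal else None


@dataclass
class MethodComparison:
    mean_diff: float
    t_statistic: float
    p_value: float
    rsd_qams_pct: float
    rsd_esm_pct: float

    @property
    def equivalent(self) -> bool:
        """No significant difference at the 5% level."""
        return self.p_value > 0.05


def rcf_from_slopes(curve_x: CalibrationCurve, curve_ref: CalibrationCurve) -> float:
    """RCF as the ratio of calibration slopes (full precision).

    This is the canonical estimator: with linear responses the response
    factor per unit concentration is the slope, so RCF_x = slope_x /
    slope_i.  Round to 3 decimals for reporting.
    """
    if curve_ref.slope <= 0:
        raise ValueError("reference slope must be positive")
    return curve_x.slope / curve_ref.slope


def rcf_from_paired_levels(
    measurements: Sequence[tuple[float, float, float, float]],
) -> tuple[float, float]:
    """Literal per-level RCF: mean and RSD% of (A_x/C_x)/(A_i/C_i).

    ``measurements`` are (A_x, C_x, A_i, C_i) tuples, one per level.  The
    RSD quantifies departure from strict proportionality.
    """
    if len(measurements) < 3:
        raise ValueError("need at least 3 paired levels")
    vals = []
    for a_x, c_x, a_i, c_i in measurements:
        if c_x == 0 or c_i == 0:
            raise ValueError("concentrations must be non-zero")
        vals.append((a_x / c_x) / (a_i / c_i))
    vals = np.asarray(vals)
    mean = float(vals.mean())
    rsd = float(100.0 * vals.std(ddof=1) / mean) if vals.size > 1 else 0.0
    return mean, rsd


def quantify_qams(a_x: float, a_i: float, c_i: float, rcf: float) -> float:
    """Single-marker concentration: C_x = C_i / RCF_x * A_x / A_i."""
    if a_i <= 0:
        raise ValueError("reference peak area must be positive (reference peak missing?)")
    if c_i <= 0 or rcf <= 0:
        raise ValueError("reference concentration and RCF must be positive")
    return c_i / rcf * a_x / a_i


def quantify_esm(a_x: float, curve_x: CalibrationCurve) -> float:
    """External-standard concentration: (A_x - intercept) / slope.

    Areas outside the calibrated area range are flagged (extrapolation);
    a negative result is clamped to 0 with a warning.
    """
    lo, hi = curve_x.linear_range
    if not (curve_x.predict_area(lo) <= a_x <= curve_x.predict_area(hi)):
        warnings.warn(f"{curve_x.analyte}: area {a_x:.3g} outside calibrated range (extrapolating)")
    c = (a_x - curve_x.intercept) / curve_x.slope
    if c < 0:
        warnings.warn(f"{curve_x.analyte}: negative back-calculated concentration clamped to 0")
        return 0.0
    return c


def compare_methods(paired: Sequence[tuple[float, float]]) -> MethodComparison:
    """Paired two-sided t-test between QAMS and ESM concentrations.

    ``paired`` holds (c_qams, c_esm) for the same samples.  Identical
    pairs give t = 0, p = 1; a constant non-zero offset with no scatter is
    maximally significant (p = 0).
    """
    if len(paired) < 3:
        raise ValueError("need at least 3 pairs")
    q = np.array([p[0] for p in paired], dtype=float)
    e = np.array([p[1] for p in paired], dtype=float)
    d = q - e
    mean_diff = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean_diff), 0.0
    else:
        t_stat, p = stats.ttest_rel(q, e)
        t_stat, p = float(t_stat), float(p)

    def rsd(x: np.ndarray) -> float:
        return float(100.0 * x.std(ddof=1) / x.mean()) if x.mean() != 0 else float("nan")

    return MethodComparison(
        mean_diff=mean_diff,
        t_statistic=t_stat,
        p_value=p,
        rsd_qams_pct=rsd(q),
        rsd_esm_pct=rsd(e),
    )


def rcf_table_from_curves(
    curves: Mapping[str, CalibrationCurve],
    reference: str = "ondansetron",
) -> RCFTable:
    """Build the slope-ratio RCF table from fitted calibrations."""
    if reference not in curves:
        raise KeyError(f"reference analyte {reference!r} has no calibration curve")
    ref = curves[reference]
    entries = {}
    for name, curve in curves.items():
        rcf = 1.0 if name == reference else rcf_from_slopes(curve, ref)
        entries[name] = RCFEntry(rcf=rcf, method="slope_ratio")
    return RCFTable(reference_analyte=reference, entries=entries)


def quantify_run(
    areas: Mapping[str, float],
    curves: Mapping[str, CalibrationCurve],
    rcf_table: RCFTable,
    reference_concentration: float,
    nominal: Mapping[str, float] | None = None,
) -> dict[str, QuantResult]:
    """Quantify every analyte of a run by both QAMS and ESM.

    ``areas`` maps analyte -> integrated peak area; the reference
    analyte's area anchors QAMS together with its known concentration
    ``reference_concentration``.  Analytes without a detected peak are
    simply absent from the result.
    """
    ref = rcf_table.reference_analyte
    if ref not in areas:
        raise ValueError(f"reference peak {ref!r} not found in this run")
    a_i = areas[ref]
    out: dict[str, QuantResult] = {}
    for name, a_x in areas.items():
        if name not in curves:
            continue
        out[name] = QuantResult(
            analyte=name,
            concentration_qams=quantify_qams(a_x, a_i, reference_concentration, rcf_table.rcf(name)),
            concentration_esm=quantify_esm(a_x, curves[name]),
            nominal=None if nominal is None else nominal.get(name),
            reference_area=a_i,
            reference_concentration=reference_concentration,
        )
    return out
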