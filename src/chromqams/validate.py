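"""ICH-style validation campaigns on simulated runs.

Precision (intra-/inter-day), accuracy by spike recovery, solution
stability, and robustness of the two transferable quantities — relative
retention time (RRT) and relative correction factor (RCF) — under
deliberate perturbations of flow rate, column temperature, mobile-phase pH
and organic fraction.

The perturbation-to-simulator mappings are declared here, not derived
from chromatographic theory: each factor carries a global time-axis scale
and detector-gain component (which cancel exactly in RRT and RCF) plus
small analyte-specific retention and response sensitivities (which do
not).  The robustness numbers are therefore structural checks on the
invariance properties of RRT and RCF, not predictions of any particular
instrument's behaviour.

All dispersions are RSD% = 100 * sd / mean with the (n-1) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationCurve
from .identify import relative_retention_time
from .signal import PeakRecord, correct_baseline, detect_peaks, label_peaks
from .simulate import AnalyteSpec, RunConfig, simulate_run, extract_trace


def rsd_pct(values: Sequence[float]) -> float:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    m = x.mean()
    if m == 0:
        raise ValueError("zero mean: RSD undefined")
    return float(100.0 * x.std(ddof=1) / m)


def measure_run(
    config: RunConfig,
    concentrations: Mapping[str, float],
    min_snr: float = 5.0,
) -> dict[str, PeakRecord]:
    """Simulate one run and return labelled peaks (analytes + marker).

    Peaks are detected per detection-wavelength trace after baseline
    correction and labelled by nearest expected retention time.
    """
    run = simulate_run(config, concentrations)
    by_wl: dict[float, list[AnalyteSpec]] = {}
    for spec in config.analytes:
        if concentrations.get(spec.name, 0.0) > 0:
            by_wl.setdefault(spec.detection_wavelength, []).append(spec)
    marker = config.dead_time_marker
    by_wl.setdefault(marker.detection_wavelength, []).append(marker)

    out: dict[str, PeakRecord] = {}
    for wl, specs in by_wl.items():
        trace = correct_baseline(extract_trace(run, wl))
        peaks = detect_peaks(trace, min_snr=min_snr)
        expected = {
            s.name: run.ground_truth[s.name].apex_time
            for s in specs
            if s.name in run.ground_truth
        }
        out.update(label_peaks(peaks, expected))
    return out


def nominal_curve(spec: AnalyteSpec, levels: Sequence[float]) -> CalibrationCurve:
    """Calibration curve implied by an analyte's configured response line."""
    return CalibrationCurve(
        analyte=spec.name,
        slope=spec.response_slope,
        intercept=spec.response_intercept,
        r=1.0,
        levels=[(float(c), spec.area_for(c), 0.0) for c in levels],
    )


# ---------------------------------------------------------------------------
# precision


@dataclass
class PrecisionRow:
    analyte: str
    concentration: float
    intraday_rsd_pct: float
    interday_rsd_pct: float


def precision_study(
    config: RunConfig,
    levels: Sequence[Mapping[str, float]],
    n_intraday: int = 3,
    n_days: int = 3,
    day_effect_rsd: float = 0.01,
) -> list[PrecisionRow]:
    """Replicate-injection precision within and across simulated days.

    Each day carries a shared multiplicative response factor (sd
    ``day_effect_rsd``) emulating day-to-day instrument drift; within-day
    replicates differ only by the config's own noise sources.  Intraday
    RSD is the mean of the within-day RSDs, interday RSD pools all runs.
    """
    if n_intraday < 3 or n_days < 2:
        raise ValueError("need n_intraday >= 3 and n_days >= 2")
    rng = np.random.default_rng(config.seed)
    rows: list[PrecisionRow] = []
    for li, level in enumerate(levels):
        areas: dict[str, list[list[float]]] = {name: [] for name in level}
        for day in range(n_days):
            gain = 1.0 + rng.normal(0.0, day_effect_rsd)
            day_areas: dict[str, list[float]] = {name: [] for name in level}
            for rep in range(n_intraday):
                cfg = replace(
                    config,
                    seed=config.seed + 100_000 * li + 1_000 * day + rep + 1,
                    detector_gain=config.detector_gain * gain,
                )
                peaks = measure_run(cfg, level)
                for name in level:
                    if name not in peaks:
                        raise RuntimeError(f"{name}: peak not detected in precision run")
                    day_areas[name].append(peaks[name].area)
            for name in level:
                areas[name].append(day_areas[name])
        for name, per_day in areas.items():
            intraday = float(np.mean([rsd_pct(d) for d in per_day]))
            interday = rsd_pct([a for d in per_day for a in d])
            rows.append(
                PrecisionRow(
                    analyte=name,
                    concentration=float(level[name]),
                    intraday_rsd_pct=intraday,
                    interday_rsd_pct=interday,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# accuracy / recovery


@dataclass
class RecoveryRow:
    analyte: str
    added: float  # ug/mL
    recovery_pct: float
    rsd_pct: float


def recovery_study(
    config: RunConfig,
    base_sample: Mapping[str, float],
    spike_levels: Sequence[Mapping[str, float]],
    n: int = 3,
    curves: Mapping[str, CalibrationCurve] | None = None,
) -> list[RecoveryRow]:
    """Spike recovery: (measured_spiked - measured_base) / added * 100.

    The base sample is measured ``n`` times, then each spike level ``n``
    times; concentrations are back-calculated through each analyte's
    calibration (the configured response lines unless ``curves`` is
    given).  Recoveries below 100% are reported as such, never as errors.
    """
    if n < 3:
        raise ValueError("need n >= 3 replicates")
    if curves is None:
        curves = {
            s.name: nominal_curve(s, [c for c in (1.0, 5.0, 20.0, 50.0, 100.0)])
            for s in config.analytes
        }

    def measured(concs: Mapping[str, float], seed: int) -> dict[str, list[float]]:
        vals: dict[str, list[float]] = {k: [] for k in concs}
        for rep in range(n):
            cfg = replace(config, seed=seed + rep)
            peaks = measure_run(cfg, concs)
            for name in concs:
                if name not in peaks:
                    raise RuntimeError(f"{name}: peak not detected in recovery run")
                area = peaks[name].area
                c = (area - curves[name].intercept) / curves[name].slope
                vals[name].append(c)
        return vals

    base_meas = measured(base_sample, config.seed + 10_000)
    rows: list[RecoveryRow] = []
    for si, spikes in enumerate(spike_levels):
        if any(v <= 0 for v in spikes.values()):
            raise ValueError("spike amounts must be positive")
        total = {k: base_sample.get(k, 0.0) + spikes.get(k, 0.0) for k in base_sample}
        spiked_meas = measured(total, config.seed + 20_000 + 100 * si)
        for name, added in spikes.items():
            base_mean = float(np.mean(base_meas[name]))
            recs = [100.0 * (c - base_mean) / added for c in spiked_meas[name]]
            rows.append(
                RecoveryRow(
                    analyte=name,
                    added=float(added),
                    recovery_pct=float(np.mean(recs)),
                    rsd_pct=rsd_pct(recs) if len(recs) > 1 and np.mean(recs) != 0 else 0.0,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# stability


@dataclass
class StabilityReport:
    rsd_by_analyte: dict[str, float]
    flagged: set[str]  # analytes exceeding the 2.0% stability criterion


def stability_series(
    areas_over_time: Sequence[tuple[float, Mapping[str, float]]],
    max_rsd_pct: float = 2.0,
) -> StabilityReport:
    """RSD% of peak areas across a timed injection series (e.g. 0-8 h)."""
    if len(areas_over_time) < 3:
        raise ValueError("need at least 3 time points")
    names = set(areas_over_time[0][1])
    rsds = {
        name: rsd_pct([dict(areas)[name] for _, areas in areas_over_time]) for name in names
    }
    return StabilityReport(
        rsd_by_analyte=rsds,
        flagged={n for n, v in rsds.items() if v > max_rsd_pct},
    )


# ---------------------------------------------------------------------------
# robustness


@dataclass(frozen=True)
class FactorSpec:
    """One robustness factor and its simulator mapping.

    ``time_scale`` and ``gain`` are global fractional changes per +1 level
    (they cancel in RRT and RCF by construction); ``retention_shift`` and
    ``response_shift`` are analyte-specific fractional sensitivities per
    +1 level (they do not cancel).
    """

    name: str
    time_scale: float = 0.0
    gain: float = 0.0
    retention_shift: Mapping[str, float] = field(default_factory=dict)
    response_shift: Mapping[str, float] = field(default_factory=dict)

    def apply(self, config: RunConfig, level: int) -> RunConfig:
        ts = 1.0 + self.time_scale * level
        analytes = [
            replace(
                a,
                retention_time=a.retention_time
                * ts
                * (1.0 + self.retention_shift.get(a.name, 0.0) * level),
                response_slope=a.response_slope
                * (1.0 + self.response_shift.get(a.name, 0.0) * level),
            )
            for a in config.analytes
        ]
        marker = replace(
            config.dead_time_marker,
            retention_time=config.dead_time_marker.retention_time * ts,
        )
        return replace(
            config,
            analytes=analytes,
            dead_time_marker=marker,
            detector_gain=config.detector_gain * (1.0 + self.gain * level),
        )


@dataclass
class PerturbationGrid:
    factors: list[FactorSpec]


def default_perturbation_grid() -> PerturbationGrid:
    """Default factor mappings for the five-setron method.

    Magnitudes correspond to the usual deliberate variations (flow +-0.02
    mL/min, temperature +-1 C, pH +-0.2, organic fraction +-2%); the
    analyte-specific sensitivities are small (0.2-1.5%) and signed
    differently per analyte so that selectivity genuinely changes.
    """
    return PerturbationGrid(
        factors=[
            FactorSpec(
                name="flow_rate",
                time_scale=-0.02,
                gain=-0.02,
                retention_shift={
                    "azasetron": 0.003,
                    "granisetron": -0.002,
                    "tropisetron": 0.002,
                    "ramosetron": -0.003,
                },
                response_shift={
                    "azasetron": 0.004,
                    "granisetron": 0.003,
                    "tropisetron": -0.003,
                    "ramosetron": 0.004,
                },
            ),
            FactorSpec(
                name="temperature",
                time_scale=-0.005,
                retention_shift={
                    "azasetron": -0.002,
                    "granisetron": 0.002,
                    "tropisetron": 0.003,
                    "ramosetron": 0.002,
                },
                response_shift={
                    "azasetron": 0.002,
                    "granisetron": -0.002,
                    "tropisetron": 0.003,
                    "ramosetron": 0.002,
                },
            ),
            FactorSpec(
                name="ph",
                retention_shift={
                    "azasetron": 0.010,
                    "granisetron": -0.008,
                    "tropisetron": 0.010,
                    "ramosetron": -0.007,
                },
                response_shift={
                    "azasetron": 0.008,
                    "granisetron": 0.006,
                    "tropisetron": -0.008,
                    "ramosetron": 0.009,
                },
            ),
            FactorSpec(
                name="acetonitrile",
                time_scale=-0.015,
                retention_shift={
                    "azasetron": 0.012,
                    "granisetron": 0.008,
                    "tropisetron": -0.010,
                    "ramosetron": 0.010,
                },
                response_shift={
                    "azasetron": -0.006,
                    "granisetron": 0.008,
                    "tropisetron": 0.007,
                    "ramosetron": -0.008,
                },
            ),
        ]
    )


@dataclass
class RobustnessReport:
    """Per-factor RSD% of RRT and RCF across the -1/0/+1 condition levels."""

    reference_analyte: str
    rrt_rsd: dict[str, dict[str, float]]  # factor -> analyte -> RSD%
    rcf_rsd: dict[str, dict[str, float]]
    rrt_values: dict[str, dict[str, list[float]]]
    rcf_values: dict[str, dict[str, list[float]]]


def robustness_campaign(
    grid: PerturbationGrid,
    config: RunConfig,
    concentrations: Mapping[str, float] | None = None,
    reference: str = "ondansetron",
) -> RobustnessReport:
    """Recompute RRT and RCF at each factor's -1/0/+1 levels.

    For every condition the run is re-simulated, peaks re-detected, the
    dead time and reference retention re-measured, and the per-analyte RRT
    and paired-level RCF recomputed; the report holds the RSD% across the
    three conditions.  The reference analyte's rows are identically zero
    by construction (RRT = RCF = 1 in every condition).
    """
    if concentrations is None:
        concentrations = {
            a.name: 3.0 if a.name == "ramosetron" else 20.0 for a in config.analytes
        }
    names = [a.name for a in config.analytes]
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among the analytes")
    c_i = concentrations[reference]

    rrt_vals: dict[str, dict[str, list[float]]] = {}
    rcf_vals: dict[str, dict[str, list[float]]] = {}
    for fi, factor in enumerate(grid.factors):
        rrt_vals[factor.name] = {n: [] for n in names}
        rcf_vals[factor.name] = {n: [] for n in names}
        for level in (-1, 0, 1):
            cfg = factor.apply(config, level)
            cfg = replace(cfg, seed=config.seed + 10 * fi + (level + 1) + 1)
            peaks = measure_run(cfg, concentrations)
            if reference not in peaks or cfg.dead_time_marker.name not in peaks:
                raise RuntimeError("reference or dead-time peak not detected")
            t_0 = peaks[cfg.dead_time_marker.name].apex_time
            t_i = peaks[reference].apex_time
            a_i = peaks[reference].area
            for n in names:
                if n not in peaks:
                    raise RuntimeError(f"{n}: peak not detected in robustness run")
                rrt_vals[factor.name][n].append(
                    relative_retention_time(peaks[n].apex_time, t_i, t_0)
                )
                rcf_vals[factor.name][n].append(
                    (peaks[n].area / concentrations[n]) / (a_i / c_i)
                )

    rrt_rsd = {f: {n: rsd_pct(v) for n, v in per.items()} for f, per in rrt_vals.items()}
    rcf_rsd = {f: {n: rsd_pct(v) for n, v in per.items()} for f, per in rcf_vals.items()}
    return RobustnessReport(
        reference_analyte=reference,
        rrt_rsd=rrt_rsd,
        rcf_rsd=rcf_rsd,
        rrt_values=rrt_vals,
        rcf_values=rcf_vals,
    )
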