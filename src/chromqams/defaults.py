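"""Built-in method constants for the five-setron HPLC-DAD assay.

The package ships a default method configuration for the simultaneous
determination of five 5-HT3 receptor antagonists (azasetron, granisetron,
tropisetron, ondansetron, ramosetron) on a 15-min isocratic C18 run with
diode-array detection.  Ondansetron is the internal reference analyte for
single-marker (QAMS) quantification; an unretained uracil-like marker at
1.20 min provides the dead time for relative-retention-time work.

Per-analyte constants:

* detection wavelengths: 307 nm (ondansetron, azasetron, ramosetron),
  302 nm (granisetron), 285 nm (tropisetron);
* area-response regression lines (area in mAU*min versus concentration in
  ug/mL), used both as the simulator's ground-truth response and as the
  nominal calibration of the method;
* retention times placed so the dead-time-corrected relative retention
  times are 0.431, 0.679, 0.812, 1.000 and 1.132 with t0 = 1.20 min and
  the reference eluting at 9.00 min;
* synthetic two-band UV spectra (Gaussian bands on 220-400 nm) shaped so
  that ondansetron and ramosetron are spectrally the closest pair and the
  first-derivative spectra separate all five analytes more strongly than
  the raw spectra do.
"""

from __future__ import annotations

import numpy as np

from .simulate import AnalyteSpec, RunConfig

REFERENCE_ANALYTE = "ondansetron"

DEAD_TIME_MIN = 1.20
REFERENCE_RETENTION_MIN = 9.00

#: calibration level grids (ug/mL): six levels per analyte
CALIBRATION_LEVELS: dict[str, tuple[float, ...]] = {
    "azasetron": (5.0, 10.0, 20.0, 50.0, 75.0, 100.0),
    "granisetron": (5.0, 10.0, 20.0, 50.0, 75.0, 100.0),
    "tropisetron": (5.0, 10.0, 20.0, 50.0, 75.0, 100.0),
    "ondansetron": (5.0, 10.0, 20.0, 50.0, 75.0, 100.0),
    "ramosetron": (0.5, 3.0, 6.0, 20.0, 30.0, 50.0),
}

#: precision-study concentration levels (ug/mL)
PRECISION_LEVELS: dict[str, tuple[float, ...]] = {
    "azasetron": (10.0, 20.0, 50.0),
    "granisetron": (10.0, 20.0, 50.0),
    "tropisetron": (10.0, 20.0, 50.0),
    "ondansetron": (10.0, 20.0, 50.0),
    "ramosetron": (1.0, 3.0, 6.0),
}


def default_analytes() -> list[AnalyteSpec]:
    """The five setron analytes with their default method constants."""
    return [
        AnalyteSpec(
            name="azasetron",
            retention_time=4.562,
            peak_width_sigma=0.060,
            response_slope=0.6321,
            response_intercept=1.3833,
            uv_bands=((240.0, 16.0, 1.00), (307.0, 28.0, 0.55)),
            detection_wavelength=307.0,
        ),
        AnalyteSpec(
            name="granisetron",
            retention_time=6.496,
            peak_width_sigma=0.080,
            response_slope=0.6957,
            response_intercept=0.5444,
            uv_bands=((236.0, 12.0, 0.62), (298.0, 30.0, 1.00)),
            detection_wavelength=302.0,
        ),
        AnalyteSpec(
            name="tropisetron",
            retention_time=7.534,
            peak_width_sigma=0.090,
            response_slope=1.0634,
            response_intercept=4.8592,
            uv_bands=((234.0, 13.0, 0.65), (285.0, 21.0, 1.00)),
            detection_wavelength=285.0,
        ),
        AnalyteSpec(
            name="ondansetron",
            retention_time=REFERENCE_RETENTION_MIN,
            peak_width_sigma=0.100,
            response_slope=1.8585,
            response_intercept=5.2914,
            uv_bands=((250.0, 17.0, 0.80), (307.0, 22.0, 1.00)),
            detection_wavelength=307.0,
        ),
        AnalyteSpec(
            name="ramosetron",
            retention_time=10.030,
            peak_width_sigma=0.110,
            response_slope=2.3167,
            response_intercept=8.6551,
            uv_bands=((256.0, 20.0, 0.72), (309.0, 26.0, 1.00)),
            detection_wavelength=307.0,
        ),
    ]


def default_dead_time_marker() -> AnalyteSpec:
    """Unretained dead-time marker (uracil-like: single 258 nm band)."""
    return AnalyteSpec(
        name="dead_time_marker",
        retention_time=DEAD_TIME_MIN,
        peak_width_sigma=0.040,
        response_slope=1.0,
        response_intercept=0.0,
        uv_bands=((258.0, 20.0, 1.0),),
        detection_wavelength=258.0,
    )


def default_config(
    seed: int,
    *,
    noise_sd: float = 0.2,
    baseline_drift: float = 0.1,
    area_noise_rsd: float = 0.01,
    wavelength_grid: np.ndarray | None = None,
) -> RunConfig:
    """Default 15-min five-setron run configuration.

    ``noise_sd`` (mAU) is additive detector noise; ``area_noise_rsd`` is the
    per-peak relative area variability that models injection/integration
    scatter (default 1%).  Pass zeros for a fully noiseless run.
    """
    if wavelength_grid is None:
        wavelength_grid = np.arange(220.0, 401.0, 1.0)
    return RunConfig(
        analytes=default_analytes(),
        dead_time_marker=default_dead_time_marker(),
        run_length=15.0,
        sampling_rate=120.0,
        wavelength_grid=wavelength_grid,
        baseline_drift=baseline_drift,
        noise_sd=noise_sd,
        area_noise_rsd=area_noise_rsd,
        seed=seed,
    )


def quantification_wavelengths() -> np.ndarray:
    """Minimal wavelength grid covering every detection channel.

    Useful for quantification-only simulations where full spectra are not
    needed (keeps the DAD matrix small).
    """
    return np.array([258.0, 285.0, 302.0, 307.0])
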