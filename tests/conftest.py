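import numpy as np
import pytest

import chromqams as cq
from chromqams import defaults

STANDARD_SAMPLE = {
    "azasetron": 20.0,
    "granisetron": 20.0,
    "tropisetron": 20.0,
    "ondansetron": 20.0,
    "ramosetron": 3.0,
}

#: printed response lines of the five analytes (slope, intercept)
RESPONSE_LINES = {
    "azasetron": (0.6321, 1.3833),
    "granisetron": (0.6957, 0.5444),
    "tropisetron": (1.0634, 4.8592),
    "ondansetron": (1.8585, 5.2914),
    "ramosetron": (2.3167, 8.6551),
}


@pytest.fixture(scope="session")
def standard_sample():
    return dict(STANDARD_SAMPLE)


@pytest.fixture(scope="session")
def noiseless_config():
    return cq.default_config(seed=1).noiseless()


@pytest.fixture(scope="session")
def noiseless_run(noiseless_config):
    return cq.simulate_run(noiseless_config, STANDARD_SAMPLE)


@pytest.fixture(scope="session")
def exact_curves():
    """Calibrations fitted to points generated exactly on the response lines."""
    curves = {}
    for name, (slope, intercept) in RESPONSE_LINES.items():
        levels = defaults.CALIBRATION_LEVELS[name]
        pts = [(c, slope * c + intercept) for c in levels]
        curves[name] = cq.fit_calibration(pts, name)
    return curves


@pytest.fixture(scope="session")
def reference_library(noiseless_config):
    """Identification library built from a noiseless run at 20 ug/mL each."""
    cfg = noiseless_config
    run = cq.simulate_run(cfg, {a.name: 20.0 for a in cfg.analytes})
    t_0 = run.ground_truth[cfg.dead_time_marker.name].apex_time
    t_i = run.ground_truth["ondansetron"].apex_time
    lib = []
    for spec in cfg.analytes:
        apex = run.ground_truth[spec.name].apex_time
        s = cq.extract_apex_spectrum(run, apex)
        s.analyte = spec.name
        lib.append((spec.name, cq.relative_retention_time(apex, t_i, t_0), s))
    return {"library": lib, "t_0": t_0, "t_i": t_i}


def quant_config(seed, **kwargs):
    """Small-wavelength-grid config for quantification-only simulations."""
    return cq.default_config(
        seed=seed, wavelength_grid=defaults.quantification_wavelengths(), **kwargs
    )
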