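"""Double-indicator identification: angle-cosine similarity, derivative
spectra, dead-time-corrected RRT, and the combined decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chromqams as cq
from chromqams.signal import PeakRecord


def _spec(values, start=220.0, step=1.0, analyte=None):
    values = np.asarray(values, float)
    wl = start + step * np.arange(values.size)
    return cq.SpectrumUV(wavelength=wl, absorbance=values, analyte=analyte)


def _band(center, width, height, wl=None):
    if wl is None:
        wl = np.arange(220.0, 401.0)
    return height * np.exp(-0.5 * ((wl - center) / width) ** 2)


# --- cosine similarity -------------------------------------------------------


def test_cosine_hand_computed_value():
    """(1,2,3) vs (2,3,4) padded to spectrum length: the 3-point core gives
    20/sqrt(14*29); here we use repeated blocks to keep >= 20 points while
    preserving the ratio structure."""
    a = np.tile([1.0, 2.0, 3.0], 8)
    b = np.tile([2.0, 3.0, 4.0], 8)
    expected = np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b))
    assert expected == pytest.approx(20 / np.sqrt(14 * 29), abs=1e-12)
    assert cq.cosine_similarity(_spec(a), _spec(b)) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_cosine_scale_invariance(scale):
    s = _spec(_band(300, 20, 1.0))
    assert cq.cosine_similarity(s, _spec(scale * s.absorbance)) == pytest.approx(1.0, abs=1e-9)


def test_cosine_symmetry_and_unit_diagonal():
    s1 = _spec(_band(260, 15, 1.0))
    s2 = _spec(_band(320, 18, 0.7))
    assert cq.cosine_similarity(s1, s2) == pytest.approx(cq.cosine_similarity(s2, s1), abs=1e-12)
    assert cq.cosine_similarity(s1, s1) == pytest.approx(1.0, abs=1e-12)


def test_cosine_orthogonal_bands_near_zero():
    s1 = _spec(_band(240, 4, 1.0))
    s2 = _spec(_band(380, 4, 1.0))
    assert abs(cq.cosine_similarity(s1, s2)) < 1e-6


def test_cosine_rejects_all_zero():
    with pytest.raises(ValueError):
        cq.cosine_similarity(_spec(np.zeros(30)), _spec(np.ones(30)))


def test_cosine_requires_sufficient_overlap():
    s1 = _spec(np.ones(30), start=220.0)
    s2 = _spec(np.ones(30), start=248.0)  # only 2 nm overlap
    with pytest.raises(ValueError):
        cq.cosine_similarity(s1, s2)


# --- derivative spectra ------------------------------------------------------


def test_derivative_of_constant_and_ramp():
    const = _spec(np.full(40, 2.5))
    np.testing.assert_allclose(cq.first_derivative(const).absorbance, 0.0, atol=1e-12)
    wl = np.arange(220.0, 260.0)
    ramp = cq.SpectrumUV(wavelength=wl, absorbance=0.3 * wl)
    np.testing.assert_allclose(cq.first_derivative(ramp).absorbance, 0.3, atol=1e-9)


def test_derivative_zero_crossing_at_band_center():
    s = _spec(_band(300, 20, 1.0))
    d = cq.first_derivative(s)
    sign = np.sign(d.absorbance)
    crossings = d.wavelength[:-1][np.diff(sign) < 0]
    assert np.any(np.abs(crossings - 300.0) <= 1.0)


def test_derivative_similarity_magnifies_differences(noiseless_config):
    """On the shipped band spectra, derivative similarity never exceeds raw
    similarity, and the most-similar cross pair is ondansetron-ramosetron
    on both indicators."""
    wl = noiseless_config.wavelength_grid
    specs = {
        a.name: cq.SpectrumUV(wavelength=wl, absorbance=a.spectrum_profile(wl), analyte=a.name)
        for a in noiseless_config.analytes
    }
    names = sorted(specs)
    raw, deriv = {}, {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            raw[(a, b)] = cq.cosine_similarity(specs[a], specs[b])
            deriv[(a, b)] = cq.cosine_similarity(
                cq.first_derivative(specs[a]), cq.first_derivative(specs[b])
            )
            assert deriv[(a, b)] <= raw[(a, b)], (a, b)
    top_raw = max(raw, key=raw.get)
    top_deriv = max(deriv, key=deriv.get)
    assert top_raw == ("ondansetron", "ramosetron")
    assert top_deriv == ("ondansetron", "ramosetron")
    # every cross pair sits below the identification thresholds
    assert max(raw.values()) < 0.99
    assert max(deriv.values()) < 0.90
    # the azasetron/ramosetron derivative similarity is far below threshold
    assert deriv[("azasetron", "ramosetron")] <= 0.5515


# --- relative retention time -------------------------------------------------


def test_rrt_reference_and_marker_anchors():
    assert cq.relative_retention_time(9.0, 9.0, 1.2) == 1.0
    assert cq.relative_retention_time(1.2, 9.0, 1.2) == 0.0


def test_rrt_reproduces_default_fixture_values():
    expected = {4.562: 0.431, 6.496: 0.679, 7.534: 0.812, 9.0: 1.0, 10.030: 1.132}
    for t_x, rrt in expected.items():
        assert round(cq.relative_retention_time(t_x, 9.0, 1.2), 3) == rrt


def test_rrt_rejects_reference_at_dead_time():
    with pytest.raises(ValueError):
        cq.relative_retention_time(5.0, 1.2, 1.2)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    a=st.floats(min_value=0.1, max_value=10.0),
    b=st.floats(min_value=-5.0, max_value=5.0),
)
def test_rrt_invariant_under_affine_time_transform(a, b):
    t_x, t_i, t_0 = 4.562, 9.0, 1.2
    orig = cq.relative_retention_time(t_x, t_i, t_0)
    mapped = cq.relative_retention_time(a * t_x + b, a * t_i + b, a * t_0 + b)
    assert mapped == pytest.approx(orig, rel=1e-9)


# --- combined decision rule --------------------------------------------------


def _fake_peak(apex):
    return PeakRecord(
        apex_time=apex, start_time=apex - 0.2, end_time=apex + 0.2,
        height=50.0, area=10.0, snr=100.0,
    )


def test_identify_round_trip_on_simulated_run(reference_library, standard_sample):
    """Every analyte peak of a noisy run is identified as itself."""
    cfg = cq.default_config(seed=21)
    run = cq.simulate_run(cfg, standard_sample)
    lib = reference_library
    for spec in cfg.analytes:
        truth = run.ground_truth[spec.name]
        trace = cq.correct_baseline(cq.extract_trace(run, spec.detection_wavelength))
        peak = min(cq.detect_peaks(trace), key=lambda p: abs(p.apex_time - truth.apex_time))
        spectrum = cq.extract_apex_spectrum(run, peak.apex_time)
        res = cq.identify_peak(peak, spectrum, lib["library"], t_i=lib["t_i"], t_0=lib["t_0"])
        assert res.candidate == spec.name
        assert res.identified, spec.name


def test_cross_spectrum_fails_spectral_indicator(reference_library, noiseless_config):
    """An azasetron spectrum presented at the ramosetron retention slot
    fails the derivative-similarity gate."""
    lib = reference_library
    wl = noiseless_config.wavelength_grid
    aza = noiseless_config.analyte("azasetron")
    spectrum = cq.SpectrumUV(wavelength=wl, absorbance=aza.spectrum_profile(wl))
    peak = _fake_peak(10.030)  # ramosetron's slot
    res = cq.identify_peak(
        peak, spectrum, lib["library"], t_i=lib["t_i"], t_0=lib["t_0"], deriv_sim_min=0.8
    )
    assert res.candidate == "ramosetron"
    assert res.rrt_pass
    assert not res.spectrum_pass
    assert not res.identified


def test_identify_rejects_empty_spectrum(reference_library):
    lib = reference_library
    zero = cq.SpectrumUV(wavelength=np.arange(220.0, 401.0), absorbance=np.zeros(181))
    with pytest.raises(ValueError):
        cq.identify_peak(_fake_peak(9.0), zero, lib["library"], t_i=lib["t_i"], t_0=lib["t_0"])


def test_ambiguous_rrt_window_uses_spectrum_tiebreak(reference_library, noiseless_config):
    """With a wide RRT window covering two candidates, the spectrum picks
    the right one and the result is flagged ambiguous."""
    lib = reference_library
    wl = noiseless_config.wavelength_grid
    onda = noiseless_config.analyte("ondansetron")
    spectrum = cq.SpectrumUV(wavelength=wl, absorbance=onda.spectrum_profile(wl))
    peak = _fake_peak(9.5)  # between ondansetron (9.0) and ramosetron (10.03)
    res = cq.identify_peak(
        peak, spectrum, lib["library"], t_i=lib["t_i"], t_0=lib["t_0"], rrt_tol_pct=10.0
    )
    assert res.ambiguous
    assert res.candidate == "ondansetron"
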