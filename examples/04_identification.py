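"""Double-indicator identification of the peaks in a noisy run.

A reference library (relative retention time + apex UV spectrum per
analyte) is built from a noiseless run of the same method; each peak of a
noisy test run is then identified only if BOTH indicators pass: RRT
within 5% of the library value, and raw / first-derivative spectral
cosine similarity above 0.99 / 0.90.  Derivative spectra magnify shape
differences, which is what separates the spectrally similar
ondansetron/ramosetron pair.
"""

import chromqams as cq

sample = {"azasetron": 20.0, "granisetron": 20.0, "tropisetron": 20.0,
          "ondansetron": 20.0, "ramosetron": 3.0}

config = cq.default_config(seed=7)

ref_run = cq.simulate_run(config.noiseless(), {k: 20.0 for k in sample})
t_0 = ref_run.ground_truth["dead_time_marker"].apex_time
t_i = ref_run.ground_truth["ondansetron"].apex_time
library = []
for spec in config.analytes:
    apex = ref_run.ground_truth[spec.name].apex_time
    s = cq.extract_apex_spectrum(ref_run, apex)
    s.analyte = spec.name
    library.append((spec.name, cq.relative_retention_time(apex, t_i, t_0), s))

run = cq.simulate_run(config, sample)
print(f"{'true analyte':<14} {'candidate':<14} {'RRT':>6} {'raw sim':>8} "
      f"{'deriv sim':>10} {'identified':>11}")
for spec in config.analytes:
    truth = run.ground_truth[spec.name]
    trace = cq.correct_baseline(cq.extract_trace(run, spec.detection_wavelength))
    peak = min(cq.detect_peaks(trace), key=lambda p: abs(p.apex_time - truth.apex_time))
    spectrum = cq.extract_apex_spectrum(run, peak.apex_time)
    res = cq.identify_peak(peak, spectrum, library, t_i=t_i, t_0=t_0)
    print(f"{spec.name:<14} {res.candidate:<14} {res.rrt:6.3f} "
          f"{res.raw_similarity:8.4f} {res.deriv_similarity:10.4f} {str(res.identified):>11}")
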