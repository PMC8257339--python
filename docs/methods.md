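# Methods

## The measurement model

The package treats an isocratic HPLC-DAD run as a time x wavelength
absorbance matrix. Each injected compound contributes one peak,

```
signal(t, w) = area * g(t) * s(w),
```

where `g(t)` is a unit-area Gaussian centred at the retention time
(optionally exponentially modified with tail constant `tau` to model
tailing), and `s(w)` is the compound's UV spectrum normalised to 1 at its
detection wavelength. The **area**, not the height, carries the
quantitative information: the detector response is modelled as the linear
law `area = slope * C + intercept` (mAU·min per µg/mL), because the
method's calibrations are area-based. On top of the peaks the simulator
adds a linear baseline drift shared by all wavelengths, i.i.d. Gaussian
detector noise per point, and a per-peak multiplicative area perturbation
representing injection/integration variability.

Quantification then proceeds two ways from the same integrated areas:

* **ESM** — invert each analyte's own line: `C = (A - b) / s`.
* **QAMS** — use one internal reference (ondansetron by default) and the
  relative correction factor `RCF_x = f_x/f_i = (A_x/C_x)/(A_i/C_i)`:
  `C_x = C_i / RCF_x * A_x / A_i`. Two RCF estimators are provided; the
  slope ratio `s_x/s_i` is canonical and used by the working equation,
  the per-level paired estimator is reported with its RSD% as a
  diagnostic of how far the responses deviate from proportionality.

### The intercept caveat (deliberate)

The QAMS working equation is intercept-free, but the configured
calibration lines are not, and the simulator keeps their intercepts on
purpose. The resulting bias factor for matched analyte/reference levels
is `[1 + b_x/(s_x C)] / [1 + b_i/(s_i C)]`; with the default response
constants it exceeds 15% for granisetron at 10 µg/mL and falls below 5%
for every analyte only at roughly 50 µg/mL and above. The implementation
does **not** correct this silently — the bias appears in quantification
reports and in the paired-levels RCF RSD — because hiding it would
misrepresent what a single-marker method can do near the bottom of the
calibrated range. Users quantifying low-level samples should rely on ESM
or re-anchor the reference at a comparable concentration.

## Identification

A peak is identified only when two independent indicators both pass:

* **RRT**, `(t_x - t_0)/(t_i - t_0)`, within 5% (relative) of the library
  value. `t_0` comes from an unretained marker peak; the correction makes
  RRT exactly invariant under affine time-axis transforms, which is the
  property that lets it transfer across instruments. The 5% default
  covers the worst observed cross-condition RRT variability (~4%) with
  margin while still separating the closest pair of library RRTs
  (1.000 vs 1.132, 13% apart).
* **Spectral similarity** of the baseline-subtracted apex spectrum
  against the library spectrum: angle cosine >= 0.99 on the raw spectrum
  and >= 0.90 on the Savitzky-Golay first derivative (window 7, order 2,
  with respect to wavelength, 220–400 nm at 1 nm). The derivative gate
  does the heavy lifting: on the shipped spectra the largest raw
  cross-similarity is 0.989 (granisetron–ondansetron region) while the
  largest derivative cross-similarity is 0.88 (ondansetron–ramosetron),
  so both thresholds sit between self- and cross-similarity.

When two library entries fall inside the RRT window the result is flagged
ambiguous and the spectrum breaks the tie.

## Signal processing conventions

* **Baseline**: asymmetric least squares (stiffness 1e8, asymmetry 1e-4,
  <= 20 reweighting iterations), recentred by the median residual of
  near-baseline points so the estimate tracks the noise mean rather than
  its lower envelope (without recentring, peak areas inherit a positive
  noise-dependent offset). A trace with fewer than 20% near-baseline
  points falls back to a flat baseline at the global minimum, with a
  warning.
* **Peak boundaries**: from each apex outwards to the first point below
  1% of the apex height, or the valley towards the adjacent peak,
  whichever comes first; areas by the trapezoid rule between boundaries.
  The 1% rule cuts 0.24% of a Gaussian's tails by construction, so
  integrated areas are systematically ~0.2–0.3% low; this cancels in
  ratios (RCF, RRT) and in recovery differences, and stays well inside
  the method's precision otherwise.
* **Detection floor**: local maxima above `min_snr` times a robust noise
  estimate (1.4826 * median |successive difference| / sqrt(2)), with a
  relative floor of 0.1% of the trace maximum so that noiseless traces do
  not sprout peaks from residual baseline curvature.
* **S/N** = peak height / (2 x sd of the blank-window signal) — the
  pharmacopoeial convention; it anchors LOD (S/N = 3) and LOQ (S/N = 10,
  with an optional replicate-RSD <= 10% constraint that, when inactive,
  leaves LOQ/LOD = 10/3 exactly). Height and area are linked through the
  Gaussian relation `height = area / (sigma * sqrt(2 pi))`.
* **Resolution**: the half-height-width convention
  `Rs = 1.18 (t2 - t1) / (w1 + w2)`, chosen over tangent constructions
  because half-height widths are robust to mild tailing.
* **Calibration**: OLS on level means (the conventional reading of
  replicate-injection designs that report one line per analyte); r is the
  Pearson correlation of the level means. 1/x and 1/x² weighting are
  available but off by default.
* Times are minutes, absorbances mAU, areas mAU·min; the time grid is
  treated as exact and never re-interpolated.

## Default method constants

Five analytes on a 15-min run sampled at 120 points/min, wavelength grid
220–400 nm at 1 nm:

| analyte | t_R (min) | sigma (min) | slope | intercept | detection (nm) |
|---|---|---|---|---|---|
| azasetron | 4.562 | 0.060 | 0.6321 | 1.3833 | 307 |
| granisetron | 6.496 | 0.080 | 0.6957 | 0.5444 | 302 |
| tropisetron | 7.534 | 0.090 | 1.0634 | 4.8592 | 285 |
| ondansetron | 9.000 | 0.100 | 1.8585 | 5.2914 | 307 |
| ramosetron | 10.030 | 0.110 | 2.3167 | 8.6551 | 307 |

The dead-time marker is an unretained uracil-like compound (t_0 = 1.20
min, single 258 nm band, injected at 20 µg/mL). Retention times are
chosen so the resulting RRTs are 0.431 / 0.679 / 0.812 / 1.000 / 1.132
and every adjacent pair is baseline-resolved (Rs > 2.4). Peak widths grow
with retention, as isocratic elution dictates. Calibration levels are
5, 10, 20, 50, 75, 100 µg/mL (0.5–50 µg/mL for ramosetron, the most
potent analyte), in triplicate.

Default noise: 0.2 mAU additive per point (which puts the LODs in the
0.1–0.4 µg/mL decade, the right order of magnitude for UV detection),
0.1 mAU/min drift, 1% per-peak area variability (typical
injection-to-injection scatter for a loop injector), all switchable off
via `RunConfig.noiseless()`.

### Synthetic UV spectra

True setron spectra are not available in machine-readable form, so each
analyte carries a synthetic two-band Gaussian spectrum, and these
fixtures are labelled as such. The bands were placed once so that the
similarity structure a DAD method relies on is respected: ondansetron and
ramosetron are the closest pair on both indicators (raw 0.987, derivative
0.881), every cross pair falls below the identification thresholds, and
derivative similarity never exceeds raw similarity on this set. Absolute
cross-similarity values are properties of the real chromophores and are
**not** reproduced — tests assert rank order and threshold separation
only.

## Validation campaigns

* **Precision**: n injections/day x d days; a shared multiplicative
  day factor (default sd 1%) creates the inter-day component, so
  interday RSD >= intraday RSD by construction when the day effect is on.
* **Recovery**: spike known amounts into an analysed base sample,
  `(measured_spiked - measured_base)/added * 100`, n >= 3, back-calculated
  through each analyte's calibration.
* **Stability**: RSD% of areas across a timed series (default 0–8 h),
  flagged above 2.0%. Note that a 5% linear loss over 8 h at the standard
  time points gives RSD 1.97% — a pure-RSD criterion is blunt against
  slow monotone drift, which is worth knowing when reading such tables.
* **Robustness**: each factor (flow ±0.02 mL/min, temperature ±1 °C,
  pH ±0.2, organic fraction ±2%) maps to a global time-axis/gain change
  plus small analyte-specific retention and response sensitivities
  (0.2–1.5%, signed per analyte). The global parts cancel exactly in RRT
  and RCF — that is the point of both ratios — so the reported RSDs
  measure only genuine selectivity changes. The mappings are declared
  configuration, not chromatographic theory: robustness output is a
  structural check of the invariances, not a prediction of a particular
  instrument. Reference-analyte rows are identically zero by
  construction.

All RSDs are 100·sd/mean with the (n−1) denominator.

## Problem sizes and determinism

The shipped studies use the design sizes stated above (3x3 precision,
n = 3 recoveries, 6-point stability, 3 levels per robustness factor); the
stochastic end-to-end check in the test suite quantifies 100 seeded
injections at 1% area noise and asserts the median per-analyte accuracy
stays within 98–102%. Simulation for quantification-only work uses a
4-wavelength grid (258/285/302/307 nm) instead of the full spectrum;
results are identical because peaks are integrated per detection channel.
Every random draw flows from an explicit integer seed, and identical
config + seed reproduces runs bit-for-bit.

## Known limitations

* No co-elution handling: the method, like the assay it implements,
  assumes baseline resolution; overlapping peaks only trigger a warning.
* The simulator does not model gradient elution, pump pulsation, detector
  nonlinearity or column chemistry; robustness sensitivities are
  declared, not derived.
* LOD/LOQ depend on the S/N convention chosen here; other conventions
  (e.g. 3.3·sd/slope) give different but order-compatible numbers.
* Passing tests on synthetic spectra demonstrate the decision logic, not
  the discriminating power of real setron spectra.
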