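# Methods

This note records the modelling assumptions, defaults and numerical choices
behind `uremiq`, and what the synthetic validation does and does not show
about real plasma spectra.

## Spectral model

Every resonance line is an absorption-mode Lorentzian; a multiplet's total
area is split over its lines by the first-order binomial ratios (1 singlet,
1:1 doublet, 1:2:1 triplet, 1:3:3:1 quartet). The strongly coupled two-spin
AB case (citric acid's CH₂ protons) is modelled exactly: with
`C = √(Δν² + J²)/2` the four lines sit at ±(C ± J/2) Hz from the pattern
centre with roofing weights `1 ± J/(2C)`. The library's default AB
parameters for citrate are J = 15.8 Hz, Δν = 30 Hz; both are editable
constants since the source spectra report only the pattern's centre
(2.94 ppm).

The simulator and the fitter deliberately share this lineshape — the method
under study *is* Lorentzian deconvolution — so the independent checks in
the test suite use a different route entirely (trapezoid integration of the
trace) to validate fitted areas.

Total multiplet area is `k·n·c` (response constant × proton count ×
in-tube concentration). The response `k` cancels in the TSP ratio, so its
value (default 1 intensity·ppm per proton·µM) only sets the intensity
scale of simulated spectra relative to the noise.

## Library defaults

Chemical shifts quoted from the source measurements at pH 2.5 are
normative: citrate AB 2.94; *p*-cresyl sulphate 2.33 (s, CH₃) with aromatic
doublets 7.19/7.27; hippurate triplets 7.54/7.62 and doublet 7.82. All
other shifts are compendium-typical values for acidified aqueous solution
and live in `data/metabolite_library.yml`, where a user can replace them
without touching code. Proton counts per quantifiable multiplet are fixed
in the library (quantification is impossible without them).

Protein-binding behaviour is encoded as two fractions per solute:
`free_fraction` (what a 10 kDa ultrafilter passes; 0 for hippuric acid and
*p*-cresyl sulphate, 1 otherwise) and `acetonitrile_recovery` (1 for
everything except citric acid, which the extraction loses entirely).
Perchloric-acid extraction is treated as fully recovering — its damage in
this pipeline is to spectral quality, not solute content.

Control reporting limits ("<5", "<30", "<50 µM") are stored as detection
thresholds; "not detected" entries are stored as absent. Creatinine's
control entry is a normal range (20–90 µM) rather than a limit; its upper
bound is stored as the threshold so "elevated vs control" comparisons are
conservative.

## Simulator

Acquisition defaults mirror a routine 500 MHz 1-D experiment: 6002 Hz
spectral width, 32 768 points, descending ppm axis centred on the water
position (4.7 ppm), 1.2 Hz linewidth. Noise is i.i.d. Gaussian per point
(default SD 200 intensity units, ≈0.8% of the height of a 10 µM singlet
proton); the baseline is a smooth random quadratic (default amplitude 100).
With the default TSP spike (603 µM in-tube) these settings put the
3.3σ detection limit in the low-µM range — e.g. ≈3.5 µM for hippurate's
2-proton doublet in the acetonitrile extract — so literature-normal control
levels of the strong binders sit at or below detection, as they should.

Patient concentrations are drawn per solute from a normal distribution
truncated at zero. The location parameter is solved (Brent's method) so the
*truncated* mean equals the configured cohort mean; without this the
reported mean would be overshot for strongly right-censored solutes
(hippurate's mean/SD of 134/111 µM shifts by +18% under naive truncation).
The SD shrinks slightly under truncation, which is tolerated. Dimethylamine
was reported from a single subject, so no spread is available; its cohort
SD is 0 and every simulated patient carries the same 17 µM. eGFR is uniform
on 14–36 ml/min/1.73 m² and independent of all concentrations — the null
hypothesis the correlation procedure is calibrated against.

PCA degradation defaults: noise ×3 and a seeded uniform global axis shift
of ±0.02 ppm. The broad protein hump of whole plasma is *not* simulated;
all simulated spectra are post-deproteinization, matching the pipeline's
scope (it never quantifies untreated plasma). No t₁-noise, phase error,
water-suppression artefacts or time-domain processing are modelled.
Passing tests therefore demonstrate correctness of the deconvolution,
calibration and statistics under these idealized conditions — not
robustness to phasing errors, lineshape distortions or unassigned
interferents in real spectra.

## Fitting

"Semi-automatic" fitting is realized as a reproducible prior: line
positions initialize at the library shifts and may move at most ±0.02 ppm;
linewidths are bounded to 0.2–10 Hz; within-multiplet area ratios are hard
constraints (a free-ratio diagnostic mode exists). Regions are built by
padding each multiplet's outermost lines by 0.06 ppm and merging anything
that touches, so overlapping multiplets from different solutes are fitted
jointly rather than winner-takes-all.

A polynomial baseline (order 1, in the centred coordinate) is fitted
*jointly* with the Lorentzians, initialized from 0.02 ppm flank strips at
the region edges. Pre-subtracting a flank-fitted baseline instead would
steal each peak's own tail and bias areas low by 1–2%; the joint fit keeps
noiseless round-trips exact to ~10⁻⁶ relative.

When a multiplet's rough (detrended) area in the region is below three
noise-equivalent areas, its centre and width are pinned to the library
prior and only the area is fitted: with no signal those parameters are
unidentifiable and letting them wander costs iterations without improving
the answer. The optimizer is trust-region least squares (lmfit /
`scipy.optimize.least_squares`), tolerances 10⁻⁸, capped at 500 iterations;
non-convergence flags the result rather than raising, so a survey run
always completes and reports.

Chemical-shift referencing finds the dominant maximum within ±0.2 ppm of
zero (requiring it to stand ≥10 robust-SDs above the window median) and
refines it by parabolic interpolation before translating the axis, so the
PCA global shift is undone to sub-gridpoint precision. Ascending input axes
are normalized to the descending NMR convention on construction.

## Quantification and detection

Concentrations are plasma-referenced: the tube-to-plasma dilution factors
are 1.0 (ultrafiltrate, measured neat), 700/500 (0.5 ml plasma resuspended
in 700 µl after acetonitrile drying) and 600/500 (100 µl acid into 500 µl
plasma). Whether the original study's table was plasma- or tube-referenced
is not stated; this package reports plasma-referenced values and says so.

A value counts as detected only above max(control reporting limit,
3.3 × noise-equivalent concentration), where the noise-equivalent area of a
multiplet is `noise_SD · (π/2) · fwhm · n_lines` (the area of lines whose
height equals the noise). Undetected values are excluded from cohort means,
never zero-imputed, mirroring per-solute detection counts. Merging follows
the complementarity rule: protein-bound solutes from the acetonitrile
extract, everything else from the ultrafiltrate, PCA never; a solute whose
source preparation is missing is reported as not quantified rather than
substituted from the other extract.

## Statistics

`C_u` is the arithmetic mean and SD the sample standard deviation (ddof 1)
over detected patients; `C_max = C_u + 2·SD`; `M/N = C_u / N`. Reporting
rounds concentrations to integer µM and M/N to one decimal, with internal
arithmetic unrounded — which is why a C_max recomputed from printed
(pre-rounded) inputs can differ by 1 µM from a published table value
(590 + 2×276 = 1142 vs a reported 1143). Such discrepancies are documented,
not adjusted away. Band boundaries: M/N > 10 high, 4–10 inclusive moderate,
< 4 low; solutes without a reference value, the single-subject detection
and creatinine are excluded from banding.

The Spearman p-value is exact for n ≤ 10: the full n! permutation null of
the rank correlation is enumerated (chunked, cached per rank
configuration; midranks handle ties), and the two-sided p is the share of
pairings with |r| at least the observed value. Larger samples fall back to
the t-approximation. Under the exact null at n = 10, |r| < 0.63 holds for
94.56% of pairings — the calibration the test suite checks by Monte Carlo.
The log-scale association is an OLS fit of ln(concentration) on eGFR
(statsmodels) reported with Pearson r and 95% confidence intervals.

## Problem sizes used in validation

The test suite and the acceptance script run the full pipeline at the
study's own scale — 10 patients and 4 controls, two usable preparations,
32K-point spectra — plus a 20-seed single-subject recovery sweep, a
1000-subject Monte-Carlo check of the cohort generator, and 200-cohort
null-calibration sweeps. These sizes make the whole suite complete in a
few minutes on one core while keeping every statistical check at the
sample size the procedure is actually used with.

## Known limitations

* Shifts are fixed per preparation; no pH- or matrix-dependent shift
  prediction, so real spectra with shifted resonances need a library edit.
* Only Lorentzian lines: no Voigt/Gaussian broadening, no phase errors.
* No unknown-peak discovery — the fit is strictly against the known panel.
* Detection frequencies of marginal solutes in real cohorts reflect
  inter-patient variance structure the generator does not know; it exposes
  per-solute means/SDs (and a degenerate SD for the single-subject case)
  but no richer presence model.
* JCAMP-DX import is not implemented; spectra enter as two-column text.
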