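# Methods

This note documents the models, numerical choices and limitations of
`nirscal`, in the spirit of a chemometrics methods section.

## Problem setting

Near-infrared reflectance spectroscopy (NIRS) predicts the digestible
energy (DE) and metabolizable energy (ME) content of feed corn for growing
pigs from log(1/R) absorbance spectra recorded on a 400–2498 nm grid at
2 nm steps (1050 points). Reference values come either from
digestion-metabolism balance trials (DE_D, ME_D, recovered by the direct
method at a 96.8 % corn inclusion rate) or from the Noblet–Perez
composition equations (DE_C, ME_C):

    DE (MJ/kg DM) = (4168 − 9.1·Ash + 1.9·CP + 3.9·EE − 3.6·NDF) × 4.18/1000
    ME (MJ/kg DM) = DE × (1.003 − 0.00021·CP)

with composition in g/kg dry matter (% DM × 10). The kcal→MJ factor is
4.18/1000 exactly as used with these equation constants, not 4.184.

## Spectral pre-treatment

Each candidate pre-treatment composes a scatter correction with a
gap-segment derivative coded `d,g,s1,s2` (derivative order, gap, and two
moving-average segment lengths, all in data points). The screening grid
crosses 7 scatter methods (None, SNVD, SNV, Detrend, SMSC, WMSC, IMSC)
with 11 derivative codes, 77 combinations.

Numerical choices:

* **Order of composition.** Scatter correction is applied before the
  derivative, matching common SNV-then-derivative practice; the
  treatments are listed elsewhere as "math + scatter" without a stated
  order, so this is declared as the package's contract.
* **Gap units.** All four code numbers are interpreted as data points
  (2 nm per point on the default grid).
* **Unnormalized differences.** Derivative differences are not divided by
  the gap width; only relative scale matters to a centred regression.
* **Edge handling.** Truncation, never padding; the retained wavelength
  sub-grid is carried with the spectra. A centred moving average of an
  even number of points is floor-centred.
* **Second smoothing** is applied after the derivative difference; every
  code in the standard grid has `s2 = 1`, so results on the standard grid
  are insensitive to this choice.
* **MSC variants.** The reference is the calibration-set mean spectrum.
  SMSC regresses each spectrum on the reference and maps it back;
  WMSC uses inverse-variance wavelength weights learned on the
  calibration set; IMSC regresses the reference on the spectrum and
  returns the fitted values. Exact commercial formulas for the weighted
  and inverse variants are proprietary, so these definitions are the
  package's contract. References are always refitted inside
  cross-validation training folds so no information leaks from held-out
  samples.
* Degenerate inputs (constant spectra under SNV, |slope| < 1e-12 under
  MSC) raise errors naming the offending rows.

## Modified partial least squares

MPLS is NIPALS PLS1 with one modification: after each extracted factor,
the X-residual columns and the y-residuals are divided by their current
standard deviations (denominator n−1; columns with SD < 1e-12 are left
unscaled) before the next factor is sought. All scalings are recorded, so
prediction replays an identical affine chain; an explicit coefficient
vector is recovered by back-propagating the weights through the
deflation/scaling chain. With standardization off the algorithm reduces
exactly to plain NIPALS PLS1 — this oracle mode is cross-checked in the
tests against both scikit-learn's PLSRegression and an independent
textbook NIPALS implementation (agreement ~1e-14 on random problems).
The exact residual moments used by commercial MPLS implementations are
not public; the per-column/per-response SD standardization implemented
here follows the published description of the Shenk–Westerhaus
modification and is stated as this package's definition.

Factor extraction stops early when the y residual no longer projects on X
(weight norm below 1e-12 of its initial value). The default search bound
is min(15, n/6) factors, which covers the 10–13 factors typically selected
on real corn data.

## Factor selection, outliers, grid search

* **Cross-validation.** The calibration set is split into 6 seeded random
  groups of near-equal size (the grouping method is not specified in the
  source protocol; seeded uniform assignment is used). SECV(p) pools
  held-out residuals over groups, √(Σe²/n); the optimal factor count
  minimises SECV, ties going to fewer factors. Setting the group count
  to n gives leave-one-out, verified against a brute-force oracle.
* **Spectral outliers.** GH_i = D²_i/p, the squared Mahalanobis distance
  of sample i's p-dimensional score vector under the calibration scores'
  mean and covariance (ddof 1), divided by p; the calibration average is
  ~(n−1)/n, and GH ≥ 10 flags a spectral outlier. A singular score
  covariance is ridge-stabilised with a warning.
* **Fit outliers.** T_i = |y_i − ŷ_i|/SEC with SEC = √(Σe²/(n−p−1));
  T strictly greater than 2.5 flags a sample. If SEC is exactly zero
  nothing is flagged.
* **Elimination loop.** H and T outliers are flagged jointly; at most two
  removal passes are executed, each followed by a full re-run of
  cross-validation and refit. Removing more than half the samples aborts
  with a diagnostic.
* **Grid search** runs this calibration for all 77 cells and ranks by
  SECV ascending, ties broken by higher cross-validation R², then fewer
  factors.

A property worth knowing: with unbounded Gaussian reference noise the
expected maximum of ~86 studentized residuals lies close to the T = 2.5
threshold, so the rule removes a borderline genuine sample in roughly
half of all runs — which is why calibrations on real data typically
report n of 85–87 out of 88. The implant-recovery tests therefore use a
bounded (uniform) noise background so that they probe the detector
rather than the tails of the noise.

## Evaluation statistics

SEC uses denominator n−p−1; SECV and SEP are uncorrected RMS errors
(√(Σe²/n)) — the validation RPDs of the reference tables reproduce from
printed SD/SEP only under this convention, and a bias-corrected SEP(C)
variant is out of scope. RSQ_cal is 1 − SSE/SST; cross-validation and
validation R² are squared Pearson correlations (the convention of the
originating software); RPD = SD/SECV (cross-validation) or SD/SEP
(validation), with 2.5 the conventional fitness bound for routine use.
SEL = √(Σ(a−b)²/2m) over m duplicate laboratory determinations and
RSEL = SEL/mean × 100. Report rounding is 2 decimals for ratios and 3
for standard errors.

## Synthetic data generator

No corn spectra were publicly deposited with the reference study, so the
generator emulates its study conditions: 117 samples, two subsample scans
each, the 1050-point grid, and per-constituent composition ranges, means
and SDs matching the published entire-set table (e.g. CP 7.80–11.00 % DM,
NDF 6.40–19.37 % DM).

* **Compositions** are drawn from a range-truncated multivariate normal.
  Constituents share a single latent "fibre quality" factor (loadings:
  NDF 0.9, ADF 0.8, ash 0.7, CP −0.7, EE −0.7, moisture 0), chosen so the
  emergent energy CV approaches the ~4.5 % reported for diverse corn
  collections; independent constituents would propagate to an
  implausibly narrow DE distribution (~0.49 MJ/kg SD).
* **Energies.** DE_C/ME_C are exact equation outputs for the tabulated
  composition. Determined values add a shared per-sample trial error
  (SD 0.15 MJ/kg DM — chosen so SD/SECV falls in the published 2.5–2.9
  RPD regime) plus a small independent urinary component (SD 0.04) for
  ME; ME is clipped to never exceed DE. Duplicate laboratory
  determinations are generated around the true composition with the
  published per-constituent SEL values so laboratory-precision statistics
  are testable.
* **Spectra.** Each scan is m·(baseline + Σ conc·band) + a + t·z + ε with
  2–3 Gaussian absorption bands per constituent in the 1400–2350 nm
  overtone/combination region, per-scan multiplicative scatter
  m ~ N(1, 0.05), additive offset (SD 0.02), baseline-tilt variation
  (SD 0.01) and white noise (SD 1e-3 absorbance). The band library is an
  invented fixture: centres sit in plausible NIR regions but amplitudes
  are set only so composition is recoverable at realistic
  signal-to-noise. Replicate scans share composition and differ in
  scatter and noise.

**What passing tests do and do not show.** The generator reproduces the
qualitative features that motivate the pre-treatment grid — baseline
shifts, parallel scatter offsets, band overlap, replicate-scan noise —
and the published reference-value distributions. It does not simulate
radiative transfer, instrument line shape, particle-size physics,
moisture–band interactions, or in-vivo digestibility variation beyond
what the composition equations encode (which also caps the synthetic DE
SD at ~0.65 MJ/kg versus the 0.75 observed in vivo). End-to-end recovery
on this simulator demonstrates that the pipeline's machinery is correct
and well-calibrated, not that real corn spectra attain any particular
accuracy.

## Problem sizes used in the shipped experiments

The end-to-end recovery experiment runs five 117-sample datasets at full
spectral resolution through a 20-cell screening subset of the grid (4
scatter methods × 5 derivative codes) with an 88/29 split; the full
77-cell grid is exercised by its own census and by unit tests on shorter
grids. Implant-recovery uses 88 samples on a 60-point grid over 10 seeds.

## Known limitations

* WMSC/IMSC and the MPLS residual scaling are declared contracts, not
  bit-reproductions of proprietary software.
* SEP carries no bias correction; repeatability-file bias/slope
  adjustment and calibration transfer between instruments are out of
  scope.
* The reported R²cv/RPD_cv of a grid winner are selection-biased upward
  (winner of 20–77 candidates) and SECV is computed on outlier-trimmed
  survivors; held-out validation statistics are the honest measure, and
  both are always reported.
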