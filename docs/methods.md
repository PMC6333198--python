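# Methods

## Model

The package treats OSLD dosimetry as a strictly multiplicative measurement
model: absorbed dose to water is the product of a corrected mean signal, a
protocol-specific calibration coefficient, and five correction factors
(linearity, fading, irradiation geometry, angle, beam quality). Everything
downstream — calibration, dose computation, uncertainty — follows from two
assumptions: (i) the factors are mutually independent, with correlations
confined to the repeated reads of a single dosimeter inside `M̄_corr`; and
(ii) each factor is adequately summarised by its first two moments. Under
(i)–(ii) the variance of the dose is *exact*, not a linearisation:
`var(XY) = var(X)var(Y) + var(X)E(Y)² + var(Y)E(X)²` for independent
factors, folded recursively over the chain (the fold order is irrelevant;
a test asserts this), and `var(X+Y) = var(X) + var(Y) + 2cov(X,Y)` for
correlated sums. The cross term `var(X)var(Y)` is what plain quadrature
omits; it is fourth-order in the relative spreads, so totals sit slightly
above the root-sum-square — strictly above whenever two components are both
uncertain (property-tested).

## Signal correction

Each optical readout depletes the trapped charge; the depletion model stores
the physical per-read loss (default 0.016) and, by default, *restores* later
reads upward by `c_d^(j−1) = (1 − loss)^−(j−1)` so the mean of J reads is a
first-read-equivalent signal — the convention a calibration against a known
dose requires. The raw-retention convention (scaling read 1's equivalent
*down*) is available as a toggle. Element sensitivity multiplies the
depletion-corrected mean; background (default 0, as no value is measured in
the supported workflows) is subtracted last. The variance of a single
sequence is the unbiased sample variance of the corrected reads over J; a
single read falls back to a configured reader-noise model (0.8% relative at
2σ). Pooling over dosimeters uses the plug-in (population) variance of the
mean for the between-dosimeter term plus the averaged within-dosimeter
variances, both over n.

For repeated reads of one dosimeter the correlation model is a shared latent
true signal plus independent read noise, giving
`var(mean_J) = (var/J)(1 + (J−1)ρ)`; full correlation removes the 1/J gain,
as it must.

## Calibration protocols

* **Vendor.** Dose is regressed on signal through the origin across the
  non-zero standard levels (weights ∝ 1/dose², appropriate for constant
  relative dose uncertainty), then multiplied by the batch-sensitivity
  adjustment (experimental over calibration batch mean, 0.93/0.85 = 1.094
  for the reference batches). The delivered-dose uncertainty (5%, 2σ) is
  systematic across levels — one irradiator — so it does not average down
  with the number of levels; only the reading noise does. A per-level mode
  returns one coefficient per standard instead of a fit.
* **Free-in-air CT.** Pooled chamber dose over pooled OSLD signal. Chamber
  readings are converted by `q·P_TP·P_elec·N_k·(μ̄_en/ρ)` with reference
  conditions defaulting to 22 °C / 101.33 kPa (ADCL convention) and the
  water/air mass energy-absorption ratio a required, visible config value
  (default 1.06 for diagnostic qualities — deliberately not buried in code).
  Repeated chamber readings share the calibration chain, so the pooled dose
  keeps a single reading's systematic relative uncertainty (default 5%, 2σ,
  treated as 2σ to match the package's uniform 2σ reporting).
* **Megavoltage (⁶⁰Co).** Delivered dose from the source's decay-corrected
  dose rate (half-life 1925.28 d, configurable) times beam-on time, with a
  0.9% (2σ) reference-dosimetry uncertainty; coefficient = dose over the
  pooled signal of the standards.

Coefficient variances use the quotient form of the product identity: the
inverse signal carries the signal's relative variance (exact to second order
in spreads well below 1%, far finer than anything quoted here).

## Correction factors

Under the supported conventions (dosimeters flat in the bore, no
differential fading, linear dose range) k_L = k_F = k_θ = 1 exactly; k_G is
1 for CT-based protocols and 1.03 for megavoltage calibration (static
en-face standards vs rotating delivery). All of the energy dependence rides
on k_Q, tabulated per protocol in versioned YAML: an 11-node mean-spectral-
energy axis (linear interpolation between nodes, hard error outside the
[45.4, 64.9] keV span — the response is too non-linear to extrapolate) and a
clinical (kVp × position) grid. The shipped values are specific to a GE
Discovery CT750 HD with medium bowtie; scanners with softer spectra need
their own tables, which is why no physics value is hard-coded. One adjacent
node pair in the CT energy column (58.1 → 58.7 keV) inverts by a single
least digit in the published data; the loaded-data monotonicity test
tolerates exactly that one inversion rather than "correcting" it.

k_Q uncertainty magnitudes are not published for these tables. The shipped
defaults (12.4% vendor, 6.3% CT, 8.2% megavoltage, plus 1.0% on k_G for
megavoltage, all 2σ) are calibrated so the propagated total dose uncertainty
reproduces the protocols' reported overall precision (≈13.5%, 8.3%, 8.5% at
2σ); they are configuration to be replaced when protocol-specific estimates
exist, and the test suite treats totals only via structural properties
(total > quadrature; Monte Carlo agreement), not as fixed numbers.

## Synthetic data

The generator builds one internally consistent truth: a corrected-signal
level per condition, `S(c) = D(c)/(N_CT · k_Q,CT(c))`, with k_Q,CT seeded
from the energy table, measured doses taken from the packaged 11-condition
reference set (25–40 mGy), and the other protocols' true coefficients and
beam-quality factors derived from the same response so each protocol chain
maps S(c) back to D(c) exactly. The one free parameter is the vendor
coefficient relative to the CT one (default 0.66, anchored at the softest
measured spectrum); with it, applying the vendor's constant 1.19 energy
correction under-corrects by amounts growing with energy — the documented
failure mode of that protocol — while the matched-k_Q paths round-trip to
machine precision at zero noise.

Stochastic components, all multiplicative lognormal by default (signals are
positive and uncertainties are quoted relatively; a Gaussian switch exists):
per-read noise 0.4% (1σ); element-sensitivity *assignment* error 0.5% (1σ —
the 1.0% 2σ component of the corrected-signal budget), distinct from the 5%
(1σ) manufacturing spread of true sensitivities that the per-dosimeter
correction removes; a per-session systematic delivered-dose error at each
protocol's reference uncertainty; 0.3% chamber repeatability; and ambient
temperature/pressure variation over 20–24 °C and 99–103 kPa. Raw counts are
generated as `S · (s̄_exp/s̄_batch) / k_s,i · (1−d)^(j−1) · noise`, so the
depletion restoration, the sensitivity multiplication and the vendor batch
adjustment each exactly invert their generating term.

What the generator does **not** emulate: reader drift between sessions,
dose-nonlinearity and fading (k_L, k_F ≠ 1 scenarios), angular response,
scanner-to-scanner spectral differences, or any photon transport — mean
spectral energies are inputs. Passing tests therefore validate the
*estimators and the propagation*, not the shipped k_Q physics.

## Statistical verification sizes

Parameter recovery uses 200 seeded calibration sessions per protocol
(coefficient bias bound 0.5%; empirical/propagated spread ratio within 15%)
and interval coverage uses 1000 replicates of the full
calibration-measurement-dose pipeline (nominal 95% intervals must cover in
93–97%), sizes at which the binomial and χ² sampling bands comfortably
contain the nominal values. The Monte Carlo oracle defaults to 10⁶ samples
and agrees with the analytic variances within 3 standard errors of the
sample variance (computed from the fourth central moment, no normality
assumed); the oracle is deterministic given its seed.

## Numerical choices and edge cases

All uncertainties are carried internally as absolute variances; interfaces
quote relative 2σ percentages. Non-positive corrected signals raise a
dedicated non-physical-signal error; empty read lists, negative backgrounds,
Cauchy–Schwarz-violating covariances, unknown protocols and missing table
keys all fail loudly with the available keys listed. Table lookups never
extrapolate. Display rounding is one decimal for mGy and percent values;
full precision is kept internally.

## Known limitations

* The published percent-difference table is not exactly reproducible from
  its own rounded dose columns: one vendor-column entry (condition 2) was
  evidently computed from unrounded doses (or referenced to the OSLD dose)
  and recomputes to 5.34 rather than the printed 5.6, moving the recomputed
  vendor column average to 15.39. The package reports the recomputed values.
* The CT-protocol coefficient uncertainty is reproduced from its configured
  components (5% ⊕ 1.3% → 5.2% at 2σ); the published 5.3% evidently includes
  an additional, un-itemised component which is not guessed here.
* The exact-moment propagation is exact for independent products and
  correlated sums, but quoting ±2σ as "95%" still invokes an approximately
  symmetric dose distribution; at the relative spreads involved (≤ ~7% σ)
  the coverage tests show this is adequate.
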