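# Methods

This note records the models, defaults and numerical choices behind
`gdose`, and what the packaged synthetic study does and does not show.

## Dose quantity and conversion coefficients

The target quantity is ambient dose equivalent rate H\*(10), the
operational area-monitoring quantity for penetrating photon fields.  The
packaged fluence-to-dose table (`gdose/data/h10_conversion_coefficients.csv`)
holds the ICRP Publication 74 / ICRU Report 57 coefficients h\*(10)/Φ in
pSv·cm² at 24 energies from 10 keV to 10 MeV; it is log-log interpolated
(exact at knots, no extrapolation) and user-replaceable via `--h-table`.
Internally dose rates are pSv/s; reported values are µSv/h (factor
3.6 × 10⁻³).

## Detector response model

The simulator stands in for full Monte Carlo photon transport and is
deliberately minimal; the conversion method consumes *any* response matrix,
so only the qualitative angular and energy behaviour matters.

For a bare NaI(Tl) cylinder (default 5.08 × 5.08 cm, 3.6 g/cm³) under a
parallel beam at incidence angle α from the axis:

* interception: the beam sees the silhouette `A(α) = πr²cosα + dh·sinα`
  (20.27 cm² end-on, 25.81 cm² side-on, max 32.6 cm² near 52°);
* interaction probability: `1 − exp(−μ_tot·ℓ̄)` with mean chord
  `ℓ̄ = V/A(α)` and μ from a packaged table of NaI photoelectric,
  incoherent and pair-production coefficients (approximate smooth XCOM
  representation, 40–4000 keV, log-log interpolated; coherent scattering
  omitted);
* energy deposition: photoelectric and pair events deposit the full
  energy in the channel containing E₀.  Compton events deposit the
  Klein–Nishina recoil-electron spectrum on [0, Compton edge]; per
  deposited energy T, the scattered photon (energy E₀ − T) escapes with
  probability `exp(−μ(E₀−T)·ℓ̄/2)`, otherwise the event is promoted to the
  full-energy peak.  This one-parameter-free reabsorption step is what
  makes the high-energy response volume- rather than area-dominated, as in
  real scintillators; without it the peak fraction collapses to a few
  percent above 1 MeV and no smooth low-order G(E) exists.

Escape peaks, coherent scattering, housing/reflector transport, the
photomultiplier backing plate (available only as an optional flat
low-energy pedestal, off by default) and electronics effects are not
modelled.  Consequences: the angular spread of the response above a few
hundred keV (10–20 % between 0° and 45°) is larger than for a real
assembly, and spectral shapes between the Compton edge and the peak are
empty.  Columns are normalised per unit fluence (cm²) and can never exceed
the projected area.

Isotropic irradiation uses the mirror and rotational symmetry of the bare
cylinder: a sin(α)-weighted Gauss–Legendre average over α ∈ [0°, 90°],
16 nodes by default (doubling the nodes changes entries at the 10⁻¹⁵
level, as the integrand is smooth).

Gaussian energy broadening applies, per channel at energy E, a Gaussian
with `σ = FWHM/2.36` and `FWHM = a + b√(E + cE²)`; defaults a = 1 keV,
b = 1.8 keV^½, c = 0 (≈7 % resolution at 662 keV, typical NaI(Tl)).  The
factor 2.36 (not 2.3548) is kept as the conventional rounded value.  Each
discrete kernel is normalised over the grid, so column sums are conserved
to floating point.

The pulse-height grid is 869 linear channels over 0–3100 keV.  The channel
count follows the study design; the calibration range (linear, 0–3100 keV)
is a package choice, flagged in the configuration.

## G(E) calibration

`G(E) = Σ_{K=1..7} A(K)(log₁₀E)^(K−1)` (Kmax = 7, M = 0; the log base is a
package convention — the classical G(E) literature uses decadic logs — and
is switchable to natural logs).  A is found by minimising the mean squared
*relative* error of the predicted dose coefficients at 30 log-spaced
calibration energies in 50–3000 keV, so keV- and MeV-range coefficients
(an order of magnitude apart) contribute comparably.

The optimizer is gradient descent with backtracking step-halving, zero
initialisation, stop at relative loss change < 10⁻¹⁰ or 10⁵ iterations.
Because the log-power basis is severely collinear, the descent runs in a
QR-whitened coordinate system; the whitening is an exactly invertible
linear map, so the reported A reproduce the fitted function identically
(verified against closed-form least squares in the tests).

G is defined as zero below a support threshold, by default half the lowest
calibration energy (25 keV).  Placing the threshold *at* the lowest
calibration energy truncates that column's broadened full-energy peak and
degrades the fit several-fold; in practice the threshold plays the role of
the detection threshold of the instrument.

Achieved calibration quality with the default simulator and the ICRP 74
table: 1.3–2.1 % RMS relative error across the four geometries.  This is
the least-squares optimum of the 7-term basis for this operator (an eighth
term would reach ~0.75 %), and it is sufficient for the validation below:
the matched-geometry energy response stays within a few percent of unity.

## Gaussian-process model

The four fitted G(E) functions, evaluated at every 8th channel inside the
support (≈100 points per geometry), form the training set over
x = log₁₀(E/keV).  Outputs are standardised (zero mean, unit variance)
so the zero-mean GP prior is adequate despite G spanning two orders of
magnitude.  The kernel is RBF; hyperparameters (lengthscale, signal
variance, noise variance) maximise the log marginal likelihood by
multi-start L-BFGS-B over log-parameters (8 seeded starts; bounds
ℓ ∈ [0.02, 3] log₁₀-keV, σ_f² ∈ [10⁻³, 10³], σ_ε² ∈ [10⁻⁸, 10]).
On the default study the fit lands at ℓ ≈ 0.73, σ_f² ≈ 2.1, σ_ε² ≈ 0.003.

The noise term σ_ε² is not counting noise — the training data are
noise-free model evaluations.  It absorbs the *disagreement between
geometry-specific G functions*, which is exactly the uncertainty the
method propagates.  Because that disagreement is a smooth function of
energy (a geometry change shifts G coherently across neighbouring
channels, and only coherent deviations survive the spectrum sum), the
pipeline draws realizations from

    N(mean, posterior covariance + σ_ε² · C)

where C is the kernel correlation matrix on the query grid
(`noise="correlated"`).  Latent-only (`"none"`) and white-noise (`"iid"`)
sampling are available; white noise averages out in the channel sum and
understates the dose uncertainty, while the latent posterior alone
collapses where training data are dense.  Confidence bands are analytic,
mean ± 1.96 SD, optionally including σ_ε; empirical percentiles are
available for diagnostics.

Factorisations use Cholesky with a relative jitter of 10⁻¹⁰, escalating
×10 up to 10⁻⁶ before failing; sampling uses an eigen square root so the
exactly-singular case (zero covariance) degrades gracefully.  Negative G
values in realization tails at low energy are kept — clamping would bias
the mean — and a warning is logged if they exceed 1 % of values.

## Validation design and what it shows

The packaged study simulates noise-free mono-energetic spectra at 21 test
energies (20 log-spaced in 50–3000 keV plus 662 keV) under all four
geometries, at unit fluence rate.  For each case it reports the 0°-G(E)
point estimate, the dose distribution over 100 realizations, and the
energy response — the estimate/truth ratio normalised at 662 keV
(Cs-137), per estimator and geometry.

Measured on the default configuration (seed 1; deterministic across seeds
to the digits shown):

* matched geometry (0° spectra, 0° G): energy response within
  [0.99, 1.04] over the whole test range;
* mismatched geometry: the conventional 0° estimate overestimates a
  70 keV / 45° field by ≈58 % (the projected-area ratio at near-total
  absorption is 1.607), while the GP mean cuts the excess roughly in half
  and its interval brackets both truth and the conservative estimate;
* coverage: the 1.96-SD interval contains the truth in 99 % and both the
  truth and the 0° estimate in 95 % of the 84 cases;
* the relative band width grows sharply below 200 keV while the absolute
  width is within an order of magnitude across the range.

Because the spectra are noise-free and the responses come from the
simplified transport model, these numbers validate the *machinery* —
calibration, pooling, sampling, interval construction — not the absolute
accuracy of any physical instrument.  Counting statistics are deliberately
not propagated (the reported uncertainty is conversion-operator
uncertainty only); Poisson noise can be added to simulated spectra for
end-to-end exercises.

## Known limitations

* The transport model's high-energy angular spread exceeds a real
  detector assembly's, so the pooled GP band at high energy is wider in
  relative terms than a calibrated instrument would warrant, and a few
  extreme 0° training points sit just outside the noise-inclusive 95 %
  band (≈91 % of points are inside).
* Kmax = 7 leaves 1–2 % RMS calibration residual under this operator;
  users fitting their own (e.g. Monte Carlo) response matrices can pass a
  different `FitOptions.kmax`.
* Only H\*(10) is wired in; any other energy-indexed dosimetric quantity
  can be used by substituting the coefficient table.
* The GP is stationary in log-energy with homoscedastic noise; the
  geometry disagreement is actually energy-dependent, so the band is
  conservative at intermediate energies and tight at the extremes.
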