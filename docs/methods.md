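# Methods

## The measure

A standardized density p(x) is expanded in the orthonormal Hermite
functions H_i (physicists' Hermite polynomials under a Gaussian envelope,
normalized so the basis is orthonormal on the real line).  Order 0 is
itself a Gaussian, so the coefficient a_0 = ∫ H_0 p carries the Gaussian
part of p and the higher coefficients carry the rest.  Non-Gaussianity is
scored as the truncated relative power outside order 0:

    J_n = 1 − a_0² / Σ_{i≤n} a_i²,  a_i estimated as (1/N) Σ_j H_i(x_j).

J_n is 0 exactly for the standard normal (which is proportional to H_0)
and only for it; it is bounded by 1.  The full infinite sum diverges for
empirical (discrete) distributions, so truncation is not merely a
numerical convenience — it is what makes the estimator well defined, and
it acts as regularization of the density shape.

Key properties the implementation relies on:

* **Affine invariance.** Samples are standardized (mean 0, SD 1) before
  coefficients are estimated, so J_n is invariant to location, scale, and
  sign of the data.
* **Parity.** Odd-order coefficients of a symmetric density vanish, so
  odd-only variants of J_n are blind to symmetric non-Gaussianity; the
  all-orders and even-orders variants coincide there.
* **Linear coefficient estimator.** â_i is a sample mean of a bounded
  function (|H_i| ≤ ~0.8), so single outliers move J_n by O(1/N), unlike
  moment-based statistics.

## Numerical choices

* Hermite functions are evaluated with the three-term recurrence on the
  *normalized* functions, H_{k+1} = x√(2/(k+1)) H_k − √(k/(k+1)) H_{k−1},
  seeded by H_0 = π^(−1/4) e^(−x²/2).  The factorial formula overflows
  near order 60 and is retained only as a test oracle (checked to 1e−10
  for n ≤ 15; Gram matrix of H_0..H_30 equals the identity to 1e−8 under
  Gauss–Hermite quadrature).
* Standardization uses the population (1/N) variance convention, matching
  the 1/N average in the coefficient estimator; the difference from
  1/(N−1) is O(1/N) and immaterial at benchmark sizes.
* Analytic coefficients use adaptive quadrature (absolute tolerance
  1e−12) on the density's support clipped to |x| ≤ 30: the Gaussian
  envelope of the basis makes every integrand numerically zero beyond
  that, regardless of the density's tails.  Raw density *moments*, by
  contrast, are integrated over the full support with infinite limits —
  heavy-tailed members (e.g. the extreme-value family with positive
  shape) lose third-moment mass if clipped.
* If the truncated coefficient power is numerically zero (< 1e−300) the
  measure is undefined and an error is raised rather than returning 0.

## Distribution families

Three 1D families probe distinct departures from normality:

* Two-component Gaussian mixture (weight α): Gaussian at α ∈ {0, 1},
  bimodal between.  Benchmark members: balanced ±2 modes (symmetric) and
  a 0.7/0.3 mixture of N(−2,1) and N(2,0.4) (asymmetric).
* Generalized normal C(β) e^(−|x|^β/2): Gaussian at β = 2, leptokurtic
  below, platykurtic above.  The normalizing constant
  C(β) = β / (2^{1+1/β} Γ(1/β)) is derived from the normalization
  integral and verified against quadrature.  Sampling uses the gamma
  transform |X|^β/2 ~ Gamma(1/β).
* Generalized extreme value (unit location/scale, shape κ): Gumbel at
  κ = 0; skewness changes sign near κ = −0.28 (located by root-finding on
  quadrature moments).  Sampling is by inverse CDF.

Multivariate benchmark datasets are product distributions: one
analytically standardized non-Gaussian axis, the rest i.i.d. standard
normal, optionally mixed by a seeded random orthogonal matrix (default:
rotated in 5D, unrotated in 2D where the search is over angles anyway).

## Search procedures

* **2D**: exhaustive sweep of the half circle at 1°, refined to 0.1°
  around the best angle.  Accuracy is the location of the peak of the
  across-replicate mean score curve; precision is the angular distance
  from the peak at which the mean ± 2 SD bands first separate.
* **d ≥ 3**: data are whitened; the FastICA contrasts use the standard
  one-unit fixed-point update with deflation (orthogonalization against
  accepted components); J_n, which is not amenable to the fixed-point
  step, uses projected gradient ascent on the unit sphere with learning
  rate η_t = η₀/(1 + t/τ) (defaults η₀ = 0.5, τ = 50, ≤ 500 iterations,
  stop when the direction moves < 1e−4 rad).  The gradient is analytic,
  via dH_k/dx = √(k/2) H_{k−1} − √((k+1)/2) H_{k+1}, including the
  dependence of the projection's standardization on the direction;
  it is verified against central finite differences.  Searches restart
  from seeded uniform random directions (default 25) and keep the best
  score; ties keep the earliest restart.
* **Cross-contrast selection**: each contrast finally picks its best
  direction among the candidates found by *all* contrasts, so algorithmic
  differences in search do not masquerade as contrast differences.
* FastICA functionals are scored as |E[g] − E_gauss[g]| (the log-cosh and
  Gaussian nonlinearities are non-monotone around their Gaussian
  expectation); normality tests are compared by their statistics oriented
  so larger = less normal (Shapiro–Wilk as 1 − W), then curve-normalized
  per panel so the maximum of each method's mean is 1.

## Error and dispersion metrics

Error is the angle between estimated and true unmixing directions,
acos(|u·v|), which ignores the inherent sign ambiguity.  Dispersion over
replicates is the angular variance 1 − ‖mean vector‖ after aligning each
member's sign with a reference.  The 2D truncation-order study searches a
uniform 0.1° grid over a ±10° window around the true axis (a denser patch
near the axis would bias the argmax of signal-free variants toward the
truth); dispersion of the estimates is reported as the circular variance
after rescaling the window to the full circle, so window-uniform scatter
scores ~1 and estimates pinned at the axis score ~0.  One caveat is
documented in the validation suite: for a variant that carries *no*
signal (odd orders on a symmetric source), the argmax of the smoothly
varying score accumulates at the window edges rather than scattering
uniformly, so its window circular variance saturates near 0.5, not 1 —
the variant's uselessness shows up instead as errors at window-uniform
level, an order of magnitude above the all-orders variant.  Two axial
helpers (`axial_circular_variance`, doubled-angle convention) are provided
for dispersion of unrestricted 2D axis estimates.

## Synthetic EEG generator

The generator is a deliberately simplified surrogate for a biophysical
head-model simulator.  It reproduces the statistical structure an ICA
artifact extractor exploits and nothing more:

* background sources: unit-RMS Gaussian processes low-passed below 40 Hz,
  mixed through smooth random scalp topographies (Gaussian blobs on a
  deterministic sunflower channel layout, plus a small rough component to
  avoid rank collapse);
* two ocular sources: Poisson-timed raised-cosine-squared pulses (300 ms,
  default rate 0.25 Hz, peak amplitude 10× background RMS, amplitude
  jitter), with fixed left/right frontal topographies.  The two eyes'
  events are kept temporally non-overlapping: correlated artifact time
  courses would make the per-eye directions unidentifiable for ICA in
  short segments, defeating the benchmark's premise that each eye's
  ground-truth direction is recoverable.  Real blinks are largely
  binocular, so this is a stated idealization;
* additive white sensor noise (default 0.1 RMS).

Every short segment is guaranteed at least one blink per eye.  Because
there is no volume conduction, no event-related structure, and no
realistic spectral content, passing results show that the pipeline
recovers spatially fixed heavy-tailed sources from linear mixtures — not
that it would perform identically on real recordings.

The recovery pipeline retains the top principal components (>99% of
variance at default generator settings), whitens, extracts components by
deflation, and matches each eye's ground-truth direction to the extracted
component with maximal |cosine| — an automated stand-in for visual
component inspection, possible here because the ground truth is known.

A caveat surfaced by the noiseless two-artifact toy: with two *extremely*
sparse sources and no noise, the empirical J_n can be slightly larger at
a blend of the two sources than at either source alone — J_n measures
deviation from normality, not statistical independence, and maximal
non-Gaussianity need not coincide with an independent source.  At
realistic noise levels and durations the blink directions are recovered
to a few degrees.

## Benchmark scales

Replicate counts default to desk scale and are configuration, not code:
the 1D sensitivity curves default to 100 runs per condition (study scale:
1,000); the truncation-order study in the validation suite uses 20
replicates per family at N = 10³ and 10⁴ with 1,000-replicate bootstrap
CIs; 2D recovery uses 10 replicates at N = 10⁴; the 5D benchmark uses 30
replicates at N = 10³ and 10 at N = 10⁴ with 10 restarts (medians and
win-rates were checked to match 25 restarts / 500 iterations); the EEG
suite uses 16 channels, 6–30 s segments, 5 seeds, 6 extracted components.
All runners derive per-task seeds from a master seed via seed sequences,
so tables reproduce bit for bit.

## Known limitations

* J_n has no analytic null distribution here; it is compared via
  normalized statistics, not calibrated p-values (a Monte-Carlo
  calibration can be built from the samplers if needed).
* The deflationary search extracts components one at a time; the measure
  is not applicable as-is to simultaneous-extraction ICA.
* The truncation-order study's dispersion convention (axial, doubled
  angles, half-circle search) is one defensible formalization of
  direction dispersion for 2D axial data; window-restricted alternatives
  bound the dispersion of uninformative variants away from 1.
* The EEG surrogate omits head-model realism (see above); absolute error
  levels there are not comparable to simulator- or data-based studies.
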