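# hermica

Hermite-function measure of non-Gaussianity for normality testing and
deflationary independent component analysis (ICA), with seeded simulation
benchmarks including a synthetic-EEG ocular-artifact recovery pipeline.

## The problem

Neural data analysis leans on measures of non-Gaussianity in two distinct
ways: as *normality tests* (is this distribution close enough to Gaussian
to justify model assumptions?) and as *ICA contrast functions* (which 1D
projection of a multichannel recording is the most non-Gaussian, and
therefore the most source-like?). Moment-based statistics are sensitive to
outliers; CDF-based statistics can overlook structure near the mode;
entropy proxies are hard to estimate from limited data.

`hermica` implements an alternative that approximates the *shape* of the
distribution directly. The orthonormal Hermite functions

    H_n(x) = (2^n n! sqrt(pi))^(-1/2) e^(-x^2/2) h_n(x),
    ∫ H_m(x) H_n(x) dx = δ_mn,

(`h_n` the physicists' Hermite polynomials) have a Gaussian as their
order-0 member, so the expansion coefficients of a standardized density
p(x),

    a_i = ∫ H_i(x) p(x) dx,   estimated from samples as  â_i = (1/N) Σ_j H_i(x_j),

split p into a Gaussian part (a_0) and a non-Gaussian remainder.  The
measure of non-Gaussianity is the truncated relative power outside order 0:

    J_n = 1 − a_0² / Σ_{i=0}^{n} a_i²,

which is 0 exactly for the standard normal and approaches 1 as the
Gaussian share vanishes.  The coefficient estimator is linear in the data
— robust to outliers — and the truncation (default n = 15) acts as a
regularizer.  The package provides:

- `hermite` — stable basis evaluation, analytic (quadrature) and sample
  coefficients, J_n with all/even/odd order-subset variants;
- `distributions` — three 1D test families (Gaussian mixtures,
  generalized normal, generalized extreme value) with densities, seeded
  samplers, and product-distribution dataset builders with known
  ground-truth mixing;
- `contrasts` — the three classic FastICA contrast functionals (pow3 /
  tanh / gaus), wrappers for five standard normality tests, and the
  per-panel curve normalization used for comparisons;
- `ica` — exhaustive 2D angular search, projected-gradient deflation ICA
  for J_n (with a time-decaying learning rate and random restarts) and
  fixed-point deflation for the FastICA contrasts, plus angular error and
  precision metrics;
- `eeg` — a simplified synthetic multichannel EEG generator with
  ground-truth eye-blink sources and a PCA → ICA → artifact-matching
  pipeline;
- `bench` / CLI — seeded, reproducible benchmark runners producing
  long-format CSV tables, ANOVA, and FDR-corrected paired tests.

## Worked example

```python
import numpy as np
from hermica import gaussian_mixture, j_from_samples, normal

mix = gaussian_mixture(0.5, -2, 1, 2, 1)   # balanced bimodal mixture
g = j_from_samples(normal().sample(10_000, seed=0))
b = j_from_samples(mix.sample(10_000, seed=0))
print(f"J_15(gaussian) = {g.value:.4f}")
print(f"J_15(bimodal)  = {b.value:.4f}")
```

prints

```
J_15(gaussian) = 0.0008
J_15(bimodal)  = 0.2520
```

— the Gaussian sample scores essentially 0 (sampling noise only), while
the bimodal mixture carries about a quarter of its truncated Hermite power
outside the Gaussian term.

Finding a non-Gaussian direction hidden in a 5D linear mixture:

```python
from hermica import ContrastSpec, deflation_search, error_angle, \
    generalized_normal, make_product_dataset, whiten

ds = make_product_dataset(generalized_normal(1.0), d=5, n=10_000,
                          rotate=True, seed=5)
z, wh = whiten(ds.data)
est = deflation_search(z, ContrastSpec("j_n", n=15), n_components=1,
                       restarts=10, seed=7)[0]
print(f"error = {error_angle(est.direction, wh.map_direction(ds.true_direction)):.2f} deg")
```

prints `error = 2.33 deg`: the gradient search recovers the heavy-tailed
axis of the rotated product distribution to within a few degrees at this
sample size.

The command-line interface exposes the benchmark runners
(`hermica score`, `bench-1d`, `bench-2d`, `order-study`, `bench-5d`,
`eeg-sim`, `bench-eeg`); see `hermica --help`.

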