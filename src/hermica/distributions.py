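"""Parametric 1D families and product-distribution dataset constructors.

Three families probe distinct departures from normality:

* ``gaussian_mixture`` — two-component normal mixture; the weight ``alpha``
  moves the family from Gaussian (``alpha`` = 0 or 1) to bimodal.
* ``generalized_normal`` — symmetric exponential-power density
  ``C(beta) exp(-|x|^beta / 2)``; Gaussian at ``beta = 2``, heavy-tailed
  (leptokurtic) below, light-tailed (platykurtic) above.
* ``gev`` — generalized extreme value with unit location/scale; the shape
  ``kappa`` controls tail asymmetry (Gumbel at ``kappa = 0``; the skewness
  changes sign near ``kappa = -0.3``).

Multidimensional benchmark datasets are product distributions with exactly
one (standardized) non-Gaussian axis and i.i.d. standard-normal remaining
axes, optionally mixed by a random orthogonal matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "DistributionSpec",
    "StandardizedDistribution",
    "MultiDataset",
    "normal",
    "gaussian_mixture",
    "generalized_normal",
    "gev",
    "mixture_density",
    "generalized_normal_density",
    "generalized_normal_constant",
    "gev_density",
    "sample",
    "make_product_dataset",
    "benchmark_specs",
    "moments_by_quadrature",
    "gev_skewness",
    "gev_skewness_sign_change",
]


def generalized_normal_constant(beta: float) -> float:
    """Normalizing constant ``C(beta) = beta / (2^{1+1/beta} Γ(1/beta))``.

    Obtained from ``∫ exp(-|x|^beta/2) dx = 2^{1+1/beta} Γ(1/beta) / beta``
    (substitute ``u = x^beta / 2``); verified against quadrature in tests.
    """
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")
    return beta / (2.0 ** (1.0 + 1.0 / beta) * special.gamma(1.0 / beta))


def mixture_density(alpha, mu1, sigma1, mu2, sigma2, x):
    """Two-component Gaussian mixture density."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("component SDs must be positive")
    return alpha * stats.norm.pdf(x, mu1, sigma1) + (1.0 - alpha) * stats.norm.pdf(
        x, mu2, sigma2
    )


def generalized_normal_density(beta, x):
    """``C(beta) exp(-|x|^beta / 2)``; standard normal at ``beta = 2``."""
    c = generalized_normal_constant(beta)
    return c * np.exp(-0.5 * np.abs(np.asarray(x, dtype=float)) ** beta)


def gev_density(kappa, x):
    """Unit-location/scale GEV density; Gumbel limit for ``|kappa| < 1e-12``.

    Outside the support (``1 + kappa*x <= 0``) the density is 0, not an
    error.  Maps onto ``scipy.stats.genextreme`` with ``c = -kappa``.
    """
    xa = np.asarray(x, dtype=float)
    if abs(kappa) < 1e-12:
        return np.exp(-xa - np.exp(-xa))[()]
    t = 1.0 + kappa * xa
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        res = np.where(
            t > 0,
            np.exp(-np.where(t > 0, t, 1.0) ** (-1.0 / kappa))
            * np.where(t > 0, t, 1.0) ** (-1.0 - 1.0 / kappa),
            0.0,
        )
    return res[()]


@dataclass(frozen=True)
class DistributionSpec:
    """A member of one of the supported 1D families.

    ``family`` is one of ``normal``, ``gaussian_mixture``,
    ``generalized_normal``, ``gev``; ``params`` holds the family-specific
    parameters.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        if self.family == "gaussian_mixture":
            a = self.params["alpha"]
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha must be in [0, 1], got {a}")
            if self.params["sigma1"] <= 0 or self.params["sigma2"] <= 0:
                raise ValueError("component SDs must be positive")
        elif self.family == "generalized_normal":
            if self.params["beta"] <= 0:
                raise ValueError("beta must be > 0")
        elif self.family not in ("normal", "gev"):
            raise ValueError(f"unknown family {self.family!r}")

    # -- density / support ------------------------------------------------
    def density(self, x):
        p = self.params
        if self.family == "normal":
            return stats.norm.pdf(x)
        if self.family == "gaussian_mixture":
            return mixture_density(
                p["alpha"], p["mu1"], p["sigma1"], p["mu2"], p["sigma2"], x
            )
        if self.family == "generalized_normal":
            return generalized_normal_density(p["beta"], x)
        return gev_density(p["kappa"], x)

    def support(self) -> tuple[float, float]:
        if self.family == "gev":
            k = self.params["kappa"]
            if k > 1e-12:
                return (-1.0 / k, np.inf)
            if k < -1e-12:
                return (-np.inf, -1.0 / k)
        return (-np.inf, np.inf)

    def cdf(self, x):
        if self.family == "normal":
            return stats.norm.cdf(x)
        if self.family == "gaussian_mixture":
            p = self.params
            return p["alpha"] * stats.norm.cdf(x, p["mu1"], p["sigma1"]) + (
                1 - p["alpha"]
            ) * stats.norm.cdf(x, p["mu2"], p["sigma2"])
        if self.family == "generalized_normal":
            # scipy's gennorm uses exp(-|y|^beta); ours is exp(-|x|^beta/2),
            # i.e. x = 2^(1/beta) y.
            b = self.params["beta"]
            return stats.gennorm.cdf(np.asarray(x) / 2.0 ** (1.0 / b), b)
        return stats.genextreme.cdf(x, -self.params["kappa"])

    # -- moments ----------------------------------------------------------
    def mean(self) -> float:
        p = self.params
        if self.family == "normal":
            return 0.0
        if self.family == "gaussian_mixture":
            return p["alpha"] * p["mu1"] + (1 - p["alpha"]) * p["mu2"]
        if self.family == "generalized_normal":
            return 0.0
        m, _ = stats.genextreme.stats(-p["kappa"], moments="mv")
        return float(m)

    def var(self) -> float:
        p = self.params
        if self.family == "normal":
            return 1.0
        if self.family == "gaussian_mixture":
            m = self.mean()
            ex2 = p["alpha"] * (p["mu1"] ** 2 + p["sigma1"] ** 2) + (
                1 - p["alpha"]
            ) * (p["mu2"] ** 2 + p["sigma2"] ** 2)
            return ex2 - m**2
        if self.family == "generalized_normal":
            b = p["beta"]
            return (
                2.0 ** (2.0 / b) * special.gamma(3.0 / b) / special.gamma(1.0 / b)
            )
        _, v = stats.genextreme.stats(-p["kappa"], moments="mv")
        return float(v)

    def std(self) -> float:
        return float(np.sqrt(self.var()))

    def standardized(self) -> "StandardizedDistribution":
        return StandardizedDistribution(self)

    # -- sampling ---------------------------------------------------------
    def sample(self, n: int, seed=None) -> np.ndarray:
        """Seeded draws; the same (spec, n, seed) always gives the same vector."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        p = self.params
        if self.family == "normal":
            return rng.standard_normal(n)
        if self.family == "gaussian_mixture":
            pick1 = rng.random(n) < p["alpha"]
            mu = np.where(pick1, p["mu1"], p["mu2"])
            sd = np.where(pick1, p["sigma1"], p["sigma2"])
            return mu + sd * rng.standard_normal(n)
        if self.family == "generalized_normal":
            # |X|^beta / 2 ~ Gamma(1/beta, 1)  =>  X = sign * (2G)^(1/beta)
            b = p["beta"]
            g = rng.gamma(1.0 / b, scale=2.0, size=n)
            sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            return sign * g ** (1.0 / b)
        # GEV via inverse CDF
        k = p["kappa"]
        u = rng.random(n)
        if abs(k) < 1e-12:
            return -np.log(-np.log(u))
        return ((-np.log(u)) ** (-k) - 1.0) / k

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": dict(self.params)})

    @classmethod
    def from_json(cls, text: str) -> "DistributionSpec":
        d = json.loads(text)
        return cls(d["family"], d["params"])


class StandardizedDistribution:
    """Affine rescaling of a spec to mean 0 and variance 1.

    Exposes the same ``density``/``support``/``sample`` surface so it can
    be fed to ``analytic_coefficients`` or to dataset constructors.
    """

    def __init__(self, inner: DistributionSpec):
        self.inner = inner
        self.loc = inner.mean()
        self.scale = inner.std()

    def density(self, x):
        return self.scale * self.inner.density(
            self.scale * np.asarray(x, dtype=float) + self.loc
        )

    def support(self) -> tuple[float, float]:
        lo, hi = self.inner.support()
        return ((lo - self.loc) / self.scale, (hi - self.loc) / self.scale)

    def sample(self, n: int, seed=None) -> np.ndarray:
        return (self.inner.sample(n, seed) - self.loc) / self.scale

    def mean(self) -> float:
        return 0.0

    def var(self) -> float:
        return 1.0

    def std(self) -> float:
        return 1.0


# -- factories ------------------------------------------------------------


def normal() -> DistributionSpec:
    return DistributionSpec("normal")


def gaussian_mixture(alpha, mu1, sigma1, mu2, sigma2) -> DistributionSpec:
    return DistributionSpec(
        "gaussian_mixture",
        {"alpha": alpha, "mu1": mu1, "sigma1": sigma1, "mu2": mu2, "sigma2": sigma2},
    )


def generalized_normal(beta) -> DistributionSpec:
    return DistributionSpec("generalized_normal", {"beta": beta})


def gev(kappa) -> DistributionSpec:
    return DistributionSpec("gev", {"kappa": kappa})


def benchmark_specs() -> dict[str, DistributionSpec]:
    """The five non-Gaussian components used in the 2D/5D benchmarks."""
    return {
        "bimodal_symmetric": gaussian_mixture(0.5, -2.0, 1.0, 2.0, 1.0),
        "bimodal_asymmetric": gaussian_mixture(0.7, -2.0, 1.0, 2.0, 0.4),
        "heavy_tailed": generalized_normal(1.0),
        "light_tailed": generalized_normal(10.0),
        "asymmetric": gev(0.0),
    }


def sample(spec: DistributionSpec, n: int, seed=None) -> np.ndarray:
    """Module-level convenience wrapper around ``spec.sample``."""
    return spec.sample(n, seed)


# -- quadrature moments ----------------------------------------------------


def moments_by_quadrature(spec) -> dict[str, float]:
    """Mean, variance, skewness, excess kurtosis by adaptive quadrature."""
    pdf, (lo, hi) = spec.density, spec.support()

    def raw(k):
        # split at an interior point: quad handles the infinite tails itself
        # (clipping would truncate slowly-decaying moments, e.g. GEV kappa > 0)
        mid = 0.0 if lo < 0.0 < hi else (lo + 1.0 if np.isfinite(lo) else hi - 1.0)
        a, _ = integrate.quad(lambda x: x**k * pdf(x), lo, mid, limit=400)
        b, _ = integrate.quad(lambda x: x**k * pdf(x), mid, hi, limit=400)
        return a + b

    m1 = raw(1)
    mu2 = raw(2) - m1**2
    mu3 = raw(3) - 3 * m1 * raw(2) + 2 * m1**3
    mu4 = raw(4) - 4 * m1 * raw(3) + 6 * m1**2 * raw(2) - 3 * m1**4
    return {
        "mean": m1,
        "var": mu2,
        "skewness": mu3 / mu2**1.5,
        "excess_kurtosis": mu4 / mu2**2 - 3.0,
    }


def gev_skewness(kappa: float) -> float:
    """Skewness of the GEV member by quadrature (third moment exists for kappa < 1/3)."""
    return moments_by_quadrature(gev(kappa))["skewness"]


def gev_skewness_sign_change(lo: float = -0.45, hi: float = -0.05) -> float:
    """Shape parameter at which GEV skewness crosses zero, by root-finding."""
    return float(optimize.brentq(gev_skewness, lo, hi, xtol=1e-6))


# -- multivariate product datasets ----------------------------------------


@dataclass(frozen=True)
class MultiDataset:
    """N x d samples with one known non-Gaussian axis.

    ``true_direction`` is the unit vector along which the non-Gaussian
    component lies after mixing; ``mixing`` is the orthogonal matrix
    applied to the raw product samples (identity if none).
    """

    data: np.ndarray
    true_direction: np.ndarray
    mixing: np.ndarray
    component_spec: DistributionSpec
    seed: int | None = None

    def save(self, directory) -> None:
        """Write the matrix as CSV plus a JSON sidecar with the ground truth."""
        from pathlib import Path

        p = Path(directory)
        p.mkdir(parents=True, exist_ok=True)
        np.savetxt(p / "data.csv", self.data, delimiter=",")
        sidecar = {
            "true_direction": self.true_direction.tolist(),
            "mixing": self.mixing.tolist(),
            "seed": self.seed,
            "component_spec": json.loads(self.component_spec.to_json()),
        }
        (p / "dataset.json").write_text(json.dumps(sidecar))


def make_product_dataset(
    non_gaussian: DistributionSpec,
    d: int = 2,
    n: int = 10_000,
    rotate: bool = False,
    seed=None,
) -> MultiDataset:
    """Sample a product distribution with one standardized non-Gaussian axis.

    Axis 0 carries the (analytically standardized) non-Gaussian component,
    the remaining ``d - 1`` axes are i.i.d. standard normal.  With
    ``rotate``, a seeded uniformly random orthogonal matrix mixes the
    axes; ``true_direction`` is its first column.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    rng = np.random.default_rng(seed)
    std_spec = non_gaussian.standardized()
    cols = np.empty((n, d))
    cols[:, 0] = std_spec.sample(n, rng)
    cols[:, 1:] = rng.standard_normal((n, d - 1))
    if rotate:
        q = stats.ortho_group.rvs(d, random_state=rng)
    else:
        q = np.eye(d)
    data = cols @ q.T
    return MultiDataset(
        data=data,
        true_direction=q[:, 0].copy(),
        mixing=q,
        component_spec=non_gaussian,
        seed=None if seed is None else int(seed) if np.isscalar(seed) else None,
    )
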