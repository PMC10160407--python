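"""ICA contrast functionals, standard normality tests, and curve normalization.

The three classic FastICA contrasts are sample means of a fixed
nonlinearity of the standardized data:

* ``fastica_i``   — kurtosis-based, ``E[X^4] / 4`` (``pow3``),
* ``fastica_ii``  — negentropy proxy ``E[log cosh X]`` (``tanh``),
* ``fastica_iii`` — negentropy proxy ``E[-exp(-X^2/2)]`` (``gaus``).

For benchmarking against J_n (which is anchored at 0 for a Gaussian) each
contrast is scored as the absolute deviation of the functional from its
standard-normal expectation; the log-cosh and Gaussian nonlinearities are
non-monotone around that expectation, so a signed deviation would fold
light- and heavy-tailed departures onto each other.

Normality tests are delegated to scipy/statsmodels; the comparison
quantity is the test statistic, oriented so that larger means more
non-Gaussian (Shapiro-Wilk is reported as ``1 - W``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .hermite import j_from_samples, standardize

__all__ = [
    "ContrastSpec",
    "CONTRAST_NAMES",
    "NORMALITY_TESTS",
    "fastica_contrast",
    "gaussian_reference",
    "contrast_score",
    "normality_suite",
    "normalize_curves",
]

CONTRAST_NAMES = ("j_n", "fastica_i", "fastica_ii", "fastica_iii")

_SHAPIRO_CAP = 5000  # library small-sample validity cap; see normality_suite


@dataclass(frozen=True)
class ContrastSpec:
    """A named contrast; ``n``/``variant`` apply only to ``j_n``."""

    name: str
    n: int = 15
    variant: str = "all"

    def __post_init__(self):
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"unknown contrast {self.name!r}")

    @property
    def label(self) -> str:
        if self.name == "j_n":
            suffix = "" if self.variant == "all" else f"_{self.variant}"
            return f"J_{self.n}{suffix}"
        return self.name


def fastica_contrast(name: str, samples) -> float:
    """Sample mean of the named FastICA nonlinearity on standardized data."""
    z = np.asarray(samples, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty sample")
    if name == "fastica_i":
        return float(np.mean(z**4) / 4.0)
    if name == "fastica_ii":
        return float(np.mean(np.log(np.cosh(z))))
    if name == "fastica_iii":
        return float(np.mean(-np.exp(-0.5 * z**2)))
    raise ValueError(f"unknown FastICA contrast {name!r}")


@lru_cache(maxsize=None)
def gaussian_reference(name: str) -> float:
    """Expectation of the contrast functional under the standard normal.

    ``fastica_i`` has the closed form 3/4 (Gaussian fourth moment); the
    others are computed once by high-precision quadrature and cached.
    """
    if name == "fastica_i":
        return 0.75
    if name == "fastica_ii":
        f = lambda x: np.log(np.cosh(x)) * stats.norm.pdf(x)
    elif name == "fastica_iii":
        f = lambda x: -np.exp(-0.5 * x**2) * stats.norm.pdf(x)
    else:
        raise ValueError(f"unknown FastICA contrast {name!r}")
    val, _ = integrate.quad(f, -12, 12, epsabs=1e-14, limit=200)
    return float(val)


def contrast_score(spec: ContrastSpec, samples) -> float:
    """Non-Gaussianity score of a standardized sample under ``spec``.

    ``j_n`` is used directly; FastICA functionals are scored as
    ``|E_hat[g] - E_gauss[g]]|`` so that 0 means Gaussian for every method.
    """
    if spec.name == "j_n":
        return j_from_samples(samples, n=spec.n, variant=spec.variant).value
    raw = fastica_contrast(spec.name, samples)
    return abs(raw - gaussian_reference(spec.name))


NORMALITY_TESTS = (
    "kolmogorov_smirnov",
    "anderson_darling",
    "jarque_bera",
    "dagostino_k2",
    "shapiro_wilk",
)


def _shapiro_statistic(x: np.ndarray) -> float:
    if x.size > _SHAPIRO_CAP:
        # deterministic fixed-stride subsample, logged to the caller
        idx = np.linspace(0, x.size - 1, _SHAPIRO_CAP).round().astype(int)
        warnings.warn(
            f"Shapiro-Wilk capped at {_SHAPIRO_CAP} samples; "
            f"using a fixed-stride subsample of {x.size}"
        )
        x = x[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = stats.shapiro(x).statistic
    return 1.0 - float(w)


def normality_suite(samples, tests=NORMALITY_TESTS) -> dict[str, float]:
    """Statistics of the five standard normality tests, larger = less normal.

    Orientation: KS distance D, Anderson-Darling A^2, Jarque-Bera JB,
    D'Agostino K^2, and 1 - W for Shapiro-Wilk.  A test that fails on the
    given input (e.g. below its validity range) is reported as NaN with a
    warning; the others are still returned.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 20:
        raise ValueError("normality suite requires at least 20 samples")
    if x.std() == 0:
        raise ValueError("constant input: normality tests undefined")
    z = standardize(x)
    out: dict[str, float] = {}
    for name in tests:
        try:
            if name == "kolmogorov_smirnov":
                out[name] = float(stats.kstest(z, "norm").statistic)
            elif name == "anderson_darling":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", FutureWarning)
                    out[name] = float(stats.anderson(x, "norm").statistic)
            elif name == "jarque_bera":
                out[name] = float(stats.jarque_bera(x).statistic)
            elif name == "dagostino_k2":
                out[name] = float(stats.normaltest(x).statistic)
            elif name == "shapiro_wilk":
                out[name] = _shapiro_statistic(x)
            else:
                raise ValueError(f"unknown test {name!r}")
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - library edge cases
            warnings.warn(f"{name} failed: {exc}")
            out[name] = float("nan")
    return out


def normalize_curves(
    table: pd.DataFrame,
    value_col: str = "value",
    method_col: str = "method",
    param_col: str = "param",
    panel_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Scale each method's curve so the maximum of its mean equals 1.

    Within every (panel, method) group the replicate values are divided by
    the maximum over parameter values of the per-parameter replicate mean.
    A group whose means are all zero is left unnormalized with a warning.
    """
    df = table.copy()
    df[value_col] = df[value_col].astype(float)
    group_cols = list(panel_cols) + [method_col]
    for key, idx in df.groupby(group_cols, sort=False).groups.items():
        sub = df.loc[idx]
        means = sub.groupby(param_col)[value_col].mean()
        peak = means.max()
        if not np.isfinite(peak) or peak == 0:
            warnings.warn(f"cannot normalize group {key}: flat/zero means")
            continue
        df.loc[idx, value_col] = sub[value_col] / peak
    return df
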