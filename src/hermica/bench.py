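"""Seeded benchmark pipelines comparing J_15 with standard methods.

Each runner draws its own reproducible data, scores it, and returns
long-format pandas tables (one record per family x parameter x size x
method x replicate).  Replicate counts default to desk scale; the full
study scale is a configuration change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from . import distributions as dist
from .contrasts import (
    ContrastSpec,
    contrast_score,
    normality_suite,
    normalize_curves,
    NORMALITY_TESTS,
)
from .eeg import extract_and_match, pca_reduce, simulate_eeg
from .hermite import estimate_coefficients, j_measure, standardize
from .ica import (
    aggregate_profiles,
    cross_contrast_select,
    deflation_search,
    error_angle,
    exhaustive_search_2d,
    order_study_search,
    precision_from_profile,
    whiten,
    window_circular_variance,
)

__all__ = [
    "RunConfig",
    "default_contrasts",
    "run_1d_benchmark",
    "run_2d_benchmark",
    "run_order_study",
    "run_5d_benchmark",
    "run_eeg_benchmark",
    "bootstrap_ci",
]


def default_contrasts() -> list[ContrastSpec]:
    return [
        ContrastSpec("j_n", n=15),
        ContrastSpec("fastica_i"),
        ContrastSpec("fastica_ii"),
        ContrastSpec("fastica_iii"),
    ]


@dataclass
class RunConfig:
    """Shared knobs for the benchmark runners (desk-scale defaults)."""

    seed: int = 0
    n_runs: int = 100
    sizes: tuple[int, ...] = (1_000,)
    families: tuple[str, ...] = (
        "bimodal_symmetric",
        "bimodal_asymmetric",
        "heavy_tailed",
        "light_tailed",
        "asymmetric",
    )
    # 1D family parameter grids (the figure abscissae)
    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    beta_grid: tuple[float, ...] = tuple(np.round(np.arange(0.5, 10.001, 0.5), 1))
    kappa_grid: tuple[float, ...] = tuple(np.round(np.arange(-0.5, 1.0001, 0.1), 1))
    # search parameters
    restarts: int = 25
    max_iter: int = 500
    n_components: int = 20
    n_bootstrap: int = 1000

    def spawn_seed(self, *indices: int) -> int:
        """Deterministic per-task seed derived from the master seed."""
        ss = np.random.SeedSequence([self.seed, *indices])
        return int(ss.generate_state(1)[0] % (2**31))


def bootstrap_ci(
    values, n_boot: int = 1000, level: float = 0.95, seed=0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )


# -- 1D sensitivity benchmark ----------------------------------------------


def _family_grid(cfg: RunConfig):
    yield "bimodal", [
        ("gaussian_mixture", dist.gaussian_mixture(a, -2.0, 1.0, 2.0, 1.0), a)
        for a in cfg.alpha_grid
    ]
    yield "tails", [
        ("generalized_normal", dist.generalized_normal(b), b) for b in cfg.beta_grid
    ]
    yield "asymmetry", [("gev", dist.gev(k), k) for k in cfg.kappa_grid]


def run_1d_benchmark(cfg: RunConfig, normalize: bool = True) -> pd.DataFrame:
    """Score J_15, five normality tests, and three FastICA contrasts.

    One record per family x parameter x size x method x replicate; when
    ``normalize`` each method's curve is scaled so the maximum of its mean
    is 1 within every (family, N) panel.
    """
    contrasts = default_contrasts()
    rows = []
    for fam_idx, (family, members) in enumerate(_family_grid(cfg)):
        for p_idx, (_, spec, param) in enumerate(members):
            for s_idx, n in enumerate(cfg.sizes):
                for rep in range(cfg.n_runs):
                    seed = cfg.spawn_seed(fam_idx, p_idx, s_idx, rep)
                    x = spec.sample(n, seed)
                    z = standardize(x)
                    for c in contrasts:
                        rows.append(
                            {
                                "family": family,
                                "param": param,
                                "N": n,
                                "method": c.label,
                                "replicate": rep,
                                "value": contrast_score(c, z),
                            }
                        )
                    for name, stat in normality_suite(x).items():
                        rows.append(
                            {
                                "family": family,
                                "param": param,
                                "N": n,
                                "method": name,
                                "replicate": rep,
                                "value": stat,
                            }
                        )
    df = pd.DataFrame(rows)
    if normalize:
        df = normalize_curves(df, panel_cols=("family", "N"))
    return df


# -- 2D exhaustive-search benchmark ----------------------------------------


def run_2d_benchmark(cfg: RunConfig, n_samples: int = 10_000):
    """Accuracy (peak location) and precision (band half-width) in 2D.

    Returns ``(table, profiles)`` where ``profiles[(family, method)]`` is
    the across-replicate PrecisionProfile on the coarse 1-degree grid.
    """
    specs = dist.benchmark_specs()
    contrasts = default_contrasts()
    rows = []
    curves: dict[tuple[str, str], list[np.ndarray]] = {}
    grid = None
    for f_idx, fam in enumerate(cfg.families):
        spec = specs[fam]
        for rep in range(cfg.n_runs):
            ds = dist.make_product_dataset(
                spec, d=2, n=n_samples, rotate=False, seed=cfg.spawn_seed(f_idx, rep)
            )
            for c in contrasts:
                est, angles, scores = exhaustive_search_2d(ds.data, c)
                grid = angles
                curves.setdefault((fam, c.label), []).append(scores)
                rows.append(
                    {
                        "family": fam,
                        "N": n_samples,
                        "method": c.label,
                        "replicate": rep,
                        "error_deg": error_angle(est.direction, ds.true_direction),
                        "value": est.contrast_value,
                    }
                )
    profiles = {
        key: aggregate_profiles(grid, np.array(cs)) for key, cs in curves.items()
    }
    return pd.DataFrame(rows), profiles


# -- truncation-order study ------------------------------------------------


def run_order_study(
    cfg: RunConfig,
    n_values=tuple(range(2, 51)),
    variants=("all", "even", "odd"),
):
    """Error and direction dispersion of J_n variants versus n and N.

    Returns ``(records, summary)``: per-replicate best angles, and per
    (family, N, n, variant) the mean error with a bootstrap CI plus the
    axial circular variance of the estimated directions.
    """
    specs = dist.benchmark_specs()
    rows = []
    for f_idx, fam in enumerate(cfg.families):
        spec = specs[fam]
        for s_idx, n_samp in enumerate(cfg.sizes):
            for rep in range(cfg.n_runs):
                ds = dist.make_product_dataset(
                    spec,
                    d=2,
                    n=n_samp,
                    rotate=False,
                    seed=cfg.spawn_seed(f_idx, s_idx, rep),
                )
                res = order_study_search(ds.data, 0.0, n_values, variants)
                res["family"] = fam
                res["N"] = n_samp
                res["replicate"] = rep
                rows.append(res)
    records = pd.concat(rows, ignore_index=True)

    summaries = []
    for g_idx, ((fam, n_samp, n, variant), sub) in enumerate(
        records.groupby(["family", "N", "n", "variant"], sort=False)
    ):
        lo, hi = bootstrap_ci(
            sub["error_deg"], n_boot=cfg.n_bootstrap, seed=cfg.spawn_seed(90_000, g_idx)
        )
        summaries.append(
            {
                "family": fam,
                "N": n_samp,
                "n": n,
                "variant": variant,
                "mean_error_deg": sub["error_deg"].mean(),
                "ci_lo": lo,
                "ci_hi": hi,
                "circular_variance": window_circular_variance(sub["est_offset_deg"]),
            }
        )
    return records, pd.DataFrame(summaries)


# -- 5D deflation benchmark ------------------------------------------------


def run_5d_benchmark(cfg: RunConfig, anova: bool = True):
    """Unmixing-direction recovery in 5D with cross-contrast selection.

    For each family x size x seed, every contrast is optimized from
    ``cfg.restarts`` random starts; each contrast then picks its best
    direction among the candidates found by *all* contrasts.  Returns
    ``(table, anova_table, ttests)``.
    """
    specs = dist.benchmark_specs()
    contrasts = default_contrasts()
    rows = []
    for f_idx, fam in enumerate(cfg.families):
        spec = specs[fam]
        for s_idx, n_samp in enumerate(cfg.sizes):
            for rep in range(cfg.n_runs):
                ds = dist.make_product_dataset(
                    spec,
                    d=5,
                    n=n_samp,
                    rotate=True,
                    seed=cfg.spawn_seed(f_idx, s_idx, rep),
                )
                z, wh = whiten(ds.data)
                u_true = wh.map_direction(ds.true_direction)
                candidates = []
                for c_idx, c in enumerate(contrasts):
                    est = deflation_search(
                        z,
                        c,
                        n_components=1,
                        restarts=cfg.restarts,
                        seed=cfg.spawn_seed(f_idx, s_idx, rep, c_idx),
                        max_iter=cfg.max_iter,
                    )[0]
                    candidates.append(est)
                for c in contrasts:
                    best = cross_contrast_select(z, candidates, c)
                    rows.append(
                        {
                            "family": fam,
                            "N": n_samp,
                            "method": c.label,
                            "replicate": rep,
                            "error_deg": error_angle(best.direction, u_true),
                            "value": best.contrast_value,
                        }
                    )
    table = pd.DataFrame(rows)
    anova_table = anova_error(table) if anova else None
    ttests = paired_method_tests(table, reference="J_15")
    return table, anova_table, ttests


def anova_error(table: pd.DataFrame) -> pd.DataFrame:
    """Three-way ANOVA of error angle on family x size x method."""
    df = table.rename(columns={"N": "size"}).copy()
    model = smf.ols(
        "error_deg ~ C(family) * C(size) * C(method)", data=df
    ).fit()
    return sm.stats.anova_lm(model, typ=2)


def paired_method_tests(
    table: pd.DataFrame, reference: str = "J_15", fdr: bool = True
) -> pd.DataFrame:
    """Paired two-tailed t-tests of the reference method against the others.

    Pairing is per replicate within each (family, N) cell; an extra
    comparison is made against the per-dataset best competing method.
    Benjamini-Hochberg adjusted p-values are appended when ``fdr``.
    """
    rows = []
    others = [m for m in table["method"].unique() if m != reference]
    for (fam, n_samp), sub in table.groupby(["family", "N"]):
        wide = sub.pivot_table(
            index="replicate", columns="method", values="error_deg"
        )
        ref = wide[reference]
        comparisons = {m: wide[m] for m in others}
        comparisons["best_other"] = wide[others].min(axis=1)
        for name, col in comparisons.items():
            t, p = stats.ttest_rel(ref, col)
            rows.append(
                {
                    "family": fam,
                    "N": n_samp,
                    "comparison": f"{reference} vs {name}",
                    "mean_diff_deg": float((ref - col).mean()),
                    "t": float(t),
                    "p": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        out["p_fdr"] = multipletests(out["p"].fillna(1.0), method="fdr_bh")[1]
    return out


# -- EEG benchmark ---------------------------------------------------------


def run_eeg_benchmark(
    cfg: RunConfig,
    durations_s: tuple[float, ...] = (6.0, 15.0, 30.0, 60.0, 150.0, 300.0),
    channels: int = 249,
    pca_k: int = 50,
    n_background: int = 20,
):
    """PCA -> deflationary ICA -> blink matching across run lengths.

    One record per duration x seed x contrast x eye, plus per-eye errors
    averaged; returns ``(table, ttests)``.
    """
    contrasts = default_contrasts()
    rows = []
    for d_idx, dur in enumerate(durations_s):
        for rep in range(cfg.n_runs):
            ds = simulate_eeg(
                dur,
                channels=channels,
                n_background=n_background,
                seed=cfg.spawn_seed(d_idx, rep),
            )
            red = pca_reduce(ds, k=pca_k)
            for c_idx, c in enumerate(contrasts):
                rec = extract_and_match(
                    red,
                    c,
                    truth=ds,
                    n_components=min(cfg.n_components, red.reduced.shape[0]),
                    restarts=cfg.restarts,
                    seed=cfg.spawn_seed(d_idx, rep, c_idx),
                    max_iter=cfg.max_iter,
                )
                for eye, err, comp in zip(
                    ("left", "right"), rec.error_deg, rec.matched_component
                ):
                    rows.append(
                        {
                            "duration_s": dur,
                            "replicate": rep,
                            "method": c.label,
                            "eye": eye,
                            "error_deg": err,
                            "component": comp,
                        }
                    )
    table = pd.DataFrame(rows)
    avg = (
        table.groupby(["duration_s", "replicate", "method"])["error_deg"]
        .mean()
        .reset_index()
        .rename(columns={"duration_s": "N"})
        .assign(family="eeg")
    )
    ttests = paired_method_tests(avg, reference="J_15")
    return table, ttests
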