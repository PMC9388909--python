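"""Gene-wise linear models with empirical-Bayes variance moderation.

The differential-translation test fits, per gene and per polysome fraction,
an ordinary least-squares model of log2-CPM on condition (high vs low
glucose), then shrinks the gene-wise residual variances s2_g toward a prior
s0^2 estimated across genes.  Writing d for the residual degrees of freedom
and d0 for the prior degrees of freedom, the posterior variance is

    s2_post = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated t statistic  t = beta_hat / (sqrt(s2_post) * su)  is
referred to a t distribution on d0 + d degrees of freedom.  (d0, s0^2) are
estimated by method of moments on z = log s2: under the scaled-F sampling
model, Var(z) = trigamma(d/2) + trigamma(d0/2) and E(z) = log s0^2 +
digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2); the variance equation
is solved for d0 by a monotone Newton inversion of the trigamma function.
When the observed spread of z is no larger than the chi-square theoretical
spread, d0 is infinite and every posterior variance equals the common
prior.  By default the prior follows the abundance trend (lowess of log s2
on mean expression) so low-count genes stay calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError
from .preprocess import cpm, validate_sample_sheet

__all__ = [
    "fit_gene_linear_models",
    "ebayes_moderate",
    "trigamma_inverse",
    "bh_adjust",
    "call_regulated",
    "differential_by_fraction",
    "venn_overlap",
]


def make_design(sample_sheet: pd.DataFrame, samples) -> pd.DataFrame:
    """Intercept + condition(high) design for the given samples."""
    sheet = sample_sheet.set_index("sample_id").loc[list(samples)]
    return pd.DataFrame(
        {
            "intercept": 1.0,
            "condition_high": (sheet["condition"] == "high").astype(float).to_numpy(),
        },
        index=list(samples),
    )


def fit_gene_linear_models(
    expr: pd.DataFrame, design: pd.DataFrame, contrast=None
) -> pd.DataFrame:
    """Per-gene OLS fit; returns logFC, residual variance and df.

    ``expr`` is genes x samples (log2 scale), ``design`` samples x
    coefficients.  ``contrast`` defaults to the last design column.  The
    returned frame has columns ``logFC`` (contrast estimate), ``ave_expr``,
    ``s2`` (RSS/df), ``df`` and ``su`` (unscaled standard error
    sqrt(c' (X'X)^-1 c)).
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if expr.shape[1] != n:
        raise DataError(f"expression has {expr.shape[1]} samples, design {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ConfigurationError("design matrix is rank-deficient")
    if n <= p:
        raise ConfigurationError(f"need more samples ({n}) than coefficients ({p})")
    if contrast is None:
        contrast = np.eye(p)[-1]
    c = np.asarray(contrast, dtype=float)
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ B
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    su = float(np.sqrt(c @ XtX_inv @ c))
    return pd.DataFrame(
        {
            "logFC": c @ B,
            "ave_expr": Y.mean(axis=0),
            "s2": s2,
            "df": float(df),
            "su": su,
        },
        index=expr.index,
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to gene-wise variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise DataError("need >= 2 positive gene variances to estimate the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s02 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # observed spread no larger than the chi-square theoretical spread:
        # infinite prior df, common variance = arithmetic mean
        d0 = np.inf
        s02 = float(np.mean(s2[ok]))
    return float(d0), float(s02)


def estimate_prior_trend(
    s2: np.ndarray, df: float, ave_expr: np.ndarray, frac: float = 0.4
) -> tuple[float, np.ndarray]:
    """Abundance-dependent prior: lowess trend of log s2 on mean expression.

    Count data carry a mean-variance trend (low-abundance genes are
    noisier on the log scale); squeezing every gene toward one global
    prior under-estimates their variance and inflates the moderated t at
    low counts.  Fitting the prior variance as a smooth function of
    average expression (the limma-trend idea) restores calibration.
    Returns (d0, per-gene s0^2 vector).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    s2 = np.asarray(s2, dtype=float)
    A = np.asarray(ave_expr, dtype=float)
    ok = s2 > 0
    if ok.sum() < 30:
        d0, s02 = estimate_prior(s2, df)
        return d0, np.full_like(s2, s02)
    e = np.full_like(s2, np.nan)
    e[ok] = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    fitted = lowess(e[ok], A[ok], frac=frac, it=3, return_sorted=False)
    # extend the trend to zero-variance genes by interpolation on A
    order = np.argsort(A[ok])
    trend = np.interp(A, A[ok][order], fitted[order])
    resid_var = np.var(e[ok] - trend[ok], ddof=1) - special.polygamma(1, df / 2.0)
    if resid_var > 0:
        d0 = 2.0 * trigamma_inverse(resid_var)
        log_s02 = trend + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        s02 = np.exp(log_s02)
    else:
        d0 = np.inf
        s02 = np.exp(trend)
    return float(d0), s02


def ebayes_moderate(
    fit: pd.DataFrame,
    d0: float | None = None,
    s02: float | np.ndarray | None = None,
    trend: bool = False,
) -> pd.DataFrame:
    """Moderated t statistics and p-values from a per-gene OLS fit.

    ``d0``/``s02`` override the estimated prior (``d0=0`` reproduces the
    ordinary t test; ``d0=np.inf`` shrinks every variance fully to the
    prior).  With ``trend`` the prior variance is an abundance-dependent
    curve rather than a constant (see :func:`estimate_prior_trend`).
    Adds columns ``s2_post``, ``t``, ``p``, ``adj_p`` plus the
    hyperparameters ``d0``/``s02`` (as frame attrs as well).
    """
    if len(fit) < 50 and d0 is None:
        import warnings

        warnings.warn(
            f"only {len(fit)} genes: empirical-Bayes hyperparameters may be unstable",
            stacklevel=2,
        )
    s2 = fit["s2"].to_numpy(dtype=float)
    df = float(fit["df"].iloc[0])
    if d0 is None or s02 is None:
        if trend:
            d0_est, s02_est = estimate_prior_trend(
                s2, df, fit["ave_expr"].to_numpy(dtype=float)
            )
        else:
            d0_est, s02_est = estimate_prior(s2, df)
        d0 = d0_est if d0 is None else d0
        s02 = s02_est if s02 is None else s02
    s02 = np.asarray(s02, dtype=float)
    if np.isinf(d0):
        s2_post = np.broadcast_to(s02, s2.shape).copy()
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post) * fit["su"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit["logFC"].to_numpy(dtype=float) / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out["adj_p"] = bh_adjust(out["p"])
    out["d0"] = d0
    out["s02"] = s02
    out.attrs["d0"] = float(d0)
    out.attrs["s02"] = float(np.mean(s02))
    return out


def bh_adjust(p, method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default).

    ``method`` is any statsmodels ``multipletests`` method name
    (``holm``, ``fdr_by``...).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise DataError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def call_regulated(
    diff: pd.DataFrame, alpha: float = 0.05, lfc: float = 0.5
) -> dict[str, set]:
    """Threshold a moderated-t result into up/down gene sets.

    up: adjusted p <= alpha and logFC > lfc; down: adjusted p <= alpha and
    logFC < -lfc (boundaries follow the published thresholds: inclusive on
    p, strict on the fold-change).
    """
    sig = diff["adj_p"] <= alpha
    up = set(diff.index[sig & (diff["logFC"] > lfc)])
    down = set(diff.index[sig & (diff["logFC"] < -lfc)])
    return {"up": up, "down": down}


def differential_by_fraction(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    fractions=("total", "mono", "light", "heavy"),
    prior_count: float = 0.5,
    d0: float | None = None,
    pool_variance: bool = False,
    trend: bool = True,
) -> dict[str, pd.DataFrame]:
    """High-vs-low moderated-t analysis separately within each fraction.

    Each fraction's samples are CPM-normalised on their own library sizes,
    log2-transformed and fitted with an (intercept, condition) model.  The
    empirical-Bayes prior follows the abundance trend by default (``trend``),
    which keeps low-count genes calibrated; ``trend=False`` gives the plain
    single-prior squeeze.  With ``pool_variance`` the (untrended) prior is
    estimated once on the variances of all fractions jointly.
    """
    validate_sample_sheet(sample_sheet, counts.columns)
    sheet = sample_sheet.set_index("sample_id").loc[counts.columns]
    fits = {}
    for frac in fractions:
        cols = sheet.index[sheet["fraction"] == frac]
        if len(cols) == 0:
            raise DataError(f"no samples for fraction {frac!r}")
        logcpm = cpm(counts[list(cols)], log=True, prior_count=prior_count)
        design = make_design(sample_sheet, cols)
        fits[frac] = fit_gene_linear_models(logcpm, design)
    if pool_variance:
        all_s2 = np.concatenate([f["s2"].to_numpy() for f in fits.values()])
        df = float(next(iter(fits.values()))["df"].iloc[0])
        d0_pool, s02_pool = estimate_prior(all_s2, df)
        return {
            f: ebayes_moderate(fit, d0=d0 if d0 is not None else d0_pool, s02=s02_pool)
            for f, fit in fits.items()
        }
    return {f: ebayes_moderate(fit, d0=d0, trend=trend) for f, fit in fits.items()}


def venn_overlap(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region cardinalities for 2-3 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection the
    count describes, e.g. ``("A",)`` = in A only, ``("A", "B")`` = in A and
    B but no other set.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ConfigurationError("venn_overlap supports 2 or 3 sets")
    regions: dict[tuple[str, ...], int] = {}
    universe = set().union(*sets.values())
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            regions[tuple(sorted(combo))] = len(inside - outside)
    assert sum(regions.values()) == len(universe)
    return regions
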