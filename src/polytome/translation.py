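"""Translation ratio, translation efficiency and A254-trace summaries.

Translation ratio TR(f, c): mean TPM of a gene in polysome fraction f under
condition c divided by its mean total-RNA TPM in the same condition — a
per-fraction ribosome-occupancy proxy.  Translation efficiency TE contrasts
the light+heavy-averaged TR between high and low glucose; genes are
classified UP / DOWN / CONTROL by fixed TE thresholds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .preprocess import validate_sample_sheet

__all__ = [
    "translation_ratio",
    "translation_efficiency",
    "classify_translation_groups",
    "rank_top_translated",
    "polysome_monosome_ratio",
    "build_log_ratio_matrix",
]

POLYSOME_FRACTIONS = ("mono", "light", "heavy")


def _condition_means(
    tpm: pd.DataFrame, sheet: pd.DataFrame, fraction: str, condition: str
) -> pd.Series:
    cols = sheet.index[(sheet["fraction"] == fraction) & (sheet["condition"] == condition)]
    if len(cols) == 0:
        raise DataError(f"no replicate for fraction={fraction!r}, condition={condition!r}")
    return tpm[list(cols)].mean(axis=1)


def translation_ratio(tpm: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """TR(f, c) per gene for f in mono/light/heavy, c in low/high.

    Columns are ``tr_{fraction}_{condition}``.  Genes with a zero total-RNA
    mean in a condition get NaN TR there (they end up UNCLASSIFIED).
    """
    validate_sample_sheet(sample_sheet, tpm.columns)
    sheet = sample_sheet.set_index("sample_id").loc[tpm.columns]
    out = {}
    for cond in ("low", "high"):
        total = _condition_means(tpm, sheet, "total", cond)
        denom = total.where(total > 0)
        for frac in POLYSOME_FRACTIONS:
            out[f"tr_{frac}_{cond}"] = _condition_means(tpm, sheet, frac, cond) / denom
    return pd.DataFrame(out, index=tpm.index)


def translation_efficiency(
    tr: pd.DataFrame, scale: str = "log2", orientation: str = "high_over_low"
) -> pd.Series:
    """TE per gene from the light+heavy-averaged translation ratio.

    A_c = (TR(light, c) + TR(heavy, c)) / 2.  Default: TE = log2(A_high) -
    log2(A_low), so positive TE = more translated in high glucose.
    ``scale="raw"`` gives the plain difference; ``orientation="low_over_high"``
    flips the sign (the literal low-minus-high phrasing).
    """
    if scale not in ("log2", "raw"):
        raise ConfigurationError(f"unknown TE scale {scale!r}")
    if orientation not in ("high_over_low", "low_over_high"):
        raise ConfigurationError(f"unknown TE orientation {orientation!r}")
    a_high = (tr["tr_light_high"] + tr["tr_heavy_high"]) / 2.0
    a_low = (tr["tr_light_low"] + tr["tr_heavy_low"]) / 2.0
    if scale == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            te = np.log2(a_high.where(a_high > 0)) - np.log2(a_low.where(a_low > 0))
    else:
        te = a_high - a_low
    if orientation == "low_over_high":
        te = -te
    return te.rename("te")


def classify_translation_groups(
    te: pd.Series,
    up: float = 0.5,
    down: float = -0.25,
    control: float = 0.01,
) -> pd.Series:
    """Partition genes by TE: UP (>= +0.5), DOWN (<= -0.25), CONTROL
    (|TE| <= 0.01), otherwise UNCLASSIFIED (NaN TE included)."""
    labels = pd.Series("UNCLASSIFIED", index=te.index, name="group")
    labels[te >= up] = "UP"
    labels[te <= down] = "DOWN"
    labels[te.abs() <= control] = "CONTROL"
    return labels


def rank_top_translated(
    tr: pd.DataFrame, n: int = 200, statistic: str = "max"
) -> dict:
    """Per-condition top-n "most translated" genes by translation ratio.

    The ranking statistic is the max (default; configurable to ``mean``) of
    the light- and heavy-polysome TR within each condition, ties broken by
    gene ID.  Reports the two ranked lists, their overlap, and the genes
    with the largest rank shift between conditions.
    """
    if statistic not in ("max", "mean"):
        raise ConfigurationError(f"unknown ranking statistic {statistic!r}")
    agg = np.maximum if statistic == "max" else lambda a, b: (a + b) / 2.0
    stat = {
        cond: agg(tr[f"tr_light_{cond}"], tr[f"tr_heavy_{cond}"]).fillna(-np.inf)
        for cond in ("low", "high")
    }
    if n > len(tr):
        warnings.warn(f"n={n} > {len(tr)} genes; truncating", stacklevel=2)
        n = len(tr)
    order, rank = {}, {}
    for cond, s in stat.items():
        # stable sort after ordering by gene ID: ties break lexicographically
        idx = s.loc[sorted(s.index)].sort_values(ascending=False, kind="mergesort").index
        order[cond] = list(idx[:n])
        rank[cond] = pd.Series(np.arange(1, len(idx) + 1), index=idx)
    top_low, top_high = set(order["low"]), set(order["high"])
    shift = (rank["high"] - rank["low"]).abs().sort_values(ascending=False)
    return {
        "top_low": order["low"],
        "top_high": order["high"],
        "overlap": sorted(top_low & top_high),
        "n_overlap": len(top_low & top_high),
        "only_high": sorted(top_high - top_low),
        "only_low": sorted(top_low - top_high),
        "rank_shift": shift,
        "largest_shift": list(shift.index[:n]),
    }


def polysome_monosome_ratio(
    position: np.ndarray,
    absorbance: np.ndarray,
    mono_window: tuple[float, float],
    poly_window: tuple[float, float],
    baseline: str | float = "min",
) -> float:
    """Polysome/monosome ratio from an A254 gradient trace.

    Trapezoidal area of the polysome window divided by the area of the 80S
    (monosome) window, each after constant-baseline subtraction
    (``baseline="min"``: the window minimum; ``"none"``/0: raw; or an
    explicit constant).
    """
    position = np.asarray(position, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if position.ndim != 1 or position.shape != absorbance.shape:
        raise DataError("position and absorbance must be equal-length vectors")
    if np.any(np.diff(position) <= 0):
        raise DataError("positions must be strictly increasing")

    def area(window: tuple[float, float]) -> float:
        lo, hi = window
        if not (position[0] <= lo < hi <= position[-1]):
            raise DataError(f"window {window} outside trace range")
        grid = np.unique(np.concatenate([[lo, hi], position[(position > lo) & (position < hi)]]))
        y = np.interp(grid, position, absorbance)
        if baseline == "min":
            y = y - y.min()
        elif baseline not in ("none", 0, 0.0):
            y = y - float(baseline)
        return float(np.trapezoid(np.clip(y, 0, None), grid))

    a_mono = area(mono_window)
    if a_mono <= 0:
        raise DataError("80S monosome peak area is zero")
    return area(poly_window) / a_mono


def build_log_ratio_matrix(
    tpm: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene log2(mean TPM high / mean TPM low) for each polysome fraction.

    This genes x {mono, light, heavy} matrix is the clustering substrate.
    Genes with a zero mean in either condition of any fraction are excluded
    (recorded in ``df.attrs["excluded"]``).
    """
    validate_sample_sheet(sample_sheet, tpm.columns)
    sheet = sample_sheet.set_index("sample_id").loc[tpm.columns]
    cols = {}
    for frac in POLYSOME_FRACTIONS:
        high = _condition_means(tpm, sheet, frac, "high")
        low = _condition_means(tpm, sheet, frac, "low")
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[frac] = np.log2(high.where(high > 0)) - np.log2(low.where(low > 0))
    mat = pd.DataFrame(cols, index=tpm.index)
    finite = mat.notna().all(axis=1) & np.isfinite(mat).all(axis=1)
    out = mat.loc[finite]
    out.attrs["excluded"] = sorted(mat.index[~finite])
    return out
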