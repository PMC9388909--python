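"""Normalisation, expression/variability filters and sample-level QC.

Counts tables are plain pandas DataFrames (genes x samples) accompanied by a
sample sheet with columns ``sample_id``, ``condition`` (low/high),
``fraction`` (total/mono/light/heavy) and ``replicate``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DataError

__all__ = [
    "validate_sample_sheet",
    "cpm",
    "tpm_from_counts",
    "filter_low_expression",
    "filter_by_cv",
    "qc_sample_clustering",
]

FRACTIONS = ("total", "mono", "light", "heavy")
CONDITIONS = ("low", "high")


def validate_sample_sheet(sheet: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    required = {"sample_id", "condition", "fraction", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise DataError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicated sample IDs: {dup}")
    bad = set(sheet["fraction"]) - set(FRACTIONS)
    if bad:
        raise DataError(f"unknown fractions {sorted(bad)}; expected {FRACTIONS}")
    bad = set(sheet["condition"]) - set(CONDITIONS)
    if bad:
        raise DataError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    if sample_ids is not None:
        absent = set(sample_ids) - set(sheet["sample_id"])
        if absent:
            raise DataError(f"samples absent from sample sheet: {sorted(absent)}")
    return sheet


def cpm(counts: pd.DataFrame, log: bool = False, prior_count: float = 0.5) -> pd.DataFrame:
    """Counts per million per library; optionally log2(CPM + prior_count)."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"zero library size for sample(s): {list(zero.index)}")
    out = counts.div(totals, axis=1) * 1e6
    if log:
        out = np.log2(out + prior_count)
    return out


def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and per-gene effective lengths.

    rate = count/length, TPM = rate / sum(rate) * 1e6 per sample.  The
    effective length here is the annotated transcript length (no
    fragment-length correction).
    """
    lengths = pd.Series(lengths)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataError(f"missing lengths for genes: {list(missing[:10])}")
    lens = lengths.loc[counts.index].astype(float)
    if (lens <= 0).any():
        raise DataError(
            f"non-positive lengths for genes: {list(lens.index[lens <= 0][:10])}"
        )
    rate = counts.div(lens, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def filter_low_expression(cpm_mat: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Expression filter: keep a gene iff CPM >= threshold in every sample.

    Returns a per-gene mask frame with columns ``keep`` and ``reason``
    (the failing rule, empty when kept).  The boundary is inclusive: a gene
    at exactly the threshold everywhere is kept (genes *smaller than* the
    threshold in at least one sample are discarded).
    """
    min_cpm = cpm_mat.min(axis=1)
    keep = min_cpm >= threshold
    reason = np.where(keep, "", f"cpm<{threshold:g} in >=1 sample")
    return pd.DataFrame({"keep": keep, "reason": reason}, index=cpm_mat.index)


def filter_by_cv(
    cpm_mat: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    cv_threshold: float = 0.75,
    mean_cpm_threshold: float | None = 4.0,
) -> pd.DataFrame:
    """Variability filter: retain genes reproducible within replicate groups.

    A replicate group is one (fraction, condition) cell.  The default rule
    retains genes whose maximum within-group coefficient of variation
    (sd/mean) is below ``cv_threshold`` AND whose overall mean CPM exceeds
    ``mean_cpm_threshold``; pass ``mean_cpm_threshold=None`` to drop the
    mean clause.  Returns a mask frame as :func:`filter_low_expression`.
    """
    validate_sample_sheet(sample_sheet, cpm_mat.columns)
    sheet = sample_sheet.set_index("sample_id").loc[cpm_mat.columns]
    max_cv = pd.Series(0.0, index=cpm_mat.index)
    for (_, _), grp in sheet.groupby(["fraction", "condition"], sort=False):
        cols = grp.index
        if len(cols) < 2:
            raise ConfigurationError(
                f"replicate group of size 1 ({grp['fraction'].iloc[0]}/"
                f"{grp['condition'].iloc[0]}): CV undefined"
            )
        sub = cpm_mat[cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = (sd / mean).replace([np.inf, -np.inf], np.nan).fillna(0.0)
        max_cv = np.maximum(max_cv, cv)
    keep = max_cv < cv_threshold
    reason = pd.Series(np.where(keep, "", f"cv>={cv_threshold:g}"), index=cpm_mat.index)
    if mean_cpm_threshold is not None:
        mean_ok = cpm_mat.mean(axis=1) > mean_cpm_threshold
        reason[keep & ~mean_ok] = f"mean_cpm<={mean_cpm_threshold:g}"
        keep &= mean_ok
    return pd.DataFrame({"keep": keep, "reason": reason}, index=cpm_mat.index)


def qc_sample_clustering(expr: pd.DataFrame) -> dict:
    """Sample QC: Ward dendrogram + first two principal components.

    Ward linkage on Euclidean distances between samples (the squared-
    distance Lance-Williams update, i.e. the Ward.D2 convention).  Returns
    ``{"linkage": Z, "order": leaves, "newick": str, "pca": DataFrame}``.
    """
    if expr.shape[1] < 3:
        raise DataError("need at least 3 samples for QC clustering")
    X = expr.T.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        warnings.warn("constant expression matrix: PCA is degenerate", stacklevel=2)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    order = [expr.columns[i] for i in hierarchy.leaves_list(Z)]
    newick = _tree_to_newick(hierarchy.to_tree(Z), list(expr.columns))
    n_comp = min(2, X.shape[0], X.shape[1])
    coords = PCA(n_components=n_comp).fit_transform(X - X.mean(axis=0))
    pca = pd.DataFrame(
        coords, index=expr.columns, columns=[f"PC{i+1}" for i in range(n_comp)]
    )
    return {"linkage": Z, "order": order, "newick": newick, "pca": pca}


def _tree_to_newick(node, labels: list[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        return f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:.6g}"

    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"
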