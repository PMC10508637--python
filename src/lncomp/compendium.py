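"""Expression-compendium assembly and QC.

Pipeline order matters: detection calls are made on RAW per-array
intensities against per-array negative-control thresholds; log2 +
quantile normalization feeds only the correlation/network stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------- normalization

def log2_and_quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform a raw matrix, then quantile-normalize across columns.

    After normalization each column's sorted values equal the across-column
    mean of order statistics; tied values within a column receive the mean
    of the reference values over their tied rank span.
    """
    values = matrix.to_numpy(dtype=float)
    if np.any(values <= 0):
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive raw intensity at probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}"
        )
    logged = np.log2(values)
    return pd.DataFrame(
        quantile_normalize(logged), index=matrix.index, columns=matrix.columns
    )


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile normalization of a 2-D array (rows = features, cols = arrays)."""
    n_rows, n_cols = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col_sorted = sorted_vals[:, j]
        assigned = reference.copy()
        # ties share the mean reference value over their rank span
        start = 0
        for i in range(1, n_rows + 1):
            if i == n_rows or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    assigned[start:i] = reference[start:i].mean()
                start = i
        out[order[:, j], j] = assigned
    return out


# ------------------------------------------------------------------ QC / outliers

@dataclass
class CompendiumQC:
    spearman: pd.DataFrame
    median_rho: pd.Series
    sample_outliers: pd.Series = field(default=None)  # type: ignore[assignment]
    series_outliers: pd.Series = field(default=None)  # type: ignore[assignment]


def compute_qc(matrix: pd.DataFrame) -> CompendiumQC:
    """Pairwise Spearman correlations between samples and per-sample medians."""
    if matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for QC")
    rho, _ = stats.spearmanr(matrix.to_numpy(), axis=0)
    rho = np.atleast_2d(rho)
    spearman = pd.DataFrame(rho, index=matrix.columns, columns=matrix.columns)
    off_diag = spearman.where(~np.eye(len(spearman), dtype=bool))
    median_rho = off_diag.median(axis=1)
    return CompendiumQC(spearman=spearman, median_rho=median_rho)


def _tukey_floor(medians: np.ndarray, floor: float) -> float:
    q1, q3 = np.percentile(medians, [25, 75])
    return max(floor, q1 - 1.5 * (q3 - q1))


def screen_outliers(
    qc: CompendiumQC, meta: pd.DataFrame | None = None, floor: float = 0.5
) -> CompendiumQC:
    """Flag samples (and series, when metadata is given) whose median
    correlation falls below max(floor, Q1 - 1.5*IQR) of the medians.
    """
    if len(qc.median_rho) < 3:
        raise ValueError("need >= 3 samples to screen outliers")
    medians = qc.median_rho.to_numpy(dtype=float)
    cutoff = _tukey_floor(medians, floor)
    qc.sample_outliers = pd.Series(medians < cutoff, index=qc.median_rho.index)
    if meta is not None:
        series_of = meta.set_index("sample_id")["series_id"]
        series_means = qc.median_rho.groupby(series_of.reindex(qc.median_rho.index)).mean()
        if len(series_means) >= 2:
            s_cut = _tukey_floor(series_means.to_numpy(dtype=float), floor)
            qc.series_outliers = series_means < s_cut
        else:
            qc.series_outliers = pd.Series(False, index=series_means.index)
    return qc


# ----------------------------------------------------------------- detection

def detection_threshold(
    negctl: pd.DataFrame, percentile: float = 95.0, pooled: bool = False
) -> pd.Series:
    """Per-array detection threshold: the given percentile (linear
    interpolation between closest ranks) of negative-control raw
    intensities. ``pooled=True`` uses one threshold from all arrays' controls.
    """
    if negctl.shape[0] < 20:
        raise ValueError(f"need >= 20 negative controls, got {negctl.shape[0]}")
    if pooled:
        t = float(np.percentile(negctl.to_numpy(dtype=float).ravel(), percentile))
        return pd.Series(t, index=negctl.columns)
    thresholds = np.percentile(negctl.to_numpy(dtype=float), percentile, axis=0)
    return pd.Series(thresholds, index=negctl.columns)


def call_detection(matrix: pd.DataFrame, thresholds: pd.Series) -> pd.DataFrame:
    """Boolean detection flags: raw intensity strictly above the array threshold."""
    missing = [c for c in matrix.columns if c not in thresholds.index]
    if missing:
        raise ValueError(f"arrays missing a detection threshold: {missing[:5]}")
    return matrix.gt(thresholds[matrix.columns], axis=1)


def drop_never_expressed(detection: pd.DataFrame) -> tuple[pd.Index, int]:
    """Retained probe ids (detected in >= 1 sample) and the dropped count."""
    detected_any = detection.any(axis=1)
    retained = detection.index[detected_any]
    return retained, int((~detected_any).sum())


# -------------------------------------------------------- tissue expression

@dataclass
class TissueExpressionSummary:
    expressed: pd.DataFrame        # probe x tissue boolean (> frac rule)
    n_tissues: pd.Series           # per-probe count of expressing tissues
    tissue_specific: dict[str, list[str]]
    per_tissue_totals: pd.Series


def tissue_expression(
    detection: pd.DataFrame, meta: pd.DataFrame, frac: float = 0.65
) -> TissueExpressionSummary:
    """Per-tissue expression calls: a probe is expressed in a tissue iff its
    detection fraction over that tissue's samples is strictly > ``frac``.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    unknown = [s for s in detection.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"samples without metadata: {unknown[:5]}")
    tissues = meta.loc[detection.columns, "tissue"]
    frac_by_tissue = detection.T.groupby(tissues.values).mean().T
    expressed = frac_by_tissue > frac
    n_tissues = expressed.sum(axis=1)
    specific = {
        t: sorted(expressed.index[expressed[t] & (n_tissues == 1)])
        for t in expressed.columns
    }
    return TissueExpressionSummary(
        expressed=expressed,
        n_tissues=n_tissues,
        tissue_specific=specific,
        per_tissue_totals=expressed.sum(axis=0).sort_values(ascending=False),
    )


def expression_breadth_report(
    summary: TissueExpressionSummary, category: pd.Series
) -> pd.DataFrame:
    """Counts and within-category percentages of probes by the number of
    tissues expressing them, split by category (mRNA vs lncRNA).
    """
    common = summary.n_tissues.index.intersection(category.index)
    n_tissues = summary.n_tissues.loc[common]
    cats = category.loc[common]
    n_bins = summary.expressed.shape[1]
    rows = []
    for cat in ["mRNA", "lncRNA"]:
        mask = cats == cat
        total = int(mask.sum())
        for k in range(n_bins + 1):
            count = int(((n_tissues == k) & mask).sum())
            rows.append({
                "n_tissues": k,
                "category": cat,
                "count": count,
                "percent": (100.0 * count / total) if total else 0.0,
            })
    return pd.DataFrame(rows)


def breadth_share(n_in_bin: int, n_total: int) -> float:
    """Percentage share of a breadth bin among all retained probes."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= n_in_bin <= n_total):
        raise ValueError("bin count outside [0, total]")
    return 100.0 * n_in_bin / n_total
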