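"""Signed weighted co-expression network: adjacency, soft-threshold
selection, topological overlap, module detection, eigengenes, module
merging, module-trait correlation and module composition statistics.

The module cut deliberately uses a static-height cut on an average-linkage
tree of 1 - TOM plus a minimum-size rule, not the dynamic hybrid tree cut
of reference implementations; the cut height defaults to a quantile of the
merge heights and is configurable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

#: Deterministic module label palette, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class NetworkParams:
    beta: int = 12
    scale_free_r2_target: float = 0.9
    mean_connectivity_cap: float = 100.0
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    cut_height_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1 or int(self.beta) != self.beta:
            raise ValueError("beta must be an integer >= 1")
        if not (0 < self.scale_free_r2_target < 1):
            raise ValueError("scale_free_r2_target must be in (0, 1)")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not (0 <= self.merge_cut_height <= 1):
            raise ValueError("merge_cut_height must be in [0, 1]")


# ------------------------------------------------------------------ adjacency

def signed_adjacency(correlations: np.ndarray, beta: int = 12) -> np.ndarray:
    """Signed weighted adjacency a_ij = ((1 + r_ij) / 2) ** beta, diagonal 1."""
    r = np.asarray(correlations, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlations outside [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    a = ((1.0 + r) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """k_i = sum_{j != i} a_ij."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit: R^2 (and slope) of log10(freq) on
    log10(mean k) over equal-width connectivity bins; empty bins dropped.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size:
            mean_k.append(members.mean())
            freq.append(members.size / k.size)
    if len(mean_k) < 2:
        raise ValueError("not enough non-empty connectivity bins")
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(freq))
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2), float(slope)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_betas: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.9,
    mean_k_cap: float = 100.0,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest beta reaching the scale-free R^2 target (with a
    negative slope) under the mean-connectivity cap; falls back to the beta
    maximizing R^2 with a warning.

    ``matrix`` is probes x samples; correlations are between probes.
    """
    r = np.corrcoef(matrix.to_numpy(dtype=float))
    rows = []
    for beta in candidate_betas:
        a = signed_adjacency(r, beta)
        k = connectivity(a)
        r2, slope = scale_free_fit(k)
        rows.append({"beta": beta, "r_squared": r2, "slope": slope, "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows)
    ok = diag[(diag.r_squared >= r2_target) & (diag.slope < 0) & (diag.mean_k < mean_k_cap)]
    if len(ok):
        chosen = int(ok.iloc[0]["beta"])
    else:
        chosen = int(diag.loc[diag.r_squared.idxmax(), "beta"])
        warnings.warn(
            f"no candidate beta reached R^2 >= {r2_target} with mean k < "
            f"{mean_k_cap}; falling back to beta={chosen} (max R^2)"
        )
    return chosen, diag


# ------------------------------------------------------------------------ TOM

def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency values outside [0, 1]")
    k = connectivity(a)
    shared = a @ a - 2.0 * a  # removes u = i and u = j terms (diag = 1)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten with TOM_ii = 1 below
    assert np.all(denom > 0), "TOM denominator must be positive for valid adjacency"
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


# -------------------------------------------------------------------- modules

def cut_modules(
    dissimilarity: np.ndarray,
    probe_ids: list[str],
    min_module_size: int = 30,
    cut_height: float | None = None,
    cut_height_quantile: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM cut at a static height.

    The cut height defaults to the midpoint of the largest gap between
    consecutive sorted merge heights (a deterministic separation of the
    strongest cluster structure); a fixed height or a merge-height quantile
    may be given instead. Clusters below ``min_module_size`` become grey;
    surviving clusters are labeled from a fixed palette by decreasing size
    (ties broken by the smallest member index).
    """
    n = len(probe_ids)
    if dissimilarity.shape != (n, n):
        raise ValueError("dissimilarity shape does not match probe_ids")
    if n < min_module_size:
        warnings.warn("fewer probes than min_module_size: everything grey")
        return pd.Series(GREY, index=probe_ids, name="module")
    d = (dissimilarity + dissimilarity.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    heights = link[:, 2]
    if cut_height is None:
        if cut_height_quantile is not None:
            cut_height = float(np.quantile(heights, cut_height_quantile))
        else:
            ordered = np.sort(heights)
            gaps = np.diff(ordered)
            i = int(np.argmax(gaps)) if len(gaps) else 0
            cut_height = float((ordered[i] + ordered[min(i + 1, len(ordered) - 1)]) / 2.0)
    raw = fcluster(link, t=cut_height, criterion="distance")
    return _label_clusters(raw, probe_ids, min_module_size)


def _label_clusters(
    raw: np.ndarray, probe_ids: list[str], min_module_size: int
) -> pd.Series:
    sizes: dict[int, int] = {}
    first_idx: dict[int, int] = {}
    for i, c in enumerate(raw):
        sizes[c] = sizes.get(c, 0) + 1
        first_idx.setdefault(c, i)
    keep = [c for c, s in sizes.items() if s >= min_module_size]
    keep.sort(key=lambda c: (-sizes[c], first_idx[c]))
    palette = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(keep)}
    labels = [palette.get(c, GREY) for c in raw]
    return pd.Series(labels, index=probe_ids, name="module")


# ----------------------------------------------------------------- eigengenes

@dataclass
class EigengeneSet:
    eigengenes: pd.DataFrame          # samples x modules, unit-norm columns
    variance_explained: pd.Series


def module_eigengene(matrix: pd.DataFrame, assignment: pd.Series) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Probes are standardized across samples; the eigengene is the first right
    singular vector, sign-oriented so its mean correlation with module
    members is >= 0. Zero-variance probes are excluded with a warning.
    """
    eg: dict[str, np.ndarray] = {}
    ve: dict[str, float] = {}
    for module in sorted(set(assignment) - {GREY}):
        members = assignment.index[assignment == module]
        sub = matrix.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if np.any(sd == 0):
            warnings.warn(f"module {module}: excluding zero-variance probes from eigengene")
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        if sub.shape[0] < 2:
            raise ValueError(f"module {module} has < 2 usable members")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        vec = vt[0]
        cors = _row_correlations(z, vec)
        if np.mean(cors) < 0 or (np.mean(cors) == 0 and cors[0] < 0):
            vec = -vec
        eg[module] = vec
        ve[module] = float(s[0] ** 2 / np.sum(s**2))
    return EigengeneSet(
        eigengenes=pd.DataFrame(eg, index=matrix.columns),
        variance_explained=pd.Series(ve, dtype=float),
    )


def _row_correlations(z: np.ndarray, vec: np.ndarray) -> np.ndarray:
    vc = vec - vec.mean()
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(zc, axis=1) * np.linalg.norm(vc)
    return (zc @ vc) / denom


def merge_close_modules(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    cut: float = 0.25,
) -> tuple[pd.Series, EigengeneSet]:
    """Iteratively merge modules whose eigengene dissimilarity (1 - Pearson r)
    is below ``cut`` (average linkage over eigengenes), recomputing
    eigengenes after each round until stable. The merged module keeps the
    label of its largest constituent.
    """
    assignment = assignment.copy()
    egs = module_eigengene(matrix, assignment)
    if cut <= 0:
        return assignment, egs
    while True:
        modules = list(egs.eigengenes.columns)
        if len(modules) < 2:
            break
        corr = np.corrcoef(egs.eigengenes.to_numpy(dtype=float).T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        link = average(squareform(np.clip(diss, 0, None), checks=False))
        groups = fcluster(link, t=cut, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        sizes = assignment.value_counts()
        relabel: dict[str, str] = {}
        for g in set(groups):
            members = [m for m, gg in zip(modules, groups) if gg == g]
            target = max(members, key=lambda m: (sizes.get(m, 0), m))
            for m in members:
                relabel[m] = target
        assignment = assignment.map(lambda m: relabel.get(m, m))
        egs = module_eigengene(matrix, assignment)
    return assignment, egs


# ------------------------------------------------------------ trait correlation

def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if np.isnan(r):
        return float("nan")
    if 1.0 - r * r < 1e-14:  # numerically perfect correlation
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with one-hot tissue
    indicators; long table (module, tissue, r, p)."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    tissues = meta.loc[eigengenes.index, "tissue"]
    n = len(eigengenes)
    if n < 3:
        raise ValueError("need >= 3 samples")
    rows = []
    for tissue in sorted(tissues.unique()):
        indicator = (tissues == tissue).to_numpy(dtype=float)
        for module in eigengenes.columns:
            vec = eigengenes[module].to_numpy(dtype=float)
            if indicator.std() == 0 or vec.std() == 0:
                r: float = float("nan")
            else:
                r = float(np.corrcoef(vec, indicator)[0, 1])
            rows.append({
                "module": module, "tissue": tissue,
                "r": r, "p": correlation_p_value(r, n),
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------- composition

def module_composition(
    assignment: pd.Series,
    category: pd.Series,
    tf_ids: set[str] | None = None,
    hkg_ids: set[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Per-module mRNA/lncRNA/TF/housekeeping counts and fractions, plus the
    across-module Pearson correlation (r, p) between the housekeeping
    fraction and the lncRNA fraction.
    """
    modules = sorted(set(assignment))
    if not modules:
        raise ValueError("empty module assignment")
    tf_ids = tf_ids or set()
    hkg_ids = hkg_ids or set()
    rows = []
    for module in modules:
        members = assignment.index[assignment == module]
        cats = category.reindex(members)
        n_m = int((cats == "mRNA").sum())
        n_l = int((cats == "lncRNA").sum())
        n_tf = sum(1 for p in members if p in tf_ids)
        n_hkg = sum(1 for p in members if p in hkg_ids)
        size = len(members)
        rows.append({
            "module": module, "size": size, "n_mRNA": n_m, "n_lncRNA": n_l,
            "n_TF": n_tf, "n_HKG": n_hkg,
            "frac_lncRNA": n_l / size if size else float("nan"),
            "frac_HKG": n_hkg / size if size else float("nan"),
        })
    table = pd.DataFrame(rows)
    non_grey = table[table.module != GREY]
    if len(non_grey) < 3:
        warnings.warn("fewer than 3 modules: HKG-vs-lncRNA correlation undefined")
        return table, float("nan"), float("nan")
    r, p = stats.pearsonr(non_grey.frac_HKG, non_grey.frac_lncRNA)
    return table, float(r), float(p)


def module_size_from_counts(n_mrna: int, n_lncrna: int, n_tf: int = 0) -> int:
    """Module-size bookkeeping from tabulated component counts (mRNAs,
    lncRNAs, and separately tabulated transcription factors)."""
    if min(n_mrna, n_lncrna, n_tf) < 0:
        raise ValueError("counts must be non-negative")
    return n_mrna + n_lncrna + n_tf
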