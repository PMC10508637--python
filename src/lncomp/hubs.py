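"""Within-module lncRNA-mRNA-TF correlation networks and hub scoring.

Edges keep within-module pairs with Pearson r strictly > ``r_min`` (signed:
anti-correlated pairs never qualify; an absolute-value mode is available)
and two-sided p strictly < ``alpha``. Hubs maximize the sum of edge
correlation coefficients, with roles kept distinct: the "gene" hubs exclude
transcription factors.
"""
from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import correlation_p_value


def cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, correlation_p_value(r, n)


def _corr_and_p_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    rr = np.clip(np.abs(r), 0.0, 1.0 - 1e-15)
    t = rr * np.sqrt(n - 2) / np.sqrt(1.0 - rr**2)
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-12] = 0.0
    return r, p


def build_edges(
    matrix: pd.DataFrame,
    assignment: pd.Series,
    kinds: pd.Series,
    r_min: float = 0.7,
    alpha: float = 0.05,
    use_absolute: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-module edge lists over all within-module unordered pairs.

    ``kinds`` maps probe -> {"lncRNA", "mRNA", "TF"} (TF implies an mRNA
    acting as a transcription factor). Returns module -> DataFrame with
    columns (node_a, node_b, r, p, kind_a, kind_b); node_a < node_b.
    """
    untagged = [p for p in assignment.index if p not in kinds.index]
    if untagged:
        raise ValueError(f"probes without kind tags: {untagged[:5]}")
    edges: dict[str, pd.DataFrame] = {}
    for module in sorted(set(assignment)):
        members = sorted(assignment.index[assignment == module])
        cols = ["node_a", "node_b", "r", "p", "kind_a", "kind_b"]
        if len(members) < 2:
            edges[module] = pd.DataFrame(columns=cols)
            continue
        values = matrix.loc[members].to_numpy(dtype=float)
        r, p = _corr_and_p_matrix(values)
        stat = np.abs(r) if use_absolute else r
        iu, ju = np.triu_indices(len(members), k=1)
        keep = (stat[iu, ju] > r_min) & (p[iu, ju] < alpha)
        edges[module] = pd.DataFrame({
            "node_a": [members[i] for i in iu[keep]],
            "node_b": [members[j] for j in ju[keep]],
            "r": r[iu, ju][keep],
            "p": p[iu, ju][keep],
            "kind_a": [kinds[members[i]] for i in iu[keep]],
            "kind_b": [kinds[members[j]] for j in ju[keep]],
        })
    return edges


def _score(edge_table: pd.DataFrame, node_kind: str, partner_kinds: set[str] | None) -> pd.Series:
    """Sum of r per node of ``node_kind`` over edges to partners of
    ``partner_kinds`` (None = any partner)."""
    scores: dict[str, float] = {}
    for row in edge_table.itertuples(index=False):
        for node, kind, partner_kind in (
            (row.node_a, row.kind_a, row.kind_b),
            (row.node_b, row.kind_b, row.kind_a),
        ):
            if kind != node_kind:
                continue
            if partner_kinds is not None and partner_kind not in partner_kinds:
                continue
            scores[node] = scores.get(node, 0.0) + row.r
    return pd.Series(scores, dtype=float)


def _argmax(scores: pd.Series) -> tuple[str | None, float]:
    if scores.empty:
        return None, float("nan")
    best = scores.max()
    winners = sorted(scores.index[scores == best])
    return winners[0], float(best)


def find_hubs(edge_table: pd.DataFrame) -> dict:
    """One hub-table row: hub TFs by lncRNA- and mRNA-partner correlation
    sums, hub lncRNA and hub (non-TF) mRNA by all-partner sums, plus counts
    of distinct nodes of each kind appearing in >= 1 edge. Ties break toward
    the lexicographically smallest node id."""
    lnc_tf, lnc_tf_score = _argmax(_score(edge_table, "TF", {"lncRNA"}))
    mrna_tf, mrna_tf_score = _argmax(_score(edge_table, "TF", {"mRNA"}))
    hub_lnc, hub_lnc_score = _argmax(_score(edge_table, "lncRNA", None))
    hub_mrna, hub_mrna_score = _argmax(_score(edge_table, "mRNA", None))
    nodes = pd.concat([
        edge_table[["node_a", "kind_a"]].rename(columns={"node_a": "node", "kind_a": "kind"}),
        edge_table[["node_b", "kind_b"]].rename(columns={"node_b": "node", "kind_b": "kind"}),
    ]).drop_duplicates() if len(edge_table) else pd.DataFrame(columns=["node", "kind"])
    kind_counts = nodes.groupby("kind")["node"].nunique() if len(nodes) else pd.Series(dtype=int)
    return {
        "lncRNA_hub_TF": lnc_tf, "lncRNA_hub_TF_score": lnc_tf_score,
        "mRNA_hub_TF": mrna_tf, "mRNA_hub_TF_score": mrna_tf_score,
        "hub_lncRNA": hub_lnc, "hub_lncRNA_score": hub_lnc_score,
        "hub_mRNA": hub_mrna, "hub_mRNA_score": hub_mrna_score,
        "n_sig_lncRNA": int(kind_counts.get("lncRNA", 0)),
        "n_sig_mRNA": int(kind_counts.get("mRNA", 0)),
        "n_sig_TF": int(kind_counts.get("TF", 0)),
        "n_edges": len(edge_table),
    }


def hub_table(edges: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    rows = []
    for module in sorted(edges):
        row = {"module": module}
        row.update(find_hubs(edges[module]))
        rows.append(row)
    return pd.DataFrame(rows)
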