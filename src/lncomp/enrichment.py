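"""Hypergeometric over-representation of gene sets in module membership
with Benjamini-Hochberg control.

Adjustment is applied within each namespace (BP/CC/MF/pathway) separately;
the q column equals the BH-adjusted p (no pi0 estimation).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p = P(X >= k) for drawing ``n`` genes from a
    universe of ``N`` containing ``K`` term members and observing ``k`` hits.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    # survival function is computed in log space internally by scipy
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich_module(
    module_genes: Iterable[str],
    gene_sets: Mapping[str, tuple[str, list[str]]],
    universe: Iterable[str],
    namespaces: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    q_cap: float = 0.2,
    filter_significant: bool = True,
) -> pd.DataFrame:
    """Test every gene set with >= 1 universe member and >= 1 module hit.

    ``namespaces`` maps term_id -> namespace tag; adjustment is performed
    within each namespace. Module genes outside the universe are dropped
    with a warning. Returns the (optionally filtered) result table sorted by
    p then term_id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    module_set = set(module_genes)
    outside = module_set - universe_set
    if outside:
        warnings.warn(f"{len(outside)} module genes outside universe dropped")
        module_set &= universe_set
    N = len(universe_set)
    n = len(module_set)
    namespaces = namespaces or {}
    rows = []
    for term_id, (term_name, members) in gene_sets.items():
        term_members = set(members) & universe_set
        K = len(term_members)
        if K == 0:
            continue
        k = len(term_members & module_set)
        if k == 0:
            continue
        rows.append({
            "term_id": term_id, "term_name": term_name,
            "namespace": namespaces.get(term_id, "default"),
            "k": k, "K": K, "n": n, "N": N,
            "p": hypergeometric_p(k, K, n, N),
        })
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "namespace", "k", "K", "n", "N",
                     "p", "p_adj", "q"]
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    for ns, idx in table.groupby("namespace").groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"])
    table["q"] = table["p_adj"]
    if filter_significant:
        table = table[(table.p_adj < alpha) & (table.q < q_cap)]
    return table.sort_values(["p", "term_id"]).reset_index(drop=True)


def enrichment_summary(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-module counts of enriched terms per namespace."""
    rows = []
    for module, table in results.items():
        if len(table):
            counts = table.groupby("namespace").size()
        else:
            counts = pd.Series(dtype=int)
        for ns, count in counts.items():
            rows.append({"module": module, "namespace": ns, "n_enriched": int(count)})
        if not len(counts):
            rows.append({"module": module, "namespace": "default", "n_enriched": 0})
    return pd.DataFrame(rows)
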