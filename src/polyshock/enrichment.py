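"""Over-representation analysis of gene sets by the hypergeometric test."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .de import adjust_bh

__all__ = ["ora", "read_annotations"]


def read_annotations(path: str) -> pd.DataFrame:
    """Read a long-format annotation TSV (term_id, term_name, gene_id)
    or a GMT file (term, description, genes...)."""
    with open(path) as fh:
        first = fh.readline()
    if first.count("\t") >= 2 and first.split("\t")[0] not in ("term_id",):
        # could still be headerless long format; GMT rows have >=3 fields
        pass
    try:
        tab = pd.read_csv(path, sep="\t")
        if {"term_id", "term_name", "gene_id"} <= set(tab.columns):
            return tab[["term_id", "term_name", "gene_id"]]
    except Exception:
        pass
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, name = parts[0], parts[1]
            for g in parts[2:]:
                if g:
                    rows.append({"term_id": term, "term_name": name, "gene_id": g})
    return pd.DataFrame(rows)


def ora(
    query_set: Iterable[str],
    universe: Iterable[str],
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_set`` in each term.

    For a universe of N genes, a term of K genes, a query of n genes
    and overlap k, the one-sided upper-tail p-value is P[X >= k] with
    X ~ Hypergeometric(N, K, n).  Terms with zero overlap are kept with
    p = 1.  P-values are BH-adjusted across terms and the table is
    sorted by adjusted p.
    """
    universe = set(universe)
    query = set(query_set)
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:5]}")
    if isinstance(annotation, pd.DataFrame):
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for term, sub in annotation.groupby("term_id"):
            terms[str(term)] = set(sub["gene_id"])
            names[str(term)] = str(sub["term_name"].iloc[0])
    else:
        terms = {str(t): set(g) for t, g in annotation.items()}
        names = {t: t for t in terms}
    if not terms:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "overlap", "set_size",
                "term_size", "universe_size", "pvalue", "padj",
            ]
        )
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(terms):
        members = terms[term_id] & universe
        K = len(members)
        k = len(members & query)
        if K == 0:
            continue
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": names[term_id],
                "overlap": k,
                "set_size": n,
                "term_size": K,
                "universe_size": N,
                "pvalue": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "term_name", "overlap", "set_size",
                "term_size", "universe_size", "pvalue", "padj", "significant",
            ]
        )
    out = pd.DataFrame(rows)
    out["padj"] = adjust_bh(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    return out.sort_values(["padj", "pvalue", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
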