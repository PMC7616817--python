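"""Weighted gene coexpression networks and module preservation.

Networks are built from biweight midcorrelations with a signed-hybrid
adjacency (positive correlations raised to a soft power, negative
correlations zeroed).  Modules come from average-linkage hierarchical
clustering of the adjacency dissimilarity with a static cut, followed
by iterative merging of modules whose eigengenes correlate above a
threshold.  Preservation of reference modules in a test network is
assessed with seven module statistics against a permutation null of
random same-size gene sets; a module counts as preserved when at
least five of the seven statistics are significant at p < 0.05.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import de

__all__ = [
    "filter_low_counts",
    "vst",
    "bicor",
    "bicor_matrix",
    "adjacency_signed_hybrid",
    "detect_modules",
    "module_eigengene",
    "degree",
    "hub_overrep",
    "preservation",
]

PRESERVATION_STATS = [
    "avg.weight",
    "coherence",
    "cor.cor",
    "cor.degree",
    "cor.contrib",
    "avg.cor",
    "avg.contrib",
]
DEFAULT_BETA = 6.0
DEFAULT_MIN_SIZE = 30
DEFAULT_MERGE_CUT = 0.8
DEFAULT_CUT_FRACTION = 0.995
UNASSIGNED = "unassigned"


def filter_low_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with less than one count in at least 50% of samples.

    A gene is kept iff it has >= 1 count in strictly more than half of
    the samples (a gene zero in exactly half the samples is removed).
    """
    if counts.empty:
        raise ValueError("empty count matrix")
    expressed = (counts >= 1).sum(axis=1)
    return counts.loc[expressed > 0.5 * counts.shape[1]]


def vst(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(normalized count + 1)."""
    if factors is None:
        factors = de.size_factors(counts)
    return np.log2(de.normalize(counts, factors) + 1.0)


def _bicor_weights(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight-centered rows of x (genes x samples); rows with
    zero MAD fall back to mean-centering (Pearson)."""
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    out = np.empty_like(x, dtype=float)
    ok = (mad[:, 0] > 0)
    if ok.any():
        u = (x[ok] - med[ok]) / (9.0 * mad[ok])
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        out[ok] = (x[ok] - med[ok]) * w
    if (~ok).any():
        out[~ok] = x[~ok] - x[~ok].mean(axis=1, keepdims=True)
    return out


def bicor_matrix(expr: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between all gene pairs (genes x samples)."""
    x = np.asarray(expr, dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    xw = _bicor_weights(x)
    norms = np.sqrt((xw**2).sum(axis=1))
    if (norms == 0).any():
        raise ValueError("constant gene encountered")
    xw = xw / norms[:, None]
    c = xw @ xw.T
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation of two vectors.

    Weights w_i = (1 - u_i^2)^2 for |u_i| < 1, u_i = (x_i - med) /
    (9 MAD); a vector with zero MAD falls back to Pearson centering.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("vectors must have equal length >= 4")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector")
    return float(bicor_matrix(np.vstack([x, y]))[0, 1])


def adjacency_signed_hybrid(cor: np.ndarray, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Signed-hybrid soft adjacency: cor^beta for cor > 0, else 0."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    adj = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def module_eigengene(expr: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a module's expression across samples.

    Gene profiles are z-scored before the SVD; the eigengene sign is
    oriented to correlate positively with the module's mean expression
    profile.  Returns (eigengene over samples, variance explained).
    """
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(eig, index=expr.columns, name="eigengene"), var_explained


def detect_modules(
    expr: pd.DataFrame,
    beta: float = DEFAULT_BETA,
    min_size: int = DEFAULT_MIN_SIZE,
    merge_cut: float = DEFAULT_MERGE_CUT,
    cut_fraction: float = DEFAULT_CUT_FRACTION,
) -> pd.Series:
    """Detect coexpression modules by clustering the adjacency.

    Average-linkage hierarchical clustering of 1 - adjacency, static
    cut at ``cut_fraction`` of the maximum merge height; clusters below
    ``min_size`` go to the unassigned background.  Modules whose
    eigengenes correlate above ``merge_cut`` are merged iteratively
    (most correlated pair first).  Returns gene -> module label
    (M1, M2, ... by decreasing size, plus "unassigned").
    """
    if len(expr) < 2 * min_size:
        raise ValueError("too few genes for module detection")
    cor = bicor_matrix(expr)
    adj = adjacency_signed_hybrid(cor, beta)
    dist = 1.0 - adj
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    height = cut_fraction * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=height, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=expr.index, dtype=object)
    clusters = [
        np.where(raw == c)[0] for c in np.unique(raw) if (raw == c).sum() >= min_size
    ]
    clusters.sort(key=len, reverse=True)
    members: list[np.ndarray] = list(clusters)

    # iterative eigengene merging
    while len(members) > 1:
        eigs = [module_eigengene(expr.iloc[m])[0].to_numpy() for m in members]
        k = len(eigs)
        best, pair = -np.inf, None
        for i in range(k):
            for j in range(i + 1, k):
                r = np.corrcoef(eigs[i], eigs[j])[0, 1]
                if r > best:
                    best, pair = r, (i, j)
        if best <= merge_cut or pair is None:
            break
        i, j = pair
        members[i] = np.concatenate([members[i], members[j]])
        del members[j]
        members.sort(key=len, reverse=True)

    for rank, m in enumerate(sorted(members, key=len, reverse=True), start=1):
        labels.iloc[m] = f"M{rank}"
    return labels.rename("module")


def degree(adj: np.ndarray) -> np.ndarray:
    """Weighted degree: row sums of the adjacency, diagonal excluded."""
    a = np.asarray(adj, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def hub_overrep(
    degrees: pd.Series,
    class_sets: Mapping[str, set],
    hub_fraction: float = 0.10,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene classes among hubs.

    Hubs are the top ``hub_fraction`` of genes by weighted degree; each
    class is tested for enrichment in the hub set over the degree-
    ranked universe.
    """
    from .enrichment import ora

    n_hub = max(1, int(round(hub_fraction * len(degrees))))
    hubs = set(degrees.sort_values(ascending=False, kind="mergesort").index[:n_hub])
    universe = set(degrees.index)
    annotation = {cls: set(genes) & universe for cls, genes in class_sets.items()}
    out = ora(hubs, universe, annotation)
    return out.rename(columns={"term_id": "class"})


def _module_stats(
    ref_expr: np.ndarray,
    test_expr: np.ndarray,
    test_gene_idx: np.ndarray,
    ref_cor_mod: np.ndarray,
    ref_degree: np.ndarray,
    ref_contrib: np.ndarray,
    beta: float,
) -> dict[str, float]:
    """The seven preservation statistics for one candidate gene set."""
    sub = test_expr[test_gene_idx]
    cor = bicor_matrix(sub)
    adj = adjacency_signed_hybrid(cor, beta)
    m = len(test_gene_idx)
    off = ~np.eye(m, dtype=bool)

    eig, coherence = _eigengene_array(sub)
    contrib = _cor_rows_with(sub, eig)
    tri = np.tril_indices(m, k=-1)

    ref_sign = np.sign(ref_contrib)
    ref_sign[ref_sign == 0] = 1.0
    return {
        "avg.weight": float(adj[off].mean()),
        "coherence": coherence,
        "cor.cor": _safe_cor(ref_cor_mod[tri], cor[tri]),
        "cor.degree": _safe_cor(ref_degree, adj.sum(axis=1)),
        "cor.contrib": _safe_cor(ref_contrib, contrib),
        "avg.cor": float(cor[off].mean()),
        "avg.contrib": float((contrib * ref_sign).mean()),
    }


def _eigengene_array(x: np.ndarray) -> tuple[np.ndarray, float]:
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if np.dot(eig, z.mean(axis=0)) < 0:
        eig = -eig
    return eig, float(s[0] ** 2 / (s**2).sum())


def _cor_rows_with(x: np.ndarray, v: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (vc**2).sum())
    denom[denom == 0] = 1.0
    return (xc @ vc) / denom


def _safe_cor(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    modules: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    beta: float = DEFAULT_BETA,
) -> pd.DataFrame:
    """Permutation test of reference-module preservation in a test network.

    For each reference module the seven statistics are computed in the
    test network on the module's genes; the null distribution comes
    from ``n_perm`` random gene sets of the same size drawn from the
    test network's non-module genes.  One-sided p-values are
    (1 + #{null >= observed}) / (1 + n_perm); a module is preserved
    when >= 5 of 7 statistics have p < 0.05.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not ref_expr.index.equals(test_expr.index):
        raise ValueError("reference and test matrices must share the gene universe")
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(ref_expr.index)}
    ref_x = ref_expr.to_numpy(dtype=float)
    test_x = test_expr.to_numpy(dtype=float)

    module_names = [m for m in modules.unique() if m != UNASSIGNED]
    module_names.sort(key=lambda m: (-int((modules == m).sum()), m))
    in_module = modules.reindex(ref_expr.index).fillna(UNASSIGNED) != UNASSIGNED
    null_pool = np.array(
        [gene_pos[g] for g in ref_expr.index[~in_module]], dtype=int
    )

    rows = []
    for name in module_names:
        genes = [g for g in modules.index[modules == name] if g in gene_pos]
        idx = np.array([gene_pos[g] for g in genes], dtype=int)
        if len(idx) < 3:
            continue
        if len(null_pool) < len(idx):
            raise ValueError(
                f"module {name} larger than the available null pool "
                f"({len(idx)} > {len(null_pool)})"
            )
        ref_sub = ref_x[idx]
        ref_cor = bicor_matrix(ref_sub)
        ref_adj = adjacency_signed_hybrid(ref_cor, beta)
        ref_eig, _ = _eigengene_array(ref_sub)
        ref_contrib = _cor_rows_with(ref_sub, ref_eig)
        ref_degree = ref_adj.sum(axis=1)

        observed = _module_stats(
            ref_sub, test_x, idx, ref_cor, ref_degree, ref_contrib, beta
        )
        exceed = {k: 0 for k in PRESERVATION_STATS}
        for _ in range(n_perm):
            perm_idx = rng.choice(null_pool, size=len(idx), replace=False)
            null = _module_stats(
                ref_sub, test_x, perm_idx, ref_cor, ref_degree, ref_contrib, beta
            )
            for k in PRESERVATION_STATS:
                if null[k] >= observed[k]:
                    exceed[k] += 1
        pvals = {k: (1 + exceed[k]) / (1 + n_perm) for k in PRESERVATION_STATS}
        n_sig = sum(p < 0.05 for p in pvals.values())
        row = {"module": name, "size": len(idx)}
        row.update({k: observed[k] for k in PRESERVATION_STATS})
        row.update({f"p.{k}": pvals[k] for k in PRESERVATION_STATS})
        row["n_significant"] = n_sig
        row["preserved"] = n_sig >= 5
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")
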