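"""Normalization, negative-binomial differential expression and midparent values.

The testing engine is a per-gene Wald test on log2 fold changes between
group means of library-size-normalized counts.  Counts are modelled as
negative binomial with Var = mu + phi * mu**2; the gene-wise dispersion
phi is estimated by the method of moments and shrunk toward a running
mean--dispersion trend.  P-values are adjusted with the step-up
Benjamini-Hochberg procedure.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "normalize",
    "estimate_dispersion",
    "wald_test",
    "adjust_bh",
    "midparent",
    "resolve_group",
]

#: default significance threshold on the BH-adjusted p-value
DEFAULT_ALPHA = 0.01

#: prior count added to normalized group means before taking log2
PRIOR_COUNT = 0.5

#: minimum number of genes positive in every sample for median-of-ratios;
#: below this the total-count fallback is used
MIN_REFERENCE_GENES = 50


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.empty:
        raise ValueError("count matrix is empty")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample scale factors by the median-of-ratios estimator.

    The reference is the per-gene geometric mean over genes expressed in
    all samples; each sample's factor is the median ratio to that
    reference.  When fewer than ``MIN_REFERENCE_GENES`` genes are
    positive everywhere, factors fall back to total-count ratios.
    Factors are rescaled to geometric mean 1.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes in rows, samples in columns.

    Returns
    -------
    pandas.Series of positive floats indexed by sample id.
    """
    _check_counts(counts)
    mat = counts.to_numpy(dtype=float)
    if mat.sum() == 0:
        raise ValueError("all-zero count matrix: size factors undefined")
    all_positive = (mat > 0).all(axis=1)
    if all_positive.sum() >= MIN_REFERENCE_GENES:
        ref = mat[all_positive]
        log_geo = np.log(ref).mean(axis=1)
        ratios = ref / np.exp(log_geo)[:, None]
        factors = np.median(ratios, axis=0)
    else:
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return counts.div(factors.reindex(counts.columns), axis=1)


def _group_lists(
    sheet: pd.DataFrame | None,
    groups: Sequence[Sequence[str]] | Mapping[str, Sequence[str]],
) -> list[list[str]]:
    if isinstance(groups, Mapping):
        return [list(v) for v in groups.values()]
    return [list(g) for g in groups]


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[Sequence[str]] | Mapping[str, Sequence[str]],
    factors: pd.Series | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Gene-wise NB dispersion with mean-trend shrinkage.

    Raw estimates are method-of-moments, phi = max(0, (s2 - m) / m^2),
    computed on normalized counts per group and pooled with weights
    (n_g - 1).  Genes are then binned by mean expression and each raw
    estimate is shrunk toward the bin median with weight
    w = n_bin / (n_bin + n_reps).

    Returns a frame with columns ``mean``, ``phi_raw``, ``phi`` indexed
    by gene.
    """
    _check_counts(counts)
    glists = _group_lists(None, groups)
    for g in glists:
        if len(g) < 2:
            raise ValueError("dispersion estimation needs >=2 replicates per group")
    if factors is None:
        factors = size_factors(counts)
    norm = normalize(counts, factors)

    num = np.zeros(len(counts))
    den = 0.0
    overall_mean = np.zeros(len(counts))
    n_total = 0
    for g in glists:
        sub = norm[g].to_numpy()
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        w = len(g) - 1
        num += w * phi_g
        den += w
        overall_mean += sub.sum(axis=1)
        n_total += len(g)
    phi_raw = np.maximum(num / den, 0.0)
    mean_expr = overall_mean / n_total
    n_reps = n_total / len(glists)

    # running-median trend over log-mean bins
    phi = phi_raw.copy()
    pos = mean_expr > 0
    if pos.sum() > 0:
        logm = np.log(mean_expr[pos])
        edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, len(edges) - 2)
        shrunk = phi_raw[pos].copy()
        raw_pos = phi_raw[pos]
        for b in range(len(edges) - 1):
            in_bin = idx == b
            nb = int(in_bin.sum())
            if nb == 0:
                continue
            trend = float(np.median(raw_pos[in_bin]))
            w = nb / (nb + n_reps)
            shrunk[in_bin] = w * trend + (1 - w) * raw_pos[in_bin]
        phi[pos] = shrunk
    phi = np.maximum(phi, 0.0)
    return pd.DataFrame(
        {"mean": mean_expr, "phi_raw": phi_raw, "phi": phi}, index=counts.index
    )


def adjust_bh(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def resolve_group(sheet: pd.DataFrame, spec: str | Sequence[str]) -> list[str]:
    """Resolve a group specification to a list of sample ids.

    ``spec`` may be an explicit list of sample ids, a plain strain
    label (all samples of that strain), or a comma-separated
    ``column=value`` selector, e.g. ``"strain=3N,generation=G225"``.
    """
    if not isinstance(spec, str):
        ids = list(spec)
        missing = [s for s in ids if s not in sheet.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return ids
    if "=" in spec:
        mask = pd.Series(True, index=sheet.index)
        for clause in spec.split(","):
            col, _, val = clause.partition("=")
            col, val = col.strip(), val.strip()
            if col not in sheet.columns:
                raise KeyError(f"sample sheet has no column {col!r}")
            mask &= sheet[col].astype(str) == val
        ids = list(sheet.index[mask])
    else:
        if "strain" not in sheet.columns:
            raise KeyError("sample sheet has no 'strain' column")
        ids = list(sheet.index[sheet["strain"].astype(str) == spec])
    if not ids:
        raise KeyError(f"group specification {spec!r} matches no samples")
    return ids


def wald_test(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald test; returns a contrast table (B over A).

    Per gene the statistic is log2((mB + c) / (mA + c)) over its delta-
    method standard error, SE^2 = sum_g (1/n_g)(1/(m_g + c) + phi) /
    ln(2)^2 with prior count c, compared with the standard normal.
    Genes with all-zero counts in both groups are reported with
    log2fc = 0 and p = 1 and excluded from the BH adjustment.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ids_a = resolve_group(sheet, group_a)
    ids_b = resolve_group(sheet, group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both groups need >=2 replicates")
    if factors is None:
        factors = size_factors(counts)
    norm = normalize(counts, factors)
    if dispersion is None:
        dispersion = estimate_dispersion(
            counts[ids_a + ids_b], [ids_a, ids_b], factors=factors[ids_a + ids_b]
        )["phi"]
    phi = dispersion.reindex(counts.index).to_numpy(dtype=float)

    ma = norm[ids_a].mean(axis=1).to_numpy()
    mb = norm[ids_b].mean(axis=1).to_numpy()
    na, nb = len(ids_a), len(ids_b)
    log2 = np.log(2.0)
    logfc = np.log2((mb + PRIOR_COUNT) / (ma + PRIOR_COUNT))
    se2 = (
        (1.0 / na) * (1.0 / (ma + PRIOR_COUNT) + phi)
        + (1.0 / nb) * (1.0 / (mb + PRIOR_COUNT) + phi)
    ) / log2**2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, logfc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    allzero = (ma == 0) & (mb == 0)
    logfc[allzero] = 0.0
    pvalue[allzero] = 1.0

    padj = np.ones_like(pvalue)
    tested = ~allzero
    if tested.any():
        padj[tested] = adjust_bh(pvalue[tested])
    return pd.DataFrame(
        {
            "log2fc": logfc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
            "mean_a": ma,
            "mean_b": mb,
        },
        index=counts.index.rename("gene"),
    )


def midparent(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    p1_group: str | Sequence[str],
    p2_group: str | Sequence[str],
    weights: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """In-silico midparent pseudo-samples on the normalized scale.

    Each pseudo-replicate is the weighted mean of one P1 and one P2
    normalized replicate, paired at random without replacement.  The
    number of pseudo-replicates is min(n_P1, n_P2).  Default weights
    are (1/2, 1/2); a ploidy-weighted midparent (e.g. 1/3 haploid, 2/3
    diploid) can be requested instead.
    """
    w1, w2 = weights
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("midparent weights must sum to 1")
    ids1 = resolve_group(sheet, p1_group)
    ids2 = resolve_group(sheet, p2_group)
    if factors is None:
        factors = size_factors(counts)
    norm = normalize(counts, factors)
    rng = np.random.default_rng(seed)
    k = min(len(ids1), len(ids2))
    pick1 = rng.permutation(len(ids1))[:k]
    pick2 = rng.permutation(len(ids2))[:k]
    data = {}
    for r, (i, j) in enumerate(zip(pick1, pick2), start=1):
        data[f"MPV_{r}"] = w1 * norm[ids1[i]] + w2 * norm[ids2[j]]
    return pd.DataFrame(data, index=counts.index)
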