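"""Synthetic inputs with known ground truth for every pipeline stage.

The count simulator emulates the study design: a haploid parent (1N),
a diploid parent (2N) and their triploid derivative sampled at
generation 0 plus five evolved lines at generations 225 and 425, six
replicates each.  Counts are negative binomial (Var = mu + phi*mu^2)
with lognormal library sizes, and per-gene expression classes are
planted explicitly: ADD genes put the hybrid at the midparent, ELD1 /
ELD2 at the matching parent, UP / DOWN beyond the extreme parent, and
NULL genes are flat everywhere.

Companion generators produce Baranyi-shaped growth curves, flow-
cytometry event clouds at chosen fluorescence peaks, and random
gene-term annotation tables with an optional planted enrichment.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import BaranyiParams, baranyi_log_density

__all__ = [
    "SimDesign",
    "study_groups",
    "simulate_counts",
    "simulate_growth",
    "simulate_cytometry",
    "simulate_annotations",
]

CLASSES = ("NULL", "ADD", "ELD1", "ELD2", "UP", "DOWN")

#: base-mean lognormal: chosen so per-gene depth matches a typical
#: 3'-tag RNA-seq experiment (median a few hundred counts per gene at
#: the default library size)
BASE_MEANLOG = np.log(100.0)
BASE_SDLOG = 1.0


def study_groups(n_replicates: int = 6) -> list[tuple[str, str, str, int]]:
    """The study's sampling design: parents, ancestral triploid and
    five evolved lines at G225 and G425."""
    groups = [
        ("1N_parent", "NA", "NA", n_replicates),
        ("2N_parent", "NA", "NA", n_replicates),
        ("3N", "G0", "NA", n_replicates),
    ]
    for gen in ("G225", "G425"):
        for line in range(1, 6):
            groups.append(("3N", gen, str(line), n_replicates))
    return groups


@dataclass
class SimDesign:
    """Design of a synthetic count experiment.

    ``lib_size_mean`` defaults to 500 counts per gene on average,
    matching the per-gene depth of the study's sequencing.  ``drift_sd``
    adds a per-line lognormal expression shift (log2 sd) to evolved
    lines so temporal and preservation analyses have signal; default 0.
    """

    n_genes: int = 2000
    groups: list[tuple[str, str, str, int]] = field(default_factory=study_groups)
    lib_size_mean: float | None = None
    lib_size_cv: float = 0.15
    dispersion: float = 0.05
    drift_sd: float = 0.0
    n_coexpr_modules: int = 0
    coexpr_size: int = 50
    coexpr_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.lib_size_mean is None:
            self.lib_size_mean = 500.0 * self.n_genes
        if self.lib_size_mean <= 0:
            raise ValueError("lib_size_mean must be positive")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be non-negative")
        for g in self.groups:
            if g[3] < 2:
                raise ValueError("every group needs at least 2 replicates")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    size = 1.0 / phi
    return rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))


def simulate_counts(
    design: SimDesign,
    class_fractions: Mapping[str, float] | None = None,
    effect_size: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a count matrix with planted expression classes.

    ``class_fractions`` maps non-null classes (ADD, ELD1, ELD2, UP,
    DOWN) to gene fractions; the remainder is NULL.  ``effect_size``
    is the parental log2 separation for ADD/ELD genes and the
    transgressive offset for UP/DOWN genes.

    Returns (counts, sample sheet, truth table).  The truth table
    records each gene's class, base mean, parental log2 ratio and the
    hybrid offset in log2 units relative to the reference parent mean.
    """
    if class_fractions is None:
        class_fractions = {}
    bad = set(class_fractions) - set(CLASSES[1:])
    if bad:
        raise ValueError(f"unknown classes: {sorted(bad)}")
    total = sum(class_fractions.values())
    if total > 1 + 1e-12:
        raise ValueError("class fractions sum to more than 1")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")

    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    genes = [f"g{i:05d}" for i in range(n)]

    labels = np.array(["NULL"] * n, dtype=object)
    start = 0
    for cls in CLASSES[1:]:
        k = int(round(class_fractions.get(cls, 0.0) * n))
        labels[start : start + k] = cls
        start += k
    rng.shuffle(labels)

    base = rng.lognormal(BASE_MEANLOG, BASE_SDLOG, size=n)
    # parental separation only for ADD/ELD genes, direction random
    sep_sign = rng.choice([-1.0, 1.0], size=n)
    has_sep = np.isin(labels, ("ADD", "ELD1", "ELD2"))
    log2_ratio = np.where(has_sep, sep_sign * effect_size, 0.0)
    p1_mean = base * 2.0 ** (log2_ratio / 2.0)
    p2_mean = base * 2.0 ** (-log2_ratio / 2.0)

    hybrid = base.copy()
    hybrid[labels == "ADD"] = 0.5 * (p1_mean + p2_mean)[labels == "ADD"]
    hybrid[labels == "ELD1"] = p1_mean[labels == "ELD1"]
    hybrid[labels == "ELD2"] = p2_mean[labels == "ELD2"]
    up = labels == "UP"
    down = labels == "DOWN"
    hybrid[up] = np.maximum(p1_mean, p2_mean)[up] * 2.0**effect_size
    hybrid[down] = np.minimum(p1_mean, p2_mean)[down] * 2.0**-effect_size

    strain_means = {"1N_parent": p1_mean, "2N_parent": p2_mean, "3N": hybrid}

    # optional planted coexpression: blocks of genes share a per-sample
    # lognormal latent factor, emulating co-regulated pathways whose
    # activity fluctuates between replicate cultures
    module_of = np.full(n, "none", dtype=object)
    loadings = np.zeros(n)
    if design.n_coexpr_modules > 0:
        need = design.n_coexpr_modules * design.coexpr_size
        if need > n:
            raise ValueError("coexpression modules exceed the gene count")
        chosen = rng.choice(n, size=need, replace=False)
        for m in range(design.n_coexpr_modules):
            idx = chosen[m * design.coexpr_size : (m + 1) * design.coexpr_size]
            module_of[idx] = f"K{m + 1}"
        # heterogeneous per-gene loadings give each module a reproducible
        # internal connectivity pattern (hub/periphery structure)
        loadings[module_of != "none"] = rng.uniform(
            0.4, 1.6, size=int((module_of != "none").sum())
        )

    sigma = np.sqrt(np.log1p(design.lib_size_cv**2)) if design.lib_size_cv > 0 else 0.0
    mu_log = np.log(design.lib_size_mean) - 0.5 * sigma**2

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    drift_cache: dict[str, np.ndarray] = {}
    for strain, generation, line, n_reps in design.groups:
        if strain not in strain_means:
            raise ValueError(f"unknown strain label {strain!r}")
        means = strain_means[strain]
        if strain == "3N" and generation not in ("NA", "G0") and design.drift_sd > 0:
            key = f"{generation}:{line}"
            if key not in drift_cache:
                line_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [design.seed, 7, zlib.crc32(key.encode()) % (2**31)]
                    )
                )
                drift_cache[key] = 2.0 ** line_rng.normal(0, design.drift_sd, size=n)
            means = means * drift_cache[key]
        rel = means / means.sum()
        for rep in range(1, n_reps + 1):
            lib = (
                float(rng.lognormal(mu_log, sigma))
                if sigma > 0
                else float(design.lib_size_mean)
            )
            mu = rel * lib
            if design.n_coexpr_modules > 0:
                log2_shift = np.zeros(n)
                for m in range(design.n_coexpr_modules):
                    f = rng.normal(0.0, design.coexpr_sd)
                    sel = module_of == f"K{m + 1}"
                    log2_shift[sel] = loadings[sel] * f
                mu = mu * 2.0**log2_shift
            sample = f"{strain}_{generation}_L{line}_r{rep}"
            columns[sample] = _nb_draw(rng, mu, design.dispersion)
            sheet_rows.append(
                {
                    "sample": sample,
                    "strain": strain,
                    "generation": generation,
                    "line": line,
                    "replicate": rep,
                }
            )

    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    sheet = pd.DataFrame(sheet_rows).set_index("sample")
    hybrid_ref = np.where(labels == "DOWN", np.minimum(p1_mean, p2_mean),
                          np.maximum(p1_mean, p2_mean))
    with np.errstate(divide="ignore"):
        offset = np.where(labels == "NULL", 0.0, np.log2(hybrid / hybrid_ref))
    truth = pd.DataFrame(
        {
            "true_class": labels,
            "base_mean": base,
            "parental_log2_ratio": log2_ratio,
            "hybrid_offset": offset,
            "coexpr_module": module_of,
        },
        index=pd.Index(genes, name="gene"),
    )
    return counts, sheet, truth


def simulate_growth(
    params: BaranyiParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    n_wells: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Baranyi-shaped OD curves with additive Gaussian noise on OD.

    Returns a long-format frame (well, time_h, od); OD values are
    floored at 1e-6.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    clean = np.exp(baranyi_log_density(params, times))
    rows = []
    for w in range(1, n_wells + 1):
        od = clean + (rng.normal(0, noise_sd, size=times.size) if noise_sd > 0 else 0.0)
        od = np.maximum(od, 1e-6)
        for t, v in zip(times, od):
            rows.append({"well": f"W{w:02d}", "time_h": t, "od": v})
    return pd.DataFrame(rows)


def simulate_cytometry(
    peaks: Sequence[tuple[float, float, int]],
    debris_fraction: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Flow-cytometry event intensities: lognormal clouds plus debris.

    ``peaks`` is a list of (mean intensity, CV, n_events).  Debris
    events, an extra ``debris_fraction`` of the total, are drawn from a
    low-intensity exponential (scale 10% of the smallest peak mean).
    """
    if not peaks:
        raise ValueError("at least one peak is required")
    rng = np.random.default_rng(seed)
    parts = []
    for mean, cv, n_events in peaks:
        if mean <= 0 or cv <= 0:
            raise ValueError("peak means and CVs must be positive")
        if n_events <= 0:
            raise ValueError("each peak needs a positive number of events")
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - 0.5 * sigma2
        parts.append(rng.lognormal(mu, np.sqrt(sigma2), size=int(n_events)))
    total = sum(int(p[2]) for p in peaks)
    if debris_fraction > 0:
        n_debris = int(round(debris_fraction * total))
        scale = 0.10 * min(p[0] for p in peaks)
        parts.append(rng.exponential(scale, size=n_debris))
    events = np.concatenate(parts)
    rng.shuffle(events)
    return events


def simulate_annotations(
    n_genes: int,
    n_terms: int,
    genes_per_term: int,
    enriched_set: Iterable[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene-term annotations with an optional planted term.

    Terms draw ``genes_per_term`` members uniformly from the gene
    universe g00000..; when ``enriched_set`` is given, term T0000 is
    built from those genes (padded or truncated to ``genes_per_term``).
    Returns a long-format frame (term_id, term_name, gene_id).
    """
    if genes_per_term > n_genes:
        raise ValueError("genes_per_term cannot exceed n_genes")
    genes = np.array([f"g{i:05d}" for i in range(n_genes)])
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        term = f"T{t:04d}"
        if t == 0 and enriched_set is not None:
            members = [g for g in enriched_set if g in set(genes)][:genes_per_term]
            pool = np.setdiff1d(genes, np.array(members))
            if len(members) < genes_per_term:
                members = list(members) + list(
                    rng.choice(pool, genes_per_term - len(members), replace=False)
                )
        else:
            members = list(rng.choice(genes, genes_per_term, replace=False))
        for g in sorted(members):
            rows.append({"term_id": term, "term_name": f"pathway {t}", "gene_id": g})
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])
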