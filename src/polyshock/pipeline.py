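"""End-to-end orchestration: simulate -> DE -> partition -> temporal ->
persistence -> enrichment -> network -> report.

The pipeline is a pure function of its configuration and seeds: every
stage writes its table to the output directory, a MANIFEST records
content hashes, and reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import de, enrichment, io, networks, partition, simulate

__all__ = ["PipelineConfig", "run_pipeline", "pca"]


@dataclass
class PipelineConfig:
    """Configuration of a synthetic end-to-end run."""

    out_dir: str = "polyshock_run"
    counts_path: str | None = None  # None -> simulate
    sheet_path: str | None = None
    n_genes: int = 800
    n_replicates: int = 6
    dispersion: float = 0.05
    effect_size: float = 2.0
    drift_sd: float = 0.05
    n_coexpr_modules: int = 3
    coexpr_size: int = 50
    coexpr_sd: float = 0.5
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "ADD": 0.05, "ELD1": 0.10, "ELD2": 0.10, "UP": 0.05, "DOWN": 0.05
        }
    )
    alpha: float = 0.01
    mpv_weights: tuple[float, float] = (0.5, 0.5)
    partition_mode: str = "strict"
    beta: float = 6.0
    min_module_size: int = 25
    merge_cut: float = 0.8
    n_perm: int = 100
    n_terms: int = 50
    genes_per_term: int = 40
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def pca(expr: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-level PCA of an expression matrix (genes x samples).

    Columns (samples) are the observations; genes are centered across
    samples before the SVD.  Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive.  Returns (scores indexed by sample, explained-variance
    fractions).
    """
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < n_components:
        raise ValueError("fewer samples than requested components")
    xc = x - x.mean(axis=1, keepdims=True)
    if np.allclose(xc, 0):
        raise ValueError("constant expression matrix")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for k in range(n_components):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    scores = (vt[:n_components] * s[:n_components, None]).T
    var_frac = (s**2 / (s**2).sum())[:n_components]
    frame = pd.DataFrame(
        scores,
        index=expr.columns.rename("sample"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return frame, var_frac


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and write the report.

    Returns the report dict; every number in it is also written as a
    TSV under ``config.out_dir``.
    """
    cfg = config
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    # the config echo omits filesystem locations so that reruns of the
    # same analysis are byte-identical wherever they are written
    echo = {k: v for k, v in asdict(cfg).items() if k != "out_dir"}
    report: dict = {"config": _jsonable(echo), "stages": {}}

    # ---- stage: inputs -------------------------------------------------
    if cfg.counts_path is not None:
        if not os.path.exists(cfg.counts_path):
            raise FileNotFoundError(f"counts file not found: {cfg.counts_path}")
        if cfg.sheet_path is None or not os.path.exists(cfg.sheet_path):
            raise FileNotFoundError("sample sheet required with external counts")
        counts = io.read_counts(cfg.counts_path)
        sheet = io.read_sample_sheet(cfg.sheet_path)
        truth = None
    else:
        design = simulate.SimDesign(
            n_genes=cfg.n_genes,
            groups=simulate.study_groups(cfg.n_replicates),
            dispersion=cfg.dispersion,
            drift_sd=cfg.drift_sd,
            n_coexpr_modules=cfg.n_coexpr_modules,
            coexpr_size=cfg.coexpr_size,
            coexpr_sd=cfg.coexpr_sd,
            seed=cfg.seed,
        )
        counts, sheet, truth = simulate.simulate_counts(
            design, cfg.class_fractions, cfg.effect_size
        )
        io.write_table(counts, os.path.join(out, "counts.tsv"))
        io.write_table(sheet, os.path.join(out, "sample_sheet.tsv"))
        io.write_table(truth, os.path.join(out, "truth.tsv"))
    report["stages"]["inputs"] = {
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
    }

    p1, p2 = "1N_parent", "2N_parent"
    f1_g0 = "strain=3N,generation=G0"
    f1_g225 = "strain=3N,generation=G225"
    f1_g425 = "strain=3N,generation=G425"

    # ---- stage: differential expression --------------------------------
    factors = de.size_factors(counts)
    contrasts = {
        "parents_1N_vs_2N": (p2, p1),
        "3N_G0_vs_1N": (p1, f1_g0),
        "3N_G0_vs_2N": (p2, f1_g0),
    }
    deg_counts = {}
    for name, (ga, gb) in contrasts.items():
        tab = de.wald_test(counts, sheet, ga, gb, cfg.alpha, factors=factors)
        io.write_table(tab, os.path.join(out, f"de_{name}.tsv"))
        deg_counts[name] = int((tab["padj"] < cfg.alpha).sum())
    mpv = de.midparent(
        counts, sheet, p1, p2, weights=cfg.mpv_weights, seed=cfg.seed, factors=factors
    )
    io.write_table(mpv, os.path.join(out, "mpv.tsv"))
    report["stages"]["de"] = {"deg_counts": deg_counts, "alpha": cfg.alpha}

    # ---- stage: partitioning -------------------------------------------
    parts = {}
    for gen, f1_spec in (("G0", f1_g0), ("G225", f1_g225), ("G425", f1_g425)):
        part = partition.partition_trio(
            counts, sheet, p1, f1_spec, p2, cfg.alpha, cfg.partition_mode
        )
        parts[gen] = part
        io.write_table(part, os.path.join(out, f"partition_{gen}.tsv"))
        summary = partition.summarize_partition(part, counts.shape[0])
        io.write_table(summary, os.path.join(out, f"partition_{gen}_summary.tsv"),
                       index=False)
    class_tables = {
        gen: {
            cls: int((p["class"] == cls).sum()) for cls in partition.CLASS_LABELS
        }
        for gen, p in parts.items()
    }
    report["stages"]["partition"] = class_tables

    # ---- stage: temporal + persistence ---------------------------------
    temporal = partition.temporal_partition(
        counts, sheet, f1_g0, f1_g225, f1_g425, cfg.alpha, cfg.partition_mode
    )
    io.write_table(temporal, os.path.join(out, "temporal_partition.tsv"))
    persist = partition.persistent_genes(parts["G0"], parts["G225"], parts["G425"])
    io.write_table(persist, os.path.join(out, "persistent_genes.tsv"))
    report["stages"]["temporal"] = {
        "n_deg": int(temporal["is_deg"].sum()),
        "n_non_deg": int((~temporal["is_deg"]).sum()),
    }
    report["stages"]["persistence"] = {
        cls: float(persist.loc[cls, "rate_pct"]) for cls in persist.index
    }

    # ---- stage: enrichment ---------------------------------------------
    universe = list(counts.index)
    deg_set = list(parts["G0"].index[parts["G0"]["class"] == "DOWN"])
    annot = simulate.simulate_annotations(
        cfg.n_genes, cfg.n_terms, cfg.genes_per_term,
        enriched_set=deg_set, seed=cfg.seed + 1,
    )
    io.write_table(annot, os.path.join(out, "annotations.tsv"), index=False)
    if deg_set:
        ora_tab = enrichment.ora(deg_set, universe, annot)
        io.write_table(ora_tab, os.path.join(out, "ora_down.tsv"), index=False)
        report["stages"]["enrichment"] = {
            "n_terms_tested": int(len(ora_tab)),
            "n_significant": int(ora_tab["significant"].sum()),
        }
    else:
        report["stages"]["enrichment"] = {"n_terms_tested": 0, "n_significant": 0}

    # ---- stage: network -------------------------------------------------
    filtered = networks.filter_low_counts(counts)
    expr = networks.vst(filtered)
    modules = networks.detect_modules(
        expr, beta=cfg.beta, min_size=cfg.min_module_size, merge_cut=cfg.merge_cut
    )
    io.write_table(modules.to_frame(), os.path.join(out, "modules.tsv"))
    adj = networks.adjacency_signed_hybrid(networks.bicor_matrix(expr), cfg.beta)
    deg = pd.Series(networks.degree(adj), index=expr.index, name="degree")
    io.write_table(deg.to_frame(), os.path.join(out, "degree.tsv"))
    class_sets = {
        cls: set(parts["G0"].index[parts["G0"]["class"] == cls])
        for cls in partition.CLASS_LABELS
    }
    class_sets = {c: s & set(expr.index) for c, s in class_sets.items() if s}
    if class_sets:
        hubs = networks.hub_overrep(deg, class_sets)
        io.write_table(hubs, os.path.join(out, "hub_overrep.tsv"), index=False)

    line1 = de.resolve_group(sheet, "strain=3N,line=1")
    line2 = de.resolve_group(sheet, "strain=3N,line=2")
    n_modules = len([m for m in modules.unique() if m != networks.UNASSIGNED])
    preserved = None
    if n_modules and len(line1) >= 4 and len(line2) >= 4:
        pres = networks.preservation(
            expr[line1], expr[line2], modules, n_perm=cfg.n_perm, seed=cfg.seed + 2,
            beta=cfg.beta,
        )
        io.write_table(pres, os.path.join(out, "preservation.tsv"))
        preserved = {m: bool(v) for m, v in pres["preserved"].items()}
    report["stages"]["network"] = {
        "n_genes_filtered": int(expr.shape[0]),
        "n_modules": n_modules,
        "preserved": preserved,
    }

    # ---- stage: PCA ------------------------------------------------------
    scores, var_frac = pca(expr, n_components=2)
    scores = scores.join(sheet[["strain", "generation", "line"]])
    io.write_table(scores, os.path.join(out, "pca_scores.tsv"))
    report["stages"]["pca"] = {
        "explained_variance": [round(float(v), 6) for v in var_frac]
    }

    # ---- report + manifest ----------------------------------------------
    report_path = os.path.join(out, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest_rows = []
    for name in sorted(os.listdir(out)):
        if name == "MANIFEST.tsv":
            continue
        path = os.path.join(out, name)
        if os.path.isfile(path):
            manifest_rows.append({"file": name, "sha256": _sha256(path)})
    pd.DataFrame(manifest_rows).to_csv(
        os.path.join(out, "MANIFEST.tsv"), sep="\t", index=False
    )
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
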