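"""Expression partitioning of a parent/hybrid trio into 12 categories / 5 classes.

For each gene three contrasts are reduced to a sign triple
(s12, sH1, sH2): the sign of the significant P1-P2, F1-P1 and F1-P2
log2 fold changes (0 when not significant at the adjusted-p threshold).
The triple is matched against 12 canonical patterns grouped in five
classes: transgressive up (UP) and down (DOWN), additivity (ADDITIVE),
and expression-level dominance toward either parent (ELD1 = toward P1,
ELD2 = toward P2).  The same machinery, applied to the G0/G225/G425
trio of a single evolving strain, tracks how expression changes over
generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import de

__all__ = [
    "CATEGORY_PATTERNS",
    "CLASS_LABELS",
    "sign_triple",
    "classify",
    "partition_trio",
    "temporal_partition",
    "persistent_genes",
    "summarize_partition",
    "swap_parents",
]

# canonical (s12, sH1, sH2) -> (category, class); s12 = sign(P1 - P2),
# sH1 = sign(F1 - P1), sH2 = sign(F1 - P2); 0 = not significant
CATEGORY_PATTERNS: dict[tuple[int, int, int], tuple[str, str]] = {
    (1, 1, 1): ("C1", "UP"),
    (0, 1, 1): ("C2", "UP"),
    (-1, 1, 1): ("C3", "UP"),
    (1, -1, -1): ("C4", "DOWN"),
    (0, -1, -1): ("C5", "DOWN"),
    (-1, -1, -1): ("C6", "DOWN"),
    (1, -1, 1): ("C7", "ADDITIVE"),
    (-1, 1, -1): ("C8", "ADDITIVE"),
    (1, 0, 1): ("C9", "ELD1"),
    (-1, 0, -1): ("C10", "ELD1"),
    (1, -1, 0): ("C11", "ELD2"),
    (-1, 1, 0): ("C12", "ELD2"),
}

CLASS_LABELS = ["UP", "DOWN", "ADDITIVE", "ELD1", "ELD2"]

# how each category of the G0/G225/G425 temporal trio reads as a
# trajectory (G0 -> P1, G225 -> F1, G425 -> P2)
TEMPORAL_LABELS = {
    "ELD2": "changed_then_stable",  # shifted by G225, then constant
    "ELD1": "late_change",          # constant to G225, shifted at G425
}


@dataclass(frozen=True)
class SignTriple:
    """Significance signs for one gene plus observed-difference signs."""

    s12: int
    sh1: int
    sh2: int
    obs12: int = 0
    obsh1: int = 0
    obsh2: int = 0


def _sig_sign(logfc: float, padj: float, alpha: float) -> int:
    return int(np.sign(logfc)) if padj < alpha else 0


def sign_triple(
    c12_row: pd.Series, ch1_row: pd.Series, ch2_row: pd.Series, alpha: float
) -> SignTriple:
    """Build the sign triple for one gene from its three contrast rows.

    Contrast orientation: c12 = P1 over P2, ch1 = F1 over P1,
    ch2 = F1 over P2 -- i.e. each row's ``log2fc`` is log2(num/den)
    and a positive significant value yields +1.  Significance is
    strict: padj exactly equal to alpha is not significant.
    """
    return SignTriple(
        s12=_sig_sign(c12_row["log2fc"], c12_row["padj"], alpha),
        sh1=_sig_sign(ch1_row["log2fc"], ch1_row["padj"], alpha),
        sh2=_sig_sign(ch2_row["log2fc"], ch2_row["padj"], alpha),
        obs12=int(np.sign(c12_row["log2fc"])),
        obsh1=int(np.sign(ch1_row["log2fc"])),
        obsh2=int(np.sign(ch2_row["log2fc"])),
    )


def classify(
    triple: SignTriple, mode: Literal["strict", "relaxed"] = "strict"
) -> tuple[str, str]:
    """Map a sign triple to (category, class).

    All-zero triples are not differentially expressed and return
    ("NONE", "NON_DEG").  In strict mode a triple matching none of the
    12 canonical patterns is UNCLASSIFIED.  Relaxed mode retries a
    non-matching triple with its zeros replaced by the observed
    mean-difference signs before giving up.
    """
    key = (triple.s12, triple.sh1, triple.sh2)
    if key == (0, 0, 0):
        return ("NONE", "NON_DEG")
    if key in CATEGORY_PATTERNS:
        return CATEGORY_PATTERNS[key]
    if mode == "relaxed":
        filled = (
            triple.s12 if triple.s12 != 0 else triple.obs12,
            triple.sh1 if triple.sh1 != 0 else triple.obsh1,
            triple.sh2 if triple.sh2 != 0 else triple.obsh2,
        )
        if filled in CATEGORY_PATTERNS:
            return CATEGORY_PATTERNS[filled]
    return ("UNCLASSIFIED", "UNCLASSIFIED")


def swap_parents(triple: SignTriple) -> SignTriple:
    """The same gene's triple with the parental roles exchanged."""
    return SignTriple(
        s12=-triple.s12,
        sh1=triple.sh2,
        sh2=triple.sh1,
        obs12=-triple.obs12,
        obsh1=triple.obsh2,
        obsh2=triple.obsh1,
    )


def _partition_from_contrasts(
    c12: pd.DataFrame,
    ch1: pd.DataFrame,
    ch2: pd.DataFrame,
    alpha: float,
    mode: str,
) -> pd.DataFrame:
    genes = c12.index
    for name, tab in (("F1-vs-P1", ch1), ("F1-vs-P2", ch2)):
        missing = genes.difference(tab.index)
        if len(missing):
            raise KeyError(
                f"genes missing from contrast {name}: {list(missing[:5])}"
            )
    sig = lambda t: np.where(  # noqa: E731
        t["padj"].to_numpy() < alpha, np.sign(t["log2fc"].to_numpy()), 0
    ).astype(int)
    s12, sh1, sh2 = sig(c12), sig(ch1.loc[genes]), sig(ch2.loc[genes])
    obs12 = np.sign(c12["log2fc"].to_numpy()).astype(int)
    obsh1 = np.sign(ch1.loc[genes, "log2fc"].to_numpy()).astype(int)
    obsh2 = np.sign(ch2.loc[genes, "log2fc"].to_numpy()).astype(int)

    cats = np.empty(len(genes), dtype=object)
    classes = np.empty(len(genes), dtype=object)
    for i in range(len(genes)):
        cat, cls = classify(
            SignTriple(s12[i], sh1[i], sh2[i], obs12[i], obsh1[i], obsh2[i]), mode
        )
        cats[i], classes[i] = cat, cls
    is_deg = (s12 != 0) | (sh1 != 0) | (sh2 != 0)
    return pd.DataFrame(
        {
            "s12": s12,
            "sh1": sh1,
            "sh2": sh2,
            "category": cats,
            "class": classes,
            "is_deg": is_deg,
        },
        index=genes.rename("gene"),
    )


def partition_trio(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    p1: str | Sequence[str],
    f1: str | Sequence[str],
    p2: str | Sequence[str],
    alpha: float = de.DEFAULT_ALPHA,
    mode: Literal["strict", "relaxed"] = "strict",
) -> pd.DataFrame:
    """Run the three pairwise contrasts and classify every gene.

    A gene is a DEG when it is significant in at least one of the three
    contrasts.  Returns the partition table (s12, sh1, sh2, category,
    class, is_deg) indexed by gene.
    """
    factors = de.size_factors(counts)
    c12 = de.wald_test(counts, sheet, p2, p1, alpha, factors=factors)  # P1 over P2
    ch1 = de.wald_test(counts, sheet, p1, f1, alpha, factors=factors)  # F1 over P1
    ch2 = de.wald_test(counts, sheet, p2, f1, alpha, factors=factors)  # F1 over P2
    return _partition_from_contrasts(c12, ch1, ch2, alpha, mode)


def temporal_partition(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    g0: str | Sequence[str],
    g225: str | Sequence[str],
    g425: str | Sequence[str],
    alpha: float = de.DEFAULT_ALPHA,
    mode: Literal["strict", "relaxed"] = "strict",
) -> pd.DataFrame:
    """Partition the G0/G225/G425 trio with the parent/hybrid machinery.

    G0 takes the P1 slot, G225 the F1 slot and G425 the P2 slot, so an
    ELD2-like pattern (G225 = G425 != G0) reads "changed then
    stabilized", a parents-equal transgressive pattern (G0 = G425,
    G225 apart) reads "transient", and an ELD1-like pattern reads
    "late change".  The extra ``trajectory`` column carries these
    labels.
    """
    table = partition_trio(counts, sheet, g0, g225, g425, alpha, mode)
    traj = np.empty(len(table), dtype=object)
    for i, (cat, cls, s12) in enumerate(
        zip(table["category"], table["class"], table["s12"])
    ):
        if cls in ("UP", "DOWN") and s12 == 0:
            traj[i] = "transient"
        else:
            traj[i] = TEMPORAL_LABELS.get(cls, cls.lower())
    table = table.copy()
    table["trajectory"] = traj
    return table


def persistent_genes(
    part_g0: pd.DataFrame, part_g225: pd.DataFrame, part_g425: pd.DataFrame
) -> pd.DataFrame:
    """Genes keeping the same class at all three timepoints.

    The persistence rate uses the G0 class membership as denominator.
    Returns a frame indexed by class with columns ``n_g0``,
    ``n_persistent``, ``rate_pct`` and ``genes`` (comma-joined ids).
    """
    tables = (part_g0, part_g225, part_g425)
    universe = part_g0.index
    for t in tables[1:]:
        if not universe.equals(t.index):
            raise ValueError("partition tables cover different gene universes")
    rows = []
    for cls in CLASS_LABELS:
        sets = [set(t.index[t["class"] == cls]) for t in tables]
        persistent = sorted(sets[0] & sets[1] & sets[2])
        n0 = len(sets[0])
        rate = 100.0 * len(persistent) / n0 if n0 else 0.0
        rows.append(
            {
                "class": cls,
                "n_g0": n0,
                "n_persistent": len(persistent),
                "rate_pct": round(rate, 2),
                "genes": ",".join(persistent),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def summarize_partition(table: pd.DataFrame, universe_size: int) -> pd.DataFrame:
    """Counts and percentages per class and category.

    Percentages are computed against ``universe_size`` (all analysed
    genes) and reported to 2 decimals.
    """
    n_classified = int((table["class"] != "NON_DEG").sum())
    if universe_size < n_classified:
        raise ValueError("universe smaller than the number of classified genes")
    rows = []
    for cls in CLASS_LABELS + ["UNCLASSIFIED", "NON_DEG"]:
        sub = table[table["class"] == cls]
        rows.append(
            {
                "level": "class",
                "label": cls,
                "n": len(sub),
                "pct": round(100.0 * len(sub) / universe_size, 2),
            }
        )
    for key, (cat, _cls) in CATEGORY_PATTERNS.items():
        n = int((table["category"] == cat).sum())
        rows.append(
            {
                "level": "category",
                "label": cat,
                "n": n,
                "pct": round(100.0 * n / universe_size, 2),
            }
        )
    n_deg = int(table["is_deg"].sum())
    rows.append(
        {
            "level": "total",
            "label": "DEG",
            "n": n_deg,
            "pct": round(100.0 * n_deg / universe_size, 2),
        }
    )
    return pd.DataFrame(rows)
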