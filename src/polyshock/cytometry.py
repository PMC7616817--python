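"""Mean-fluorescence-intensity estimation and genome-size arithmetic.

PI fluorescence of stained nuclei is proportional to DNA content, so
ratios of mean fluorescence intensities (MFIs) measure relative
ploidy, the summed parental MFI (SPV) is the expected genome size of a
loss-free merger, and deviations from it quantify genome loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "estimate_mfi",
    "ploidy_ratio",
    "spv",
    "spv_fraction",
    "genome_loss",
]

MIN_GATED_EVENTS = 100
#: events below this fraction of the modal intensity are gated out as debris
DEBRIS_MODE_FRACTION = 0.25


def estimate_mfi(
    events: np.ndarray, debris_fraction_of_mode: float = DEBRIS_MODE_FRACTION
) -> dict:
    """MFI of an event cloud after a modal-fraction debris gate.

    The modal intensity is located on a log-intensity histogram; events
    below ``debris_fraction_of_mode`` times the mode are discarded.
    The MFI is the arithmetic mean of the gated events.

    Returns a dict with ``mfi``, ``sd`` and ``n`` (gated events).
    """
    events = np.asarray(events, dtype=float)
    events = events[np.isfinite(events) & (events >= 0)]
    if events.size == 0:
        raise ValueError("empty event set")
    positive = events[events > 0]
    if positive.size < MIN_GATED_EVENTS:
        raise ValueError("fewer than 100 positive events")
    logs = np.log(positive)
    hist, edges = np.histogram(logs, bins=max(20, int(np.sqrt(positive.size))))
    mode = float(np.exp(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])))
    gated = positive[positive >= debris_fraction_of_mode * mode]
    if gated.size < MIN_GATED_EVENTS:
        raise ValueError("fewer than 100 events pass the debris gate")
    return {
        "mfi": float(gated.mean()),
        "sd": float(gated.std(ddof=1)),
        "n": int(gated.size),
    }


def ploidy_ratio(mfi_a: float, mfi_b: float) -> float:
    """Ratio of two MFIs (a over b), to 3 decimals."""
    if mfi_a <= 0 or mfi_b <= 0:
        raise ValueError("MFIs must be positive")
    return round(mfi_a / mfi_b, 3)


def spv(mfi_p1: float, mfi_p2: float) -> float:
    """Summed parental value: arithmetic sum of the parental MFIs."""
    if mfi_p1 <= 0 or mfi_p2 <= 0:
        raise ValueError("MFIs must be positive")
    return mfi_p1 + mfi_p2


def spv_fraction(mfi_hybrid: float, spv_value: float) -> float:
    """Hybrid MFI as a percentage of the summed parental value, 1 decimal."""
    if spv_value <= 0:
        raise ValueError("SPV must be positive")
    return round(100.0 * mfi_hybrid / spv_value, 1)


def genome_loss(mfi_ref: float, mfi_obs: float) -> float:
    """Percent reduction of ``mfi_obs`` relative to ``mfi_ref``, 1 decimal.

    Negative values indicate gain.
    """
    if mfi_ref <= 0:
        raise ValueError("reference MFI must be positive")
    return round(100.0 * (1.0 - mfi_obs / mfi_ref), 1)
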