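"""Baranyi-Roberts growth-curve fitting and fitness comparison.

The model describes log population density y(t) = ln OD(t) with four
parameters: initial level y0, asymptote ymax, maximum specific growth
rate mu_max (per hour) and the dimensionless lag parameter h0 (lag
duration lambda = h0 / mu_max):

    A(t) = t + (1/mu) * ln(exp(-mu t) + exp(-h0) - exp(-mu t - h0))
    y(t) = y0 + mu * A(t) - ln(1 + (exp(mu * A(t)) - 1) / exp(ymax - y0))

The maximum growth rate (MGR) of a fitted well is the fitness proxy.
Group comparisons follow an adaptive strategy: Shapiro-Wilk on pooled
centered residuals and Levene (median-centered) decide between a
t-test (Welch under heteroscedasticity) and a Mann-Whitney U test,
with BH correction over all pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .de import adjust_bh

__all__ = [
    "BaranyiParams",
    "baranyi_log_density",
    "fit_baranyi",
    "fit_plate",
    "compare_mgr",
    "generations",
]

MU_MAX_BOUND = 5.0
H0_BOUND = 50.0
#: multi-start grid of (mu_max, h0) initial values
START_GRID = [(mu, h0) for mu in (0.05, 0.15, 0.3, 0.6, 1.2) for h0 in (0.0, 1.5, 5.0, 15.0)]
OD_FLOOR = 1e-6
NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class BaranyiParams:
    """Baranyi-Roberts parameters on the ln(OD) scale."""

    y0: float
    ymax: float
    mu_max: float
    h0: float

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.h0 < 0:
            raise ValueError("h0 must be non-negative")
        if self.ymax <= self.y0:
            raise ValueError("ymax must exceed y0")


def baranyi_log_density(params: BaranyiParams, t: np.ndarray | float) -> np.ndarray:
    """ln OD(t) under the Baranyi-Roberts model; y(0) = y0 exactly."""
    t = np.asarray(t, dtype=float)
    return _baranyi(t, params.y0, params.ymax, params.mu_max, params.h0)


def _baranyi(t, y0, ymax, mu, h0):
    # adjustment function A(t) via log-sum-exp for numerical stability
    a = -mu * t
    b = np.full_like(np.asarray(t, dtype=float), -h0)
    # ln(e^a + e^-h0 - e^(a - h0)) = ln(e^a (1 - e^-h0) + e^-h0)
    big = np.maximum(a, b)
    inner = np.exp(a - big) * (1.0 - math.exp(-h0)) + np.exp(b - big)
    A = t + (np.log(inner) + big) / mu
    muA = mu * A
    return y0 + muA - np.log1p(np.expm1(muA) * math.exp(-(ymax - y0)))


def fit_baranyi(times: np.ndarray, od: np.ndarray) -> dict:
    """Nonlinear least squares of the model to one well, on ln(OD).

    OD readings are floored at a small positive constant before the log
    transform.  Initial values for (mu_max, h0) are taken from a fixed
    grid; y0 and ymax start at the observed extremes; the best residual
    sum of squares wins.  Returns a dict with the parameter estimates,
    ``rss``, ``converged``, and ``mgr`` (= mu_max estimate).
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if len(times) < 6:
        raise ValueError("need at least 6 timepoints")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    y = np.log(np.maximum(od, OD_FLOOR))
    y0_init, ymax_init = float(y[0]), float(y.max())
    if ymax_init <= y0_init:
        ymax_init = y0_init + 0.1

    best = None
    lower = [y.min() - 5.0, y.min() - 5.0 + 1e-6, 1e-6, 0.0]
    upper = [y.max() + 5.0, y.max() + 5.0, MU_MAX_BOUND, H0_BOUND]

    def resid(theta):
        p_y0, p_ymax, p_mu, p_h0 = theta
        if p_ymax <= p_y0:
            return np.full_like(y, 1e6)
        return _baranyi(times, p_y0, p_ymax, p_mu, p_h0) - y

    for mu0, h00 in START_GRID:
        x0 = [y0_init, max(ymax_init, y0_init + 0.5), mu0, h00]
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lower, upper), method="trf", xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best["rss"]):
            best = {
                "y0": float(sol.x[0]),
                "ymax": float(sol.x[1]),
                "mu_max": float(sol.x[2]),
                "h0": float(sol.x[3]),
                "rss": rss,
                "converged": True,
            }
    if best is None:
        return {
            "y0": np.nan, "ymax": np.nan, "mu_max": np.nan, "h0": np.nan,
            "rss": np.nan, "converged": False, "mgr": np.nan,
        }
    # a fit pinned at the lower mu bound or with no dynamic range is degenerate
    if best["mu_max"] <= 2e-6 or (best["ymax"] - best["y0"]) < 1e-3:
        best["converged"] = False
    best["mgr"] = best["mu_max"] if best["converged"] else np.nan
    return best


def fit_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Fit every well of a long-format plate table (well, time_h, od)."""
    rows = []
    for well, sub in plate.groupby("well", sort=True):
        sub = sub.sort_values("time_h")
        fit = fit_baranyi(sub["time_h"].to_numpy(), sub["od"].to_numpy())
        fit["well"] = well
        rows.append(fit)
    return pd.DataFrame(rows).set_index("well")


def compare_mgr(mgr_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise MGR comparisons with the adaptive test strategy.

    Groups with fewer than 3 values are excluded.  For each pair the
    residuals (values centered by their group mean) are pooled and
    tested with Shapiro-Wilk; Levene's test (median-centered) checks
    homoscedasticity.  Normal residuals -> two-sample t-test, Welch
    when Levene rejects at 0.05; otherwise Mann-Whitney U.  P-values
    are BH-adjusted over all pairs.
    """
    groups = {
        k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for k, v in mgr_by_group.items()
    }
    usable = {k: v for k, v in groups.items() if len(v) >= 3}
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        va, vb = usable[a], usable[b]
        resid = np.concatenate([va - va.mean(), vb - vb.mean()])
        if np.allclose(resid, resid[0]):
            shapiro_p, levene_p = 1.0, 1.0
            normal, equal_var = True, True
        else:
            shapiro_p = float(stats.shapiro(resid).pvalue)
            levene_p = float(stats.levene(va, vb, center="median").pvalue)
            normal = shapiro_p >= NORMALITY_ALPHA
            equal_var = levene_p >= NORMALITY_ALPHA
        if np.allclose(va, va[0]) and np.allclose(vb, vb[0]) and va[0] == vb[0]:
            test, stat, p = "t", 0.0, 1.0
        elif normal:
            test = "t" if equal_var else "welch"
            res = stats.ttest_ind(va, vb, equal_var=equal_var)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            test = "mannwhitney"
            res = stats.mannwhitneyu(va, vb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "test": test,
                "statistic": stat,
                "pvalue": min(p, 1.0),
                "shapiro_p": shapiro_p,
                "levene_p": levene_p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = adjust_bh(out["pvalue"].to_numpy())
    return out


def generations(n_transfers: int, dilution: float = 20.0) -> int:
    """Number of mitotic generations of a serial-transfer experiment.

    N_g = round(N_t * log2(D)) for N_t transfers at dilution factor D;
    e.g. 52 transfers at 1:20 dilution give 225 generations.
    """
    if n_transfers < 0:
        raise ValueError("number of transfers must be non-negative")
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    return round(n_transfers * math.log2(dilution))
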