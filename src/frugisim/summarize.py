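"""Smooth trajectories, combine them across networks, and compute effect sizes.

Each per-network trajectory (metric vs. % birds removed) is smoothed with a
locally weighted polynomial regression (loess: tricube weights over a
nearest-neighbour window, local quadratic fit by default) and evaluated on a
common grid of 100 points spanning 0-100% removal. Curves are then combined
across networks as a pointwise mean with a t-based 95% confidence band, and
the effect size of downsizing is the pointwise difference between the
downsizing and random curves of the same network, expressed as extra loss
(positive = downsizing is worse), summarised the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extinction_sim import ExtinctionTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GRID",
    "SummaryCurve",
    "loess",
    "smooth_trajectory",
    "cross_network_summary",
    "effect_size",
    "effect_curves",
]

GRID = np.linspace(0.0, 100.0, 100)

#: metrics where loss is recorded as a positive percentage; LDD change is
#: negative under loss, hence the -1 when converting to a loss scale.
LOSS_SIGN = {
    "pct_interactions_lost": 1.0,
    "pct_plants_extinct": 1.0,
    "pct_ldd_change": -1.0,
}


@dataclass(frozen=True)
class SummaryCurve:
    """Cross-network mean +/- 95% CI of a smoothed change metric."""

    metric: str
    grid: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_networks: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pct_birds_removed": self.grid,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def _fit_point(x: np.ndarray, y: np.ndarray, g: float, k: int, degree: int):
    """Weighted local polynomial fit at grid point g using the k nearest x.

    Returns (prediction, condition number of the weighted design matrix).
    """
    d = np.abs(x - g)
    idx = np.argsort(d, kind="stable")[:k]
    dmax = d[idx].max()
    if dmax == 0:
        return float(np.mean(y[idx])), 1.0
    w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, 1.0) ** 3
    pos = w > 0
    deg = min(degree, max(int(pos.sum()) - 1, 0))
    xc = x[idx] - g
    design = np.vander(xc, deg + 1, increasing=True)
    sw = np.sqrt(w)
    a = design * sw[:, None]
    b = y[idx] * sw
    coef, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    if rank < deg + 1:
        cond = np.inf
    return float(coef[0]), cond


def loess(x, y, span: float | None = None, degree: int = 2,
          grid: np.ndarray = GRID, max_cond: float = 1e8) -> np.ndarray:
    """Locally weighted polynomial regression evaluated on ``grid``.

    ``span`` is the fraction of points in each local window (nearest
    neighbours, tricube-weighted). When ``span`` is None the smallest
    feasible span is selected automatically: the smallest window for which
    the local fit is well-conditioned at every grid point (condition number
    below ``max_cond``); the choice is logged. This keeps the fit as close
    to the raw trajectory as a well-posed local regression allows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    k_min = degree + 2
    if span is None:
        k_start = k_min
    else:
        if not 0 < span <= 1:
            raise ValueError(f"span must be in (0, 1], got {span}")
        k_start = max(k_min, int(span * n))
    preds = np.empty(len(grid))
    for k in range(k_start, n + 1):
        ok = True
        for j, g in enumerate(grid):
            pred, cond = _fit_point(x, y, float(g), k, degree)
            if cond > max_cond or not np.isfinite(pred):
                ok = False
                break
            preds[j] = pred
        if ok:
            if span is None:
                logger.debug("loess: selected window of %d/%d points (span %.3f)", k, n, k / n)
            elif k > k_start:
                logger.warning("loess: span %.3f infeasible, increased window to %d/%d points",
                               span, k, n)
            return preds
    raise ValueError("no feasible loess span: data may be degenerate")


def smooth_trajectory(traj: ExtinctionTrajectory, metric: str,
                      span: float | None = None, degree: int = 2,
                      grid: np.ndarray = GRID) -> np.ndarray:
    """Smoothed predictions of one metric of one trajectory on ``grid``."""
    if metric not in traj.steps.columns:
        raise KeyError(f"trajectory has no metric {metric!r}")
    return loess(traj.steps["pct_birds_removed"].to_numpy(),
                 traj.steps[metric].to_numpy(), span=span, degree=degree, grid=grid)


def cross_network_summary(curves: Sequence[np.ndarray], metric: str = "",
                          grid: np.ndarray = GRID, ci_level: float = 0.95,
                          method: str = "t") -> SummaryCurve:
    """Pointwise mean and confidence band of smoothed curves across networks.

    ``method="t"`` (default) uses the t distribution with n-1 degrees of
    freedom; ``"percentile"`` uses empirical quantiles. With one network the
    band is undefined (NaN).
    """
    arr = np.asarray(list(curves), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(grid):
        raise ValueError("curves must all lie on the common grid")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n < 2:
        ci_low = np.full_like(mean, np.nan)
        ci_high = np.full_like(mean, np.nan)
    elif method == "t":
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
        tq = stats.t.ppf(0.5 + ci_level / 2, df=n - 1)
        ci_low, ci_high = mean - tq * sem, mean + tq * sem
    elif method == "percentile":
        alpha = 1 - ci_level
        ci_low = np.quantile(arr, alpha / 2, axis=0)
        ci_high = np.quantile(arr, 1 - alpha / 2, axis=0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return SummaryCurve(metric, grid, mean, ci_low, ci_high, n)


def effect_size(down_curve: np.ndarray, rand_curve: np.ndarray,
                metric: str = "pct_interactions_lost") -> np.ndarray:
    """Extra loss under downsizing vs. random removal, per grid point.

    Both curves must come from the same network and grid. The result is on a
    loss scale where positive values mean downsizing loses more: for loss
    metrics (already positive) it is ``down - random``; for LDD change
    (negative under loss) the sign is flipped.
    """
    down_curve = np.asarray(down_curve, dtype=float)
    rand_curve = np.asarray(rand_curve, dtype=float)
    if down_curve.shape != rand_curve.shape:
        raise ValueError("scenario curves are on different grids")
    sign = LOSS_SIGN.get(metric, 1.0)
    return sign * (down_curve - rand_curve)


def effect_curves(down_curves: Sequence[np.ndarray], rand_curves: Sequence[np.ndarray],
                  metric: str, grid: np.ndarray = GRID) -> SummaryCurve:
    """Cross-network summary of per-network downsizing effect sizes."""
    if len(down_curves) != len(rand_curves):
        raise ValueError("need one downsizing and one random curve per network")
    effects = [effect_size(d, r, metric) for d, r in zip(down_curves, rand_curves)]
    return cross_network_summary(effects, metric=f"effect_{metric}", grid=grid)
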