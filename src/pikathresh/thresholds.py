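"""Loess response curves, peak thresholds and relative change rates.

The disturbance threshold of a diversity metric is the burrow density at
which its loess-fitted response peaks; densities beyond it mark incipient
degradation.  When Shannon diversity and species richness disagree on the
peak, the adopted management threshold is the smaller (conservative) one —
unless the candidates differ by less than a negligible-difference tolerance
(0.5% relative), in which case the minimum is adopted on the grounds that
the metrics effectively agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import RESPONSE_METRICS
from .errors import InvalidParameterError


@dataclass
class LoessFit:
    """A fitted local-polynomial regression and its evaluation grid."""

    x: np.ndarray
    y: np.ndarray
    span: float
    degree: int
    grid: np.ndarray
    fitted: np.ndarray

    def predict(self, x_new) -> np.ndarray:
        return _loess_predict(self.x, self.y, np.atleast_1d(np.asarray(x_new, float)),
                              self.span, self.degree)


@dataclass
class ThresholdDecision:
    """Per-type candidate peak densities and the adopted threshold."""

    grassland_type: str
    candidates: dict  # metric -> peak density (holes/ha)
    adopted: float
    principle: str  # "conservative" | "negligible-difference"
    tolerance: float = 0.005
    boundary_flags: dict = field(default_factory=dict)  # metric -> peak hit grid edge


def _loess_predict(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                   span: float, degree: int) -> np.ndarray:
    n = x.size
    k = int(np.ceil(span * n))
    k = max(k, degree + 1)
    k = min(k, n)
    out = np.empty(grid.size)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(k)
        else:
            w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, None) ** 3
        if w.sum() <= 0 or (w > 0).sum() < degree + 1:
            raise InvalidParameterError(
                f"loess window at x={x0:g} has fewer than degree+1 weighted points; "
                "increase span"
            )
        # local polynomial in (x − x0): the intercept is the fitted value
        basis = np.vander(x[idx] - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(basis * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def loess_fit(x, y, span: float = 0.75, degree: int = 2, grid_size: int = 512) -> LoessFit:
    """Locally weighted polynomial regression with tricube weights.

    At each evaluation point the ``ceil(span·n)`` nearest training points
    are fit by a weighted polynomial of ``degree``; the classical tricube
    kernel w = (1 − (d/d_max)³)³ downweights distant points.  A noiseless
    polynomial of degree ≤ ``degree`` is reproduced exactly.  No robustness
    iterations are applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be 1-D arrays of equal length")
    if not (0 < span <= 1):
        raise InvalidParameterError(f"span must lie in (0, 1], got {span}")
    if degree not in (0, 1, 2):
        raise InvalidParameterError(f"degree must be 0, 1 or 2, got {degree}")
    if np.unique(x).size < degree + 2:
        raise InvalidParameterError("need at least degree + 2 distinct x values")
    if int(np.ceil(span * x.size)) < degree + 1:
        raise InvalidParameterError("span·n must be at least degree + 1")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = _loess_predict(x, y, grid, span, degree)
    if not np.isfinite(fitted).all():
        raise InvalidParameterError("loess produced non-finite fitted values")
    return LoessFit(x=x, y=y, span=span, degree=degree, grid=grid, fitted=fitted)


def find_peak(fit: LoessFit) -> tuple:
    """Density at the maximum of the fitted curve on its evaluation grid.

    Ties break toward the lowest density (the protective choice).  Returns
    ``(peak_density, is_boundary)``: a peak on the first grid point signals
    a degraded monotone response with no interior optimum.
    """
    vals = fit.fitted
    best = np.flatnonzero(vals == vals.max())[0]
    peak = float(fit.grid[best])
    is_boundary = best == 0 or best == vals.size - 1
    return peak, bool(is_boundary)


def adopt_threshold(candidates: dict, tolerance: float = 0.005,
                    grassland_type: str = "", boundary_flags: dict | None = None) -> ThresholdDecision:
    """Apply the conservative threshold-adoption rule to candidate peaks.

    The adopted threshold is the minimum candidate.  If the candidates'
    relative spread (max − min)/max falls below ``tolerance`` the metrics
    are considered to agree ("negligible-difference"); otherwise the
    minimum is adopted as the conservative value preserving every diversity
    dimension.
    """
    if not candidates:
        raise InvalidParameterError("no candidate thresholds supplied")
    vals = np.array(list(candidates.values()), dtype=float)
    if (vals <= 0).any() or not np.isfinite(vals).all():
        raise InvalidParameterError(f"candidates must be positive and finite: {candidates}")
    spread = (vals.max() - vals.min()) / vals.max()
    principle = "negligible-difference" if spread < tolerance else "conservative"
    return ThresholdDecision(
        grassland_type=grassland_type,
        candidates=dict(candidates),
        adopted=float(vals.min()),
        principle=principle,
        tolerance=tolerance,
        boundary_flags=dict(boundary_flags or {}),
    )


def diversity_thresholds(
    indicators: pd.DataFrame,
    grassland_type: str,
    metrics: tuple = ("SW", "SR"),
    span: float = 0.75,
    degree: int = 2,
    grid_size: int = 512,
    tolerance: float = 0.005,
) -> ThresholdDecision:
    """Loess-fit each diversity metric against burrow density and adopt a threshold."""
    sub = indicators[indicators["type"] == grassland_type]
    if sub.empty:
        raise InvalidParameterError(f"no plots of type {grassland_type!r}")
    x = sub["EH"].to_numpy(dtype=float)
    candidates, flags = {}, {}
    for m in metrics:
        fit = loess_fit(x, sub[m].to_numpy(dtype=float), span=span, degree=degree,
                        grid_size=grid_size)
        peak, boundary = find_peak(fit)
        candidates[m] = peak
        flags[m] = boundary
    return adopt_threshold(candidates, tolerance=tolerance,
                           grassland_type=grassland_type, boundary_flags=flags)


def relative_change_rate(baseline: float, value: float) -> float:
    """Percent change of ``value`` relative to ``baseline``: 100·(v − b)/b."""
    if baseline == 0:
        raise InvalidParameterError("relative change undefined for zero baseline")
    return 100.0 * (value - baseline) / baseline


def change_table(
    indicators: pd.DataFrame,
    levels: pd.Series,
    metrics: list | None = None,
    density_quantile: float = 0.90,
) -> pd.DataFrame:
    """Relative change of each metric from the least- to the most-disturbed state.

    Per grassland type: baseline = mean over level-I plots (no significant
    disturbance); comparison value = mean over plots above the
    ``density_quantile`` of burrow density within the type.  Returns a
    (type × metric) table of percent changes.
    """
    metrics = metrics or RESPONSE_METRICS
    df = indicators.copy()
    if "plot_id" in df.columns:
        df = df.set_index("plot_id")
    df["level"] = levels.reindex(df.index)
    rows = {}
    for gtype, sub in df.groupby("type", sort=True):
        base = sub[sub["level"] == "I"]
        cut = sub["EH"].quantile(density_quantile)
        top = sub[sub["EH"] >= cut]
        missing = [name for name, grp in (("level-I baseline", base), ("top-density", top))
                   if grp.empty]
        if missing:
            raise InvalidParameterError(
                f"type {gtype!r}: empty group(s) for change table: {missing}"
            )
        rows[gtype] = {
            m: relative_change_rate(float(base[m].mean()), float(top[m].mean()))
            for m in metrics
        }
    return pd.DataFrame.from_dict(rows, orient="index")[metrics]
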