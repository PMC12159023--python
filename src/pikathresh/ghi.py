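"""Grassland health index (GHI) and disturbance-level classification.

GHI = Σ_i v_i·w_i, where v_i are min-max standardized plot indicators
(oriented so that larger always means healthier) and w_i are weights from a
principal-components analysis of the indicator correlation matrix: each
indicator's weight is the variance-explained-weighted sum of its absolute
loadings over the Kaiser-retained components, normalized to sum to one.
Sampling adequacy is reported with the Kaiser-Meyer-Olkin measure and
Bartlett's test of sphericity.  Plots are then partitioned into four
disturbance levels (I = no significant … IV = heavy) by Ward hierarchical
clustering of the scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2 as chi2_dist

from .diversity import INDICATOR_COLUMNS
from .errors import InvalidParameterError, NearSingularityError

#: default orientation of each indicator: +1 if larger is healthier.
#: Effective burrow density (EH) is the disturbance variable itself, so it
#: is reversed — the only direction under which the score is a health index.
DEFAULT_ORIENTATIONS = {
    "VC": +1, "AB": +1, "EH": -1, "CH": +1, "SR": +1, "HB": +1, "SW": +1,
}

LEVEL_LABELS = ["I", "II", "III", "IV"]


@dataclass
class IndicatorMatrix:
    """Min-max standardized indicators, one row per plot, values in [0, 1]."""

    values: pd.DataFrame  # index = plot_id
    orientations: dict
    dropped: list = field(default_factory=list)  # zero-variance columns

    @property
    def columns(self) -> list:
        return list(self.values.columns)


@dataclass
class GHIResult:
    weights: pd.Series  # per retained indicator, sums to 1
    kmo: float
    bartlett_chi2: float
    bartlett_p: float
    scores: pd.Series  # GHI per plot, in [0, 1]
    levels: pd.Series  # "I".."IV" per plot
    linkage_matrix: np.ndarray
    dropped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ghi": self.scores, "level": self.levels})


def min_max_standardize(raw: pd.DataFrame, orientations: dict | None = None) -> IndicatorMatrix:
    """Map each column to [0, 1]; reversed columns use (max − x)/(max − min).

    Zero-variance columns carry no ranking information and are dropped with
    a warning.  Requires at least two rows.
    """
    if len(raw) < 2:
        raise InvalidParameterError("min-max standardization needs >= 2 plots")
    orientations = dict(orientations or DEFAULT_ORIENTATIONS)
    out, dropped, kept_orient = {}, [], {}
    for col in raw.columns:
        x = raw[col].astype(float)
        lo, hi = x.min(), x.max()
        if not np.isfinite([lo, hi]).all():
            raise InvalidParameterError(f"non-finite values in indicator {col!r}")
        if hi == lo:
            dropped.append(col)
            warnings.warn(f"indicator {col!r} has zero variance and was dropped", stacklevel=2)
            continue
        sense = orientations.get(col, +1)
        out[col] = (x - lo) / (hi - lo) if sense >= 0 else (hi - x) / (hi - lo)
        kept_orient[col] = +1 if sense >= 0 else -1
    return IndicatorMatrix(values=pd.DataFrame(out, index=raw.index), orientations=kept_orient,
                           dropped=dropped)


def _correlation(x: np.ndarray) -> np.ndarray:
    r = np.corrcoef(x, rowvar=False)
    return np.atleast_2d(r)


def kmo_from_correlation(r: np.ndarray) -> float:
    """Overall KMO from a correlation matrix.

    KMO = Σ r² / (Σ r² + Σ q²) over off-diagonal entries, where q are the
    anti-image partial correlations q_ij = −s_ij/√(s_ii s_jj), S = R⁻¹.
    """
    r = np.asarray(r, dtype=float)
    p = r.shape[0]
    if p < 2:
        raise InvalidParameterError("KMO needs >= 2 variables")
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise NearSingularityError(f"correlation matrix is singular: {exc}") from exc
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    q = -s / d
    off = ~np.eye(p, dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def kmo(data) -> float:
    """KMO sampling-adequacy measure of a (plots × indicators) data matrix."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InvalidParameterError("KMO needs >= 3 rows and >= 2 columns")
    r = _correlation(x)
    cond = np.linalg.cond(r)
    if not np.isfinite(cond) or cond > 1e12:
        worst = _most_collinear_columns(r)
        raise NearSingularityError(
            f"correlation matrix near-singular (cond={cond:.3g}); "
            f"most collinear column pair: {worst}"
        )
    return kmo_from_correlation(r)


def _most_collinear_columns(r: np.ndarray):
    off = np.abs(r - np.eye(r.shape[0]))
    i, j = np.unravel_index(np.argmax(off), off.shape)
    return (int(i), int(j))


def bartlett_sphericity(data) -> tuple:
    """Bartlett's test that the correlation matrix is the identity.

    chi² = −(n − 1 − (2p+5)/6)·ln det R on p(p−1)/2 degrees of freedom.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n <= p:
        raise InvalidParameterError(f"Bartlett needs more rows ({n}) than columns ({p})")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise NearSingularityError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(chi2_dist.sf(chi2, df))
    return float(chi2), pval


def pca_weights(matrix: IndicatorMatrix | pd.DataFrame, eigenvalue_threshold: float = 1.0) -> pd.Series:
    """Composite-index weights from a PCA of the indicator correlations.

    Components with eigenvalue above ``eigenvalue_threshold`` (Kaiser rule;
    at least one always) are retained; indicator i gets
    w_i ∝ Σ_k varexp_k·|loading_ik|, normalized to Σ w_i = 1.
    """
    vals = matrix.values if isinstance(matrix, IndicatorMatrix) else matrix
    x = vals.to_numpy(dtype=float)
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise InvalidParameterError("PCA weighting needs >= 3 plots and >= 2 indicators")
    r = _correlation(x)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    retained = evals > eigenvalue_threshold
    if not retained.any():
        retained[0] = True
    lam = evals[retained]
    load = np.abs(evecs[:, retained]) * np.sqrt(np.maximum(lam, 0.0))
    varexp = lam / evals.sum()
    w = (load * varexp).sum(axis=1)
    w = w / w.sum()
    return pd.Series(w, index=vals.columns, name="weight")


def ghi_score(matrix: IndicatorMatrix | pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Per-plot weighted sum of standardized indicators; lies in [0, 1]."""
    vals = matrix.values if isinstance(matrix, IndicatorMatrix) else matrix
    if list(vals.columns) != list(weights.index):
        raise InvalidParameterError(
            f"weights {list(weights.index)} are not aligned with indicators {list(vals.columns)}"
        )
    return pd.Series(vals.to_numpy(dtype=float) @ weights.to_numpy(dtype=float),
                     index=vals.index, name="ghi")


def classify_disturbance(scores: pd.Series, k: int = 4) -> tuple:
    """Ward-cluster the 1-D GHI scores into k disturbance levels.

    Clusters are labeled I (highest mean GHI = healthiest) through IV
    (lowest).  Returns ``(levels, linkage_matrix)``.  Ties in cluster means
    are broken by the smallest member plot id for a deterministic output.
    """
    s = scores.astype(float)
    if s.nunique() < k:
        raise InvalidParameterError(
            f"only {s.nunique()} distinct scores; choose k <= that (got k={k})"
        )
    z = linkage(s.to_numpy()[:, None], method="ward")
    assign = fcluster(z, t=k, criterion="maxclust")
    order = sorted(
        np.unique(assign),
        key=lambda c: (-s[assign == c].mean(), min(str(i) for i in s.index[assign == c])),
    )
    labels = _level_names(k)
    mapping = {c: labels[rank] for rank, c in enumerate(order)}
    levels = pd.Series([mapping[c] for c in assign], index=s.index, name="level")
    return levels, z


def _level_names(k: int) -> list:
    if k <= len(LEVEL_LABELS):
        return LEVEL_LABELS[:k]
    return LEVEL_LABELS + [f"L{i}" for i in range(len(LEVEL_LABELS) + 1, k + 1)]


def build_ghi(
    indicators: pd.DataFrame,
    orientations: dict | None = None,
    k: int = 4,
    eigenvalue_threshold: float = 1.0,
    columns: list | None = None,
) -> GHIResult:
    """Standardize → adequacy statistics → PCA weights → scores → levels.

    ``indicators`` has one row per plot (index or ``plot_id`` column) with
    the seven indicator columns.  Typically called once per grassland type.
    """
    df = indicators.copy()
    if "plot_id" in df.columns:
        df = df.set_index("plot_id")
    cols = columns or [c for c in INDICATOR_COLUMNS if c in df.columns]
    if not cols:
        raise InvalidParameterError("no indicator columns found")
    raw = df[cols]
    std = min_max_standardize(raw, orientations)
    x = raw[std.columns].to_numpy(dtype=float)
    adequacy_kmo = kmo(x)
    chi2, pval = bartlett_sphericity(x)
    weights = pca_weights(std, eigenvalue_threshold)
    scores = ghi_score(std, weights)
    levels, z = classify_disturbance(scores, k=k)
    return GHIResult(
        weights=weights, kmo=adequacy_kmo, bartlett_chi2=chi2, bartlett_p=pval,
        scores=scores, levels=levels, linkage_matrix=z, dropped=std.dropped,
    )
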