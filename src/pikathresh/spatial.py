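"""Spatial and nonparametric statistics: geodesic distances, dbMEM,
Moran's I, permutation Mantel tests and the Wilcoxon rank-sum test.

Distance-based Moran's eigenvector maps (dbMEM) turn plot coordinates into
orthogonal multi-scale spatial predictors: the geographic distance matrix is
truncated at the longest minimum-spanning-tree edge (distances beyond it set
to four times the threshold), Gower double-centered, and eigendecomposed;
eigenvectors with positive eigenvalues are the MEM variables, broad-scale
first.  Mantel tests correlate unfolded distance matrices with significance
from simultaneous row/column permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.stats import norm, rankdata

from .errors import InvalidParameterError
from .synthetic import EARTH_RADIUS_KM

__all__ = [
    "DistanceMatrix", "MEMBasis", "MantelResult",
    "geodesic_distance_matrix", "euclidean_distance_matrix", "dbmem",
    "morans_i", "mantel", "mantel_screen", "wilcoxon_rank_sum",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with a zero diagonal and plot labels."""

    values: np.ndarray
    labels: list
    units: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise InvalidParameterError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise InvalidParameterError("distance matrix must be nonnegative")
        self.values = v
        if len(self.labels) != v.shape[0]:
            raise InvalidParameterError("labels do not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class MEMBasis:
    """Retained spatial eigenvectors (columns) with their eigenvalues."""

    eigenvectors: np.ndarray  # plots × axes
    eigenvalues: np.ndarray  # descending, all > 0
    truncation_km: float
    labels: list

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"MEM{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.eigenvectors, index=self.labels, columns=cols)


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    method: str
    seed: int | None = None


def geodesic_distance_matrix(coordinates, labels=None) -> DistanceMatrix:
    """Pairwise haversine distances (km, sphere radius 6371) between
    (latitude, longitude) pairs in WGS84 decimal degrees."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InvalidParameterError("coordinates must be (n, 2) lat/lon pairs")
    lat, lon = coords[:, 0], coords[:, 1]
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise InvalidParameterError("latitude must be in [-90, 90], longitude in [-180, 180]")
    la = np.radians(lat)[:, None]
    lo = np.radians(lon)[:, None]
    a = (np.sin((la - la.T) / 2) ** 2
         + np.cos(la) * np.cos(la.T) * np.sin((lo - lo.T) / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    labels = list(labels) if labels is not None else list(range(coords.shape[0]))
    return DistanceMatrix(values=d, labels=labels, units="km")


def euclidean_distance_matrix(values, labels=None, units: str = "") -> DistanceMatrix:
    """Euclidean distances between rows of a (n,) or (n, d) value array."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    labels = list(labels) if labels is not None else list(range(x.shape[0]))
    return DistanceMatrix(values=d, labels=labels, units=units)


def dbmem(dist: DistanceMatrix, rel_tolerance: float = 1e-9) -> MEMBasis:
    """Distance-based Moran's eigenvector maps of a geographic distance matrix.

    Truncation threshold = longest edge of the minimum spanning tree (the
    shortest link keeping all plots connected); larger distances are
    replaced by 4× the threshold; −d²/2 is Gower double-centered and
    eigendecomposed.  Eigenvectors whose eigenvalues exceed
    ``rel_tolerance`` × the largest eigenvalue are retained, in decreasing
    eigenvalue order (broad-scale structure first).
    """
    if dist.n < 3:
        raise InvalidParameterError("dbMEM needs at least 3 plots")
    d = dist.values
    mst = minimum_spanning_tree(d).toarray()
    threshold = float(mst.max())
    if threshold <= 0:
        raise InvalidParameterError("degenerate coordinates: zero-length spanning tree")
    trunc = np.where(d > threshold, 4.0 * threshold, d)
    np.fill_diagonal(trunc, 0.0)
    a = -0.5 * trunc**2
    n = dist.n
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    g = centerer @ a @ centerer
    g = (g + g.T) / 2
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rel_tolerance * evals[0]
    return MEMBasis(
        eigenvectors=evecs[:, keep],
        eigenvalues=evals[keep],
        truncation_km=threshold,
        labels=list(dist.labels),
    )


def morans_i(values, weights) -> float:
    """Moran's spatial autocorrelation I of ``values`` under a weight matrix.

    I = (n/ΣW)·Σ_ij w_ij z_i z_j / Σ_i z_i², z = x − x̄.  Null expectation
    is −1/(n−1); positive I means similar values cluster in space.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise InvalidParameterError("Moran's I needs at least 3 values")
    if w.shape != (n, n):
        raise InvalidParameterError("weights must be n × n")
    if (w < 0).any() or not np.allclose(np.diag(w), 0.0):
        raise InvalidParameterError("weights must be nonnegative with a zero diagonal")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise InvalidParameterError("Moran's I undefined for zero-variance values")
    return float(n / w.sum() * (w * np.outer(z, z)).sum() / denom)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _mantel_r(a_vec: np.ndarray, b_vec: np.ndarray, method: str) -> float:
    if method == "spearman":
        a_vec = rankdata(a_vec)
        b_vec = rankdata(b_vec)
    elif method != "pearson":
        raise InvalidParameterError(f"unknown method {method!r}")
    a0 = a_vec - a_vec.mean()
    b0 = b_vec - b_vec.mean()
    denom = np.sqrt((a0**2).sum() * (b0**2).sum())
    if denom == 0:
        raise InvalidParameterError("Mantel r undefined: a distance matrix is constant")
    return float((a0 * b0).sum() / denom)


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    n_permutations: int = 999,
    method: str = "pearson",
    seed: int | None = None,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices with permutation p.

    r is the (Pearson or Spearman) correlation of the strict upper
    triangles; the null distribution simultaneously permutes the rows and
    columns of the second matrix.  One-sided (positive association) by
    default, ``alternative="two-sided"`` doubles the smaller tail.  With
    ``exhaustive=True`` all n! relabelings are enumerated and the p-value
    is exact (only sensible for small n).
    """
    if dist_a.n != dist_b.n:
        raise InvalidParameterError(f"matrix sizes differ: {dist_a.n} vs {dist_b.n}")
    if list(dist_a.labels) != list(dist_b.labels):
        raise InvalidParameterError("distance-matrix labels differ or are misordered")
    n = dist_a.n
    if n < 4:
        raise InvalidParameterError("Mantel test needs at least 4 objects")
    a_vec = _upper(dist_a.values)
    b = dist_b.values
    r_obs = _mantel_r(a_vec, _upper(b), method)

    def tail_p(r_perm: np.ndarray, count: int) -> float:
        eps = 1e-12
        if exhaustive:
            ge = (r_perm >= r_obs - eps).sum()
            le = (r_perm <= r_obs + eps).sum()
            if alternative == "greater":
                return ge / count
            return min(1.0, 2.0 * min(ge / count, le / count))
        ge = 1 + (r_perm >= r_obs - eps).sum()
        le = 1 + (r_perm <= r_obs + eps).sum()
        if alternative == "greater":
            return ge / (count + 1)
        return min(1.0, 2.0 * min(ge / (count + 1), le / (count + 1)))

    if exhaustive:
        r_perm = np.array([
            _mantel_r(a_vec, _upper(b[np.ix_(p, p)]), method)
            for p in map(list, permutations(range(n)))
        ])
        p_val = tail_p(r_perm, r_perm.size)
        return MantelResult(r=r_obs, p=float(p_val), n_permutations=r_perm.size,
                           method=method, seed=seed)

    if n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        r_perm[i] = _mantel_r(a_vec, _upper(b[np.ix_(perm, perm)]), method)
    p_val = tail_p(r_perm, n_permutations)
    return MantelResult(r=r_obs, p=float(p_val), n_permutations=n_permutations,
                        method=method, seed=seed)


def mantel_screen(
    response_dist: DistanceMatrix,
    predictors: dict,
    n_permutations: int = 999,
    method: str = "pearson",
    seed: int | None = None,
) -> pd.DataFrame:
    """One Mantel test per named predictor distance matrix.

    Returns a table (one row per predictor, input order preserved) with r,
    permutation p and significance bin ("p<0.01", "p<0.05" or "ns").  Each
    test draws from an independent seeded stream.
    """
    rows = []
    base = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    children = base.spawn(len(predictors))
    for (name, dmat), child in zip(predictors.items(), children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        res = mantel(response_dist, dmat, n_permutations=n_permutations,
                     method=method, seed=sub_seed)
        rows.append({
            "predictor": name, "r": res.r, "p": res.p,
            "n_permutations": res.n_permutations,
            "significance": "p<0.01" if res.p < 0.01 else ("p<0.05" if res.p < 0.05 else "ns"),
        })
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(x, y, exact_limit: int = 16) -> tuple:
    """Two-sample Wilcoxon rank-sum test; returns (W, two-sided p).

    W is the rank sum of the first sample using midranks for ties.  When
    m + n ≤ ``exact_limit`` and there are no ties, the p-value is exact:
    all C(m+n, m) equally likely rank assignments are enumerated and the
    two-sided p doubles the smaller tail (capped at 1).  Otherwise a normal
    approximation with tie correction and a 0.5 continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise InvalidParameterError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if (m + n) <= exact_limit and not has_ties:
        total = m + n
        all_ranks = np.arange(1, total + 1)
        sums = np.fromiter(
            (sum(c) for c in combinations(all_ranks, m)), dtype=float,
        )
        count = sums.size
        p_le = (sums <= w + 1e-9).sum() / count
        p_ge = (sums >= w - 1e-9).sum() / count
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w, float(p)

    total = m + n
    mu = m * (total + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((total) * (total - 1))
    var = m * n / 12.0 * ((total + 1) - tie_term)
    if var <= 0:  # every observation identical
        return w, 1.0
    diff = w - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return w, p
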