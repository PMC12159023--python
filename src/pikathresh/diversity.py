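"""Per-quadrat and per-plot community metrics.

The downstream health-index and threshold stages consume one row per plot
with seven disturbance-related indicators: Shannon-Wiener diversity (SW,
nats), species richness (SR), aboveground dry biomass (AB, g/m²), mean
community height (CH, cm), vegetation cover (VC, proportion), proportion of
edible forage (HB, proportion) and effective burrow-entrance density (EH,
holes/ha).  Quadrat-level metrics are averaged within a plot; richness is
the pooled species count across the plot's quadrats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCommunityError, InvalidParameterError

#: canonical indicator column order used throughout the package
INDICATOR_COLUMNS = ["VC", "AB", "EH", "CH", "SR", "HB", "SW"]

#: diversity/vegetation metrics reported in change-rate tables (EH excluded:
#: it is the gradient variable, not a response)
RESPONSE_METRICS = ["SW", "SR", "AB", "CH", "VC", "HB"]


@dataclass(frozen=True)
class PlotIndicators:
    """The seven per-plot metrics plus identity and location metadata."""

    plot_id: str
    grassland_type: str  # "AM" | "AS"
    shannon: float  # nats
    richness: int
    biomass: float  # g dry weight / m²
    height: float  # cm
    cover: float  # proportion in [0, 1]
    edible_proportion: float  # proportion in [0, 1]
    effective_holes: float  # burrow entrances / ha
    latitude: float = float("nan")
    longitude: float = float("nan")

    def as_row(self) -> dict:
        return {
            "plot_id": self.plot_id,
            "type": self.grassland_type,
            "lat": self.latitude,
            "lon": self.longitude,
            "VC": self.cover,
            "AB": self.biomass,
            "EH": self.effective_holes,
            "CH": self.height,
            "SR": self.richness,
            "HB": self.edible_proportion,
            "SW": self.shannon,
        }


def shannon_wiener(abundances: Sequence[float]) -> float:
    """Shannon-Wiener diversity H = −Σ p_i ln p_i in nats.

    Species with zero abundance contribute nothing.  Raises
    :class:`EmptyCommunityError` when no species has positive abundance.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size and (a < 0).any():
        raise InvalidParameterError("abundances must be nonnegative")
    total = a.sum()
    if total <= 0:
        raise EmptyCommunityError("all-zero abundance vector has no diversity")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def species_richness(abundances: Sequence[float]) -> int:
    """Number of species with positive abundance (0 for an empty vector)."""
    a = np.asarray(abundances, dtype=float)
    if a.size == 0:
        return 0
    return int((a > 0).sum())


def edible_proportion(abundances: Sequence[float], edible_flags: Sequence[bool]) -> float:
    """Share of total abundance contributed by edible-forage species."""
    a = np.asarray(abundances, dtype=float)
    e = np.asarray(edible_flags, dtype=bool)
    if a.shape != e.shape:
        raise InvalidParameterError(
            f"abundances ({a.shape}) and edible_flags ({e.shape}) differ in length"
        )
    total = a.sum()
    if total <= 0:
        raise EmptyCommunityError("edible proportion undefined for an empty community")
    return float(a[e].sum() / total)


def aggregate_plot(quadrats: pd.DataFrame, plot_meta: dict) -> PlotIndicators:
    """Collapse a plot's quadrat records into one :class:`PlotIndicators` row.

    ``quadrats`` is long-format: one row per (quadrat_id, species_id) with
    columns ``plot_id, quadrat_id, species_id, abundance, edible, cover,
    height_cm, biomass_g_m2``.  Continuous metrics (cover, height, biomass,
    Shannon, edible proportion) are arithmetic means over quadrats; richness
    is the count of distinct species with positive abundance pooled across
    quadrats.
    """
    plot_ids = quadrats["plot_id"].unique()
    if len(plot_ids) != 1:
        raise InvalidParameterError(f"mixed plot_ids in quadrat table: {sorted(plot_ids)}")
    if str(plot_ids[0]) != str(plot_meta["plot_id"]):
        raise InvalidParameterError(
            f"quadrat plot_id {plot_ids[0]!r} does not match metadata {plot_meta['plot_id']!r}"
        )

    shannons, edibles, covers, heights, biomasses = [], [], [], [], []
    for _, q in quadrats.groupby("quadrat_id", sort=True):
        ab = q["abundance"].to_numpy(dtype=float)
        if ab.sum() > 0:
            shannons.append(shannon_wiener(ab))
            edibles.append(edible_proportion(ab, q["edible"].to_numpy(dtype=bool)))
        else:  # explicitly bare quadrat
            shannons.append(0.0)
            edibles.append(0.0)
        covers.append(float(q["cover"].iloc[0]))
        heights.append(float(q["height_cm"].iloc[0]))
        biomasses.append(float(q["biomass_g_m2"].iloc[0]))

    pooled = quadrats.loc[quadrats["abundance"] > 0, "species_id"].nunique()
    return PlotIndicators(
        plot_id=str(plot_meta["plot_id"]),
        grassland_type=str(plot_meta["type"]),
        shannon=float(np.mean(shannons)),
        richness=int(pooled),
        biomass=float(np.mean(biomasses)),
        height=float(np.mean(heights)),
        cover=float(np.mean(covers)),
        edible_proportion=float(np.mean(edibles)),
        effective_holes=float(plot_meta["effective_holes"]),
        latitude=float(plot_meta.get("lat", float("nan"))),
        longitude=float(plot_meta.get("lon", float("nan"))),
    )


def build_plot_indicators(quadrats: pd.DataFrame, plots: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`aggregate_plot` to every plot; returns one row per plot.

    ``plots`` carries plot metadata (type, lat, lon, effective_holes and any
    covariate columns); covariates are passed through unchanged.
    """
    rows = []
    covariate_cols = [
        c for c in plots.columns
        if c not in {"plot_id", "type", "lat", "lon", "effective_holes"}
    ]
    meta_by_id = plots.set_index(plots["plot_id"].astype(str))
    for pid, q in quadrats.groupby(quadrats["plot_id"].astype(str), sort=True):
        meta = meta_by_id.loc[pid].to_dict()
        meta["plot_id"] = pid
        row = aggregate_plot(q, meta).as_row()
        for c in covariate_cols:
            row[c] = meta[c]
        rows.append(row)
    return pd.DataFrame(rows)
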