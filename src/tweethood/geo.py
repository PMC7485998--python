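"""Spatial join of tweets to zones and zone-level exposure construction.

Zones play the role of zip-code areas: each classified tweet is assigned to
the zone whose polygon contains it, per-zone percentages of each tweet
category are computed, zones are cut into tertiles per characteristic, and
continuous zone covariates can be masked to 20-quantile group medians (a
disclosure-protection transform).

Point-in-polygon uses even-odd ray casting on planar lon/lat coordinates;
at zip-code scale the curvature error is negligible.  Boundary points count
as inside, so edge tweets are never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Zone",
    "point_in_polygon",
    "assign_zone",
    "aggregate_zone",
    "tertile_cut",
    "quantile_mask",
    "zones_from_geojson",
    "zones_to_geojson",
    "CHARACTERISTICS",
]

#: The four zone characteristics used as model predictors, plus overall food.
CHARACTERISTICS = ("happy", "physical_activity", "healthy_food", "fast_food")

Ring = Sequence[tuple[float, float]]


@dataclass(frozen=True)
class Zone:
    """A zone polygon (possibly multi-ring) with a stable identifier."""

    zone_id: str
    rings: tuple[tuple[tuple[float, float], ...], ...]
    bbox: tuple[float, float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        norm = []
        for ring in self.rings:
            ring = [tuple(map(float, v)) for v in ring]
            if len(ring) < 3:
                raise ValueError(f"zone {self.zone_id}: ring with <3 vertices")
            if ring[0] == ring[-1]:
                ring = ring[:-1]  # store open rings internally
            if len(ring) < 3:
                raise ValueError(f"zone {self.zone_id}: degenerate ring")
            norm.append(tuple(ring))
        object.__setattr__(self, "rings", tuple(norm))
        xs = [v[0] for ring in self.rings for v in ring]
        ys = [v[1] for ring in self.rings for v in ring]
        object.__setattr__(self, "bbox", (min(xs), min(ys), max(xs), max(ys)))
        if self.bbox[0] == self.bbox[2] or self.bbox[1] == self.bbox[3]:
            raise ValueError(f"zone {self.zone_id}: zero-area polygon")

    def contains(self, lon: float, lat: float) -> bool:
        x0, y0, x1, y1 = self.bbox
        if not (x0 <= lon <= x1 and y0 <= lat <= y1):
            return False
        return point_in_polygon((lon, lat), self.rings)


def _on_segment(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12 * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    return min(ax, bx) - 1e-15 <= px <= max(ax, bx) + 1e-15 and min(ay, by) - 1e-15 <= py <= max(ay, by) + 1e-15


def point_in_polygon(point: tuple[float, float], rings: Iterable[Ring]) -> bool:
    """Even-odd ray-casting containment test; boundary points are inside.

    ``rings`` is one or more closed rings (closing vertex optional); holes
    follow from the even-odd rule.  Raises ValueError for a ring with fewer
    than three distinct vertices.
    """
    px, py = float(point[0]), float(point[1])
    inside = False
    any_ring = False
    for ring in rings:
        verts = [tuple(map(float, v)) for v in ring]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError("polygon ring must have at least 3 distinct vertices")
        any_ring = True
        n = len(verts)
        for i in range(n):
            ax, ay = verts[i]
            bx, by = verts[(i + 1) % n]
            if _on_segment(px, py, ax, ay, bx, by):
                return True
            # edge crosses the horizontal ray to the right of the point
            if (ay > py) != (by > py):
                x_cross = ax + (py - ay) * (bx - ax) / (by - ay)
                if x_cross > px:
                    inside = not inside
    if not any_ring:
        raise ValueError("polygon has no rings")
    return inside


def assign_zone(
    points: Sequence[tuple[float, float]], zones: Sequence[Zone]
) -> tuple[list[str | None], int]:
    """Map each point to the id of the zone containing it.

    Zones are tried in stable input order, so for overlapping zones the
    first match wins (a warning is logged once).  Returns the per-point
    zone ids (None when outside all zones) and the unassigned count.
    """
    ids: list[str | None] = []
    unassigned = 0
    warned = False
    for lon, lat in points:
        hits = [z.zone_id for z in zones if z.contains(lon, lat)]
        if not hits:
            ids.append(None)
            unassigned += 1
            continue
        if len(hits) > 1 and not warned:
            logger.warning("point (%s, %s) falls in %d overlapping zones; using first", lon, lat, len(hits))
            warned = True
        ids.append(hits[0])
    return ids, unassigned


def aggregate_zone(
    classified: pd.DataFrame,
    zones: Sequence[Zone] | Sequence[str],
    min_tweets: int = 1,
) -> pd.DataFrame:
    """Per-zone tweet counts and category percentages.

    ``classified`` needs a ``zone_id`` column plus the five boolean flag
    columns.  The denominator is all tweets assigned to the zone (not
    food-only).  Zones with fewer than ``min_tweets`` assigned tweets are
    emitted with NaN percentages and are excluded from tertile cutting.
    Raises KeyError when a tweet references an unknown zone id.
    """
    zone_ids = [z.zone_id if isinstance(z, Zone) else str(z) for z in zones]
    known = set(zone_ids)
    present = set(classified["zone_id"].dropna().unique())
    unknown = present - known
    if unknown:
        raise KeyError(f"classified tweets reference unknown zone ids: {sorted(unknown)[:5]}")
    flags = ["happy", "food", "healthy_food", "fast_food", "physical_activity"]
    grouped = classified.dropna(subset=["zone_id"]).groupby("zone_id")
    counts = grouped.size().reindex(zone_ids, fill_value=0)
    out = pd.DataFrame({"zone_id": zone_ids, "n_tweets": counts.to_numpy(dtype=int)})
    for flag in flags:
        flagged = grouped[flag].sum().reindex(zone_ids, fill_value=0).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * flagged / out["n_tweets"].to_numpy()
        pct[out["n_tweets"].to_numpy() < max(min_tweets, 1)] = np.nan
        out[f"pct_{flag}"] = pct
    for char in CHARACTERISTICS:
        vals = out[f"pct_{char}"]
        codes = pd.Series(np.nan, index=out.index)
        defined = vals.notna()
        if defined.sum() >= 3:
            codes[defined] = tertile_cut(vals[defined].to_numpy())
        out[f"tertile_{char}"] = codes
    return out


def tertile_cut(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Rank zones into three near-equal groups; 1 = lowest (reference).

    Stable order breaks ties, so group sizes always differ by at most one.
    Requires at least three defined values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("tertile_cut needs at least 3 one-dimensional values")
    if np.isnan(values).any():
        raise ValueError("tertile_cut does not accept NaN; filter first")
    order = np.argsort(values, kind="stable")
    n = len(values)
    codes = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        codes[idx] = rank * 3 // n + 1
    return codes


def quantile_mask(
    values: np.ndarray | Sequence[float], q: int = 20, log_transform: bool = False
) -> np.ndarray:
    """Replace each value with the median of its rank-based q-quantile group.

    With ``log_transform`` the replacement is the natural log of the group
    median (used for median household income).  Rank-preserving: the output
    is a nondecreasing function of the input.  Output order matches input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("quantile_mask needs a non-empty 1-d array")
    if np.isnan(values).any():
        raise ValueError("quantile_mask does not accept NaN")
    if log_transform and (values <= 0).any():
        raise ValueError("log_transform requires strictly positive values")
    n = len(values)
    order = np.argsort(values, kind="stable")
    group = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        group[idx] = rank * q // n if n >= q else rank  # degenerate n<q: one value per group
    out = np.empty(n, dtype=float)
    for g in np.unique(group):
        med = float(np.median(values[group == g]))
        out[group == g] = np.log(med) if log_transform else med
    return out


def mask_zone_covariates(covariates: pd.DataFrame, q: int = 20) -> pd.DataFrame:
    """Apply the disclosure mask to the four standard zone covariates.

    Percent non-Hispanic white, population density, and median age are
    replaced by their q-quantile group medians; median household income by
    the log of its group median.  Masked columns get a ``_masked`` suffix.
    """
    out = covariates.copy()
    for col in ("pct_nonhispanic_white", "population_density", "median_age"):
        out[f"{col}_masked"] = quantile_mask(out[col].to_numpy(), q=q)
    out["median_income_masked"] = quantile_mask(
        out["median_income"].to_numpy(), q=q, log_transform=True
    )
    return out


# -- GeoJSON IO -----------------------------------------------------------


def zones_from_geojson(path: str | Path) -> list[Zone]:
    """Load zones from a GeoJSON FeatureCollection with a zone_id property."""
    obj = json.loads(Path(path).read_text())
    zones: list[Zone] = []
    for feat in obj["features"]:
        geom = feat["geometry"]
        if geom["type"] == "Polygon":
            polys = [geom["coordinates"]]
        elif geom["type"] == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            raise ValueError(f"unsupported geometry type {geom['type']!r}")
        rings = tuple(
            tuple(tuple(v) for v in ring) for poly in polys for ring in poly
        )
        zones.append(Zone(zone_id=str(feat["properties"]["zone_id"]), rings=rings))
    return zones


def zones_to_geojson(zones: Sequence[Zone], path: str | Path) -> None:
    feats = []
    for z in zones:
        rings = [list(ring) + [list(ring[0])] for ring in z.rings]
        rings = [[list(v) for v in ring] for ring in rings]
        feats.append(
            {
                "type": "Feature",
                "properties": {"zone_id": z.zone_id},
                "geometry": {"type": "Polygon", "coordinates": rings},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True))
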