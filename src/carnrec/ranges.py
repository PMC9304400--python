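"""Gridded range maps: presence/origin filtering, rasterization, altitude
masking, richness summation, and realm overlays.

Operations work on an abstract rectangular grid (0-based, row-major,
half-open cell extents of unit size) so the same code runs on a toy 50x50
raster or a real equal-area grid.  Polygon ranges are rasterized by the
cell-center rule — a cell belongs to a range iff its center lies inside the
polygon — with an ``intersects`` rule available for sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from shapely.geometry import Point, box
from shapely.prepared import prep

log = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RangeFeature",
    "RealmMap",
    "filter_features",
    "rasterize",
    "altitude_mask",
    "richness",
    "realm_proportions",
]

_KEEP_ORIGIN = frozenset({"native", "reintroduced"})
_KEEP_PRESENCE = frozenset({"extant", "probably_extant"})


@dataclass(frozen=True)
class GridSpec:
    n_rows: int
    n_cols: int
    cell_area: float = 1.0

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0 or self.cell_area <= 0:
            raise ValueError("grid dimensions and cell area must be positive")

    def contains(self, cell: tuple) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def cell_center(self, cell: tuple) -> tuple:
        r, c = cell
        return (c + 0.5, r + 0.5)  # x = column axis, y = row axis


@dataclass(frozen=True)
class RangeFeature:
    """One range polygon (or explicit cell set) with IUCN coding."""

    species_id: str
    origin: str = "native"
    presence: str = "extant"
    cells: Optional[frozenset] = None
    polygon: object = None  # shapely geometry

    def __post_init__(self):
        if (self.cells is None) == (self.polygon is None):
            raise ValueError("exactly one of cells/polygon must be given")


@dataclass
class RealmMap:
    """Per-cell realm labels plus each realm's type (terrestrial/marine)."""

    labels: np.ndarray  # (rows, cols) array of realm-name strings
    realm_types: dict  # realm -> "terrestrial" | "marine"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        missing = {str(x) for x in self.labels.ravel()} - set(self.realm_types)
        if missing:
            raise ValueError(f"realm map labels without a realm type: {sorted(missing)}")


def filter_features(features: Iterable[RangeFeature]):
    """Keep only native/reintroduced, extant/probably-extant features.

    Returns (retained, excluded_species): species whose every feature was
    dropped are reported so the share of unmappable species can be tracked.
    """
    features = list(features)
    retained = [
        f
        for f in features
        if f.origin in _KEEP_ORIGIN and f.presence in _KEEP_PRESENCE
    ]
    before = {f.species_id for f in features}
    after = {f.species_id for f in retained}
    excluded = sorted(before - after)
    if excluded:
        log.info(
            "filter_features: %d/%d species lost all range features",
            len(excluded),
            len(before),
        )
    return retained, excluded


def rasterize(feature: RangeFeature, grid: GridSpec, rule: str = "center") -> set:
    """Cell set of one range feature on the grid.

    Explicit cell sets pass through (out-of-bounds cells are an error);
    polygons are rasterized by cell-center containment, or by cell-rectangle
    intersection when ``rule="intersects"``.
    """
    if feature.cells is not None:
        bad = [c for c in feature.cells if not grid.contains(c)]
        if bad:
            raise ValueError(f"{feature.species_id}: cells outside grid: {sorted(bad)[:5]}")
        return set(feature.cells)
    geom = feature.polygon
    minx, miny, maxx, maxy = geom.bounds
    if maxx <= 0 or maxy <= 0 or minx >= grid.n_cols or miny >= grid.n_rows:
        log.warning("%s: polygon entirely outside grid", feature.species_id)
        return set()
    prepared = prep(geom)
    r_lo = max(0, int(np.floor(miny)))
    r_hi = min(grid.n_rows, int(np.ceil(maxy)))
    c_lo = max(0, int(np.floor(minx)))
    c_hi = min(grid.n_cols, int(np.ceil(maxx)))
    cells = set()
    for r in range(r_lo, r_hi):
        for c in range(c_lo, c_hi):
            if rule == "center":
                hit = prepared.contains(Point(grid.cell_center((r, c))))
            elif rule == "intersects":
                hit = prepared.intersects(box(c, r, c + 1, r + 1))
            else:
                raise ValueError(f"unknown rasterization rule: {rule}")
            if hit:
                cells.add((r, c))
    return cells


def altitude_mask(cells: set, elevation_grid: np.ndarray, limits) -> set:
    """Remove cells whose elevation falls outside [min, max]; no limits is
    the identity.  Masking only ever shrinks the cell set."""
    if limits is None:
        return set(cells)
    lo, hi = limits
    lo = -np.inf if lo is None else lo
    hi = np.inf if hi is None else hi
    elev = np.asarray(elevation_grid, dtype=float)
    return {(r, c) for (r, c) in cells if lo <= elev[r, c] <= hi}


def richness(range_layers: dict, grid: GridSpec, subset=None) -> np.ndarray:
    """Per-cell species count from a mapping species_id -> cell set.

    ``subset`` restricts the sum to the named species (e.g. recovering
    species only).  Richness is additive over disjoint species subsets and
    satisfies sum(richness) == sum of range sizes.
    """
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    ids = range_layers.keys() if subset is None else [s for s in range_layers if s in set(subset)]
    for sid in ids:
        for (r, c) in range_layers[sid]:
            if not grid.contains((r, c)):
                raise ValueError(f"{sid}: cell ({r},{c}) outside {grid.n_rows}x{grid.n_cols} grid")
            counts[r, c] += 1
    return counts


def realm_proportions(cells: set, realm_map: RealmMap, species_systems) -> dict:
    """Share of a species' range in each applicable realm.

    Marine realms are reported only for partly-marine species and
    terrestrial realms only for partly-terrestrial/freshwater species.  In
    cells where both realm types overlap along coasts the marine label is
    suppressed (terrestrial realm maps are the more reliable there), so each
    cell contributes to exactly one realm type's denominator.
    """
    if not cells:
        log.warning("realm_proportions: empty cell set")
        return {}
    systems = set(species_systems)
    want_marine = "marine" in systems
    want_terrestrial = bool(systems & {"terrestrial", "freshwater"})
    counts: dict[str, int] = {}
    for (r, c) in cells:
        label = str(realm_map.labels[r, c])
        counts[label] = counts.get(label, 0) + 1
    out = {}
    total = sum(counts.values())
    for realm in sorted(realm_map.realm_types):
        rtype = realm_map.realm_types[realm]
        if rtype == "marine" and not want_marine:
            continue
        if rtype == "terrestrial" and not want_terrestrial:
            continue
        out[realm] = counts.get(realm, 0) / total
    return out
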