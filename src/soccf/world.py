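"""Spatial units: homogeneous regions and the geographic pixel grid.

A `Region` is the unit of calculation — uniform climate, soil and feasible
land-use set — carrying its country assignment, area and a rectangular
pixel footprint on a 0.083-degree geographic grid (pixel-center registered,
north-up, longitudes in [-180, 180)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import MonthlyClimate, SoilProfile

__all__ = ["Grid", "Region", "LU_SHARE_CATEGORIES"]

#: Land-use share categories carried by every region, mapping to foreground
#: class categories as cropland->cropland, forestry->forest,
#: grazing->grassland, urban->urban.
LU_SHARE_CATEGORIES = ("cropland", "forestry", "grazing", "urban")

SHARE_TO_CATEGORY = {"cropland": "cropland", "forestry": "forest",
                     "grazing": "grassland", "urban": "urban"}

#: Grid resolution in decimal degrees.
PIXEL_SIZE_DEG = 0.083


@dataclass(frozen=True)
class Grid:
    """North-up geographic grid. ``lat0``/``lon0`` locate the center of the
    top-left pixel."""

    lat0: float
    lon0: float
    n_rows: int
    n_cols: int
    pixel_size: float = PIXEL_SIZE_DEG

    def pixel_center(self, row: int, col: int):
        return (self.lat0 - row * self.pixel_size,
                self.lon0 + col * self.pixel_size)


@dataclass
class Region:
    """A homogeneous territorial unit."""

    region_id: str
    country: str
    area_ha: float
    climate: MonthlyClimate
    soil: SoilProfile
    feasible_classes: tuple
    lu_shares: dict
    c_inputs: dict  # class_id -> annual plant C input, t C/ha/yr
    lat: float = 0.0
    lon: float = 0.0
    footprint: tuple | None = None  # (row0, col0, n_rows, n_cols)

    def __post_init__(self):
        if self.area_ha <= 0:
            raise ValueError("region area must be positive")
        self.feasible_classes = tuple(self.feasible_classes)
        shares = {k: float(self.lu_shares.get(k, 0.0))
                  for k in LU_SHARE_CATEGORIES}
        if any(v < 0 or v > 1 for v in shares.values()):
            raise ValueError("land-use shares must lie in [0, 1]")
        if sum(shares.values()) > 1.0 + 1e-9:
            raise ValueError("land-use shares must sum to at most 1")
        self.lu_shares = shares

    def replace(self, **changes) -> "Region":
        return replace(self, **changes)
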