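"""Well-plate phantom geometry and CPR zone layout.

The phantom is a square plate carrying a regular grid of circular wells
filled with an ICG-albumin solution.  Twelve wells are grouped into three
diagonal *zones* used for the center-versus-periphery (CPR) assessment:

* zone 1 — the four innermost wells,
* zone 2 — the wells diagonally adjacent, outward from the zone-1 corners,
* zone 3 — the four plate-corner wells on the same diagonals.

All coordinates are millimetres relative to the plate center; the plate
normal is the +z axis and the camera looks down it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WellPlateGeometry"]


@dataclass(frozen=True)
class WellPlateGeometry:
    """Square well plate with a ``grid x grid`` layout of circular wells.

    Parameters
    ----------
    plate_side:
        Side length of the square plate, mm.
    grid:
        Number of wells per side (must be even and >= 6 so the three
        diagonal zones exist).
    well_diameter, well_depth:
        Well dimensions, mm.
    """

    plate_side: float = 150.0
    grid: int = 6
    well_diameter: float = 20.0
    well_depth: float = 5.0
    zone_map: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.grid < 6 or self.grid % 2:
            raise ValueError("grid must be even and >= 6 for the zone layout")
        if self.well_diameter > self.plate_side / self.grid:
            raise ValueError("wells overlap: diameter exceeds grid pitch")
        object.__setattr__(self, "zone_map", self._build_zone_map())
        # all well centers must lie inside the plate square
        half = self.plate_side / 2
        if np.any(np.abs(self.well_centers()) > half):
            raise ValueError("well centers fall outside the plate")

    # -- layout -----------------------------------------------------------

    @property
    def pitch(self) -> float:
        """Center-to-center well spacing, mm."""
        return self.plate_side / self.grid

    @property
    def half_diagonal(self) -> float:
        """Distance from plate center to a plate corner, mm."""
        return self.plate_side * math.sqrt(2) / 2

    def well_center(self, index: int) -> tuple[float, float]:
        """(x, y) of well ``index`` (row-major), mm from plate center."""
        row, col = divmod(index, self.grid)
        off = -self.plate_side / 2 + self.pitch / 2
        return (off + col * self.pitch, off + row * self.pitch)

    def well_centers(self) -> np.ndarray:
        """(grid^2, 2) array of well centers, mm from plate center."""
        return np.array([self.well_center(i) for i in range(self.grid**2)])

    def _build_zone_map(self) -> dict[int, int]:
        g, m = self.grid, self.grid // 2
        diag = {
            1: [(m - 1, m - 1), (m - 1, m), (m, m - 1), (m, m)],
            2: [(m - 2, m - 2), (m - 2, m + 1), (m + 1, m - 2), (m + 1, m + 1)],
            3: [(0, 0), (0, g - 1), (g - 1, 0), (g - 1, g - 1)],
        }
        return {r * g + c: z for z, cells in diag.items() for r, c in cells}

    # -- zone queries -----------------------------------------------------

    def zone_wells(self, zone: int) -> list[int]:
        """Indices of the four wells in ``zone`` (1, 2 or 3)."""
        wells = sorted(i for i, z in self.zone_map.items() if z == zone)
        if not wells:
            raise ValueError(f"unknown zone {zone}")
        return wells

    def well_radius_mm(self, index: int) -> float:
        """Radial distance of a well center from the plate center, mm."""
        x, y = self.well_center(index)
        return math.hypot(x, y)

    def radius_fraction(self, index: int) -> float:
        """Well radial position as a fraction of the plate half-diagonal.

        This is the screen-radius coordinate used by the vignette model
        under a perpendicular pinhole view centered on the plate.
        """
        return self.well_radius_mm(index) / self.half_diagonal

    def zone_radius_fraction(self, zone: int) -> float:
        """Common radius fraction of the four wells of a zone."""
        fracs = [self.radius_fraction(i) for i in self.zone_wells(zone)]
        return float(np.mean(fracs))
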