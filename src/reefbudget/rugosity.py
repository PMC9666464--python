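"""Site rugosity from a digital elevation model.

Rugosity — the ratio of true 3D surface area to planimetric area — is taken
over a 15 m x 15 m region of interest (ROI) centered on the site coordinate
of a projected-CRS elevation grid (1 m LiDAR topobathymetry in the intended
use).  Elevations are treated as point samples at cell centers; the surface
is triangulated over every 2x2 block of neighboring samples by splitting the
quad along the fixed NW-SE diagonal, and the planimetric reference area is
the same quad support (n_quads * cell_size**2), so quads dropped for NoData
leave the ratio unbiased and rugosity >= 1 always holds.

Grids are read and written as single-band ESRI ASCII rasters (a plain-text
format with a 6-line header); inputs must already be in a projected CRS in
meters — no geodesy is performed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DemGrid",
    "RugosityResult",
    "read_esri_ascii",
    "write_esri_ascii",
    "clip_roi",
    "surface_area_3d",
    "rugosity",
]


class DemError(ValueError):
    """Raised for invalid DEM inputs (empty ROI, all-NoData, bad grids)."""


@dataclass
class DemGrid:
    """Rectangular elevation grid in a projected CRS.

    ``elevations[0, 0]`` is the north-west sample; ``origin`` is the (x, y)
    of the lower-left corner of the grid footprint.  NoData is NaN.
    """

    elevations: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise DemError("elevation grid must be 2-D")
        if self.cell_size_m <= 0:
            raise DemError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    def x_range(self) -> tuple[float, float]:
        return self.origin[0], self.origin[0] + self.shape[1] * self.cell_size_m

    def y_range(self) -> tuple[float, float]:
        return self.origin[1], self.origin[1] + self.shape[0] * self.cell_size_m


@dataclass
class RugosityResult:
    area_3d_m2: float
    area_2d_m2: float
    rugosity: float
    n_valid_cells: int
    flags: set[str] = field(default_factory=set)


def read_esri_ascii(path: str | Path) -> DemGrid:
    """Read a single-band ESRI ASCII grid; honors the NODATA_value tag."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise DemError(f"ESRI ASCII grid missing {key} header")
    z = np.loadtxt(lines[body_start:], dtype=float)
    z = z.reshape(int(header["nrows"]), int(header["ncols"]))
    if "nodata_value" in header:
        z[z == header["nodata_value"]] = np.nan
    return DemGrid(
        elevations=z,
        cell_size_m=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_esri_ascii(dem: DemGrid, path: str | Path, nodata: float = -9999.0) -> None:
    nrows, ncols = dem.shape
    z = np.where(np.isnan(dem.elevations), nodata, dem.elevations)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {dem.origin[0]:.6f}\n")
        fh.write(f"yllcorner {dem.origin[1]:.6f}\n")
        fh.write(f"cellsize {dem.cell_size_m:.6f}\n")
        fh.write(f"NODATA_value {nodata:.1f}\n")
        for row in z:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def clip_roi(dem: DemGrid, center: tuple[float, float], side_m: float = 15.0) -> DemGrid:
    """Clip the axis-aligned square ROI of side ``side_m`` centered at ``center``.

    ROI edges snap *outward* to cell boundaries, so every cell with any
    overlap is included; an ROI edge falling exactly on a boundary includes
    no extra cell.  A center on a cell corner therefore yields side+1 cells
    per axis (e.g. 16x16 at 1 m cells), a center on a cell center yields
    side cells (15x15).  Raises if the ROI misses the DEM entirely.
    """
    cs = dem.cell_size_m
    x0, x1 = dem.x_range()
    y0, y1 = dem.y_range()
    lo_x, hi_x = center[0] - side_m / 2, center[0] + side_m / 2
    lo_y, hi_y = center[1] - side_m / 2, center[1] + side_m / 2
    if hi_x <= x0 or lo_x >= x1 or hi_y <= y0 or lo_y >= y1:
        raise DemError("ROI lies fully outside the DEM")
    j0 = max(0, math.floor((lo_x - x0) / cs))
    j1 = min(dem.shape[1], math.ceil((hi_x - x0) / cs))
    # row 0 is the northern edge (max y)
    i0 = max(0, math.floor((y1 - hi_y) / cs))
    i1 = min(dem.shape[0], math.ceil((y1 - lo_y) / cs))
    sub = dem.elevations[i0:i1, j0:j1].copy()
    return DemGrid(
        elevations=sub,
        cell_size_m=cs,
        origin=(x0 + j0 * cs, y1 - i1 * cs),
    )


def _quad_areas(z: np.ndarray, cs: float) -> np.ndarray:
    """Triangle-pair area for each 2x2 quad, NaN where any node is NoData.

    Quads split along the NW-SE diagonal: triangles (NW, NE, SE) and
    (NW, SE, SW).  A triangle over half a quad with corner rises dz1, dz2
    along the two legs has area cs/2 * sqrt(cs^2 + dz1^2 + dz2^2 ... ) —
    computed here from the exact cross product.
    """
    nw = z[:-1, :-1]
    ne = z[:-1, 1:]
    sw = z[1:, :-1]
    se = z[1:, 1:]

    def tri(za, zb, zc, ab, ac):
        # vertices a, b, c with in-plane offsets ab, ac (each an (dx, dy))
        ux, uy, uz = ab[0], ab[1], zb - za
        vx, vy, vz = ac[0], ac[1], zc - za
        cxv = uy * vz - uz * vy
        cyv = uz * vx - ux * vz
        czv = ux * vy - uy * vx
        return 0.5 * np.sqrt(cxv**2 + cyv**2 + czv**2)

    # NW at (0, 0), NE at (cs, 0), SW at (0, -cs), SE at (cs, -cs)
    t1 = tri(nw, ne, se, (cs, 0.0), (cs, -cs))
    t2 = tri(nw, se, sw, (cs, -cs), (0.0, -cs))
    return t1 + t2


def surface_area_3d(dem: DemGrid) -> float:
    """3D surface area (m^2) of the triangulated grid; NoData quads skipped."""
    return rugosity(dem).area_3d_m2


def rugosity(dem: DemGrid) -> RugosityResult:
    """Rugosity = 3D surface area / planimetric area over the valid quads.

    A flat grid gives exactly 1; the result carries a ``high_nodata`` flag
    when more than half the cells are NoData.
    """
    z = dem.elevations
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise DemError("need at least a 2x2 grid to triangulate")
    valid = np.isfinite(z)
    if not valid.any():
        raise DemError("all cells are NoData")
    areas = _quad_areas(z, dem.cell_size_m)
    ok = np.isfinite(areas)
    n_quads = int(ok.sum())
    if n_quads == 0:
        raise DemError("no fully valid 2x2 quad in the grid")
    a3 = float(areas[ok].sum())
    a2 = n_quads * dem.cell_size_m**2
    flags: set[str] = set()
    if valid.mean() < 0.5:
        flags.add("high_nodata")
        warnings.warn("more than 50% NoData in ROI", stacklevel=2)
    r = a3 / a2
    if r < 1.0 - 1e-9:
        raise DemError(f"computed rugosity {r} below 1")
    return RugosityResult(
        area_3d_m2=a3,
        area_2d_m2=a2,
        rugosity=r,
        n_valid_cells=int(valid.sum()),
        flags=flags,
    )


def site_rugosity(dem: DemGrid, center: tuple[float, float],
                  side_m: float = 15.0) -> RugosityResult:
    """Convenience: clip the ROI then compute rugosity."""
    return rugosity(clip_roi(dem, center, side_m))
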