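"""Square-grid standardization of sampling units.

Clustered, unevenly sampled survey sites are grouped into square cells of a
metric grid (default 75 km) so that every cell — not every site — carries
the same weight in the trend model.  Cell centroid latitudes feed the
latitude term of the hierarchical model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection import get_projection
from .survey_io import SurveyTable


class AssignmentError(ValueError):
    """A site falls outside the grid."""


@dataclass(frozen=True)
class GridSpec:
    """A square grid in a projected plane.

    ``x0``/``y0`` anchor the lower-left corner of cell (0, 0); membership is
    half-open on both axes, so a site with ``x0 + k*s <= x < x0 + (k+1)*s``
    lies in column ``k``.
    """

    x0: float
    y0: float
    cell_size: float = 75_000.0
    crs: str = "laea-europe"

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def cell_index(self, x, y):
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def cell_centroid(self, row, col):
        cx = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        cy = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return cx, cy


@dataclass
class CellAssignment:
    """Partition of sites into occupied grid cells.

    Attributes
    ----------
    site_cells:
        DataFrame (site_id, cell_id).
    cells:
        DataFrame (cell_id, row, col, cx, cy, lat, n_sites) — centroid
        coordinates in meters, centroid latitude ``lat`` (the L_q of the
        hierarchical model) in WGS84 degrees.
    """

    site_cells: pd.DataFrame
    cells: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_of_site(self) -> pd.Series:
        return self.site_cells.set_index("site_id")["cell_id"]


def build_grid(table: SurveyTable, cell_size: float = 75_000.0,
               origin: tuple[float, float] | None = None) -> GridSpec:
    """Anchor a grid over the bounding box of the (projected) sites.

    By default the origin is the bounding-box minimum floored to a multiple
    of ``cell_size``, which makes the anchoring deterministic; pass
    ``origin`` to match an externally defined grid exactly.
    """
    if "x" not in table.sites.columns:
        raise ValueError("sites must be projected before gridding (run project_coordinates)")
    if table.n_sites == 0:
        raise ValueError("cannot build a grid with no sites")
    if origin is not None:
        x0, y0 = origin
    else:
        x0 = np.floor(table.sites["x"].min() / cell_size) * cell_size
        y0 = np.floor(table.sites["y"].min() / cell_size) * cell_size
    return GridSpec(x0=float(x0), y0=float(y0), cell_size=float(cell_size),
                    crs=table.crs or "laea-europe")


def assign_sites(table: SurveyTable, grid: GridSpec) -> CellAssignment:
    """Assign every site to its grid cell; only occupied cells are listed."""
    sites = table.sites
    row, col = grid.cell_index(sites["x"].to_numpy(), sites["y"].to_numpy())
    if (row < 0).any() or (col < 0).any():
        bad = sites.loc[(row < 0) | (col < 0), "site_id"].tolist()
        raise AssignmentError(f"sites outside the grid extent: {bad[:10]}")
    cell_id = [f"r{r}c{c}" for r, c in zip(row, col)]
    site_cells = pd.DataFrame({"site_id": sites["site_id"], "cell_id": cell_id})
    occ = (
        pd.DataFrame({"cell_id": cell_id, "row": row, "col": col})
        .groupby(["cell_id", "row", "col"], as_index=False)
        .size()
        .rename(columns={"size": "n_sites"})
    )
    cx, cy = grid.cell_centroid(occ["row"].to_numpy(), occ["col"].to_numpy())
    proj = get_projection(grid.crs)
    _, lat = proj.inverse(cx, cy)
    cells = occ.assign(cx=cx, cy=cy, lat=lat).sort_values(["row", "col"]).reset_index(drop=True)
    return CellAssignment(site_cells=site_cells.reset_index(drop=True), cells=cells)


def cell_latitudes(assignment: CellAssignment) -> pd.Series:
    """Centroid latitude L_q (degrees) per occupied cell."""
    if assignment.n_cells == 0:
        raise ValueError("empty assignment")
    return assignment.cells.set_index("cell_id")["lat"]


def assignment_to_csv(assignment: CellAssignment, path) -> None:
    lat = assignment.cells.set_index("cell_id")["lat"]
    out = assignment.site_cells.copy()
    out["L_q"] = out["cell_id"].map(lat)
    out.to_csv(path, index=False)


def grid_to_geojson(assignment: CellAssignment, grid: GridSpec, path) -> None:
    """Export occupied cell polygons (WGS84) as GeoJSON."""
    proj = get_projection(grid.crs)
    s = grid.cell_size
    features = []
    for rec in assignment.cells.itertuples(index=False):
        xlo = grid.x0 + rec.col * s
        ylo = grid.y0 + rec.row * s
        corners_x = np.array([xlo, xlo + s, xlo + s, xlo, xlo])
        corners_y = np.array([ylo, ylo, ylo + s, ylo + s, ylo])
        lon, lat = proj.inverse(corners_x, corners_y)
        features.append({
            "type": "Feature",
            "properties": {"cell_id": rec.cell_id, "n_sites": int(rec.n_sites),
                           "centroid_lat": float(rec.lat)},
            "geometry": {"type": "Polygon",
                         "coordinates": [[[float(a), float(b)] for a, b in zip(lon, lat)]]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
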