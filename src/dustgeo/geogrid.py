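"""Equal-area gridding of occurrence records and the point-to-grid surface.

Occurrence points are projected with a Lambert azimuthal equal-area (LAEA)
projection on the authalic sphere and binned into square cells (250 km by
default).  Each OTU's pooled occurrence records give a binarized distribution
— a cell is *positive* when it holds at least two records — and the
distributions of all mapped OTUs in a sample are overlaid into a
:class:`GridSurface`: per cell, the fraction of mapped OTUs positive there.
Binarizing per OTU before overlaying normalizes away record-density bias and
damps the influence of wide-ranging (cosmopolitan) OTUs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoMappedOtusError, OffGridError
from .occurrences import OccurrenceStore, species_query_seed

#: authalic-sphere radius (km) used for the equal-area projection
EARTH_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class GridSpec:
    """Square equal-area grid on an LAEA plane.

    The default is a 6000 km x 4000 km box of 250-km cells centred on the
    conterminous United States (projection centre 98°W, 39.5°N), i.e. a
    24 x 16 grid.  Rows index south-to-north, columns west-to-east.
    """

    cell_km: float = 250.0
    center: tuple[float, float] = (-98.0, 39.5)  # (lon0, lat0)
    width_km: float = 6000.0
    height_km: float = 4000.0

    def __post_init__(self) -> None:
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        for side in (self.width_km, self.height_km):
            n = side / self.cell_km
            if abs(n - round(n)) > 1e-9 or n < 1:
                raise ValueError("extent sides must be positive integer multiples of cell_km")

    @property
    def ncols(self) -> int:
        return int(round(self.width_km / self.cell_km))

    @property
    def nrows(self) -> int:
        return int(round(self.height_km / self.cell_km))

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def x0(self) -> float:
        return -self.width_km / 2.0

    @property
    def y0(self) -> float:
        return -self.height_km / 2.0


def project(lon, lat, spec: GridSpec):
    """LAEA forward projection, degrees -> planar km (vectorized)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = np.radians(spec.center[0]), np.radians(spec.center[1])
    dlam = lam - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    if np.any(denom < 1e-12):
        raise ValueError("point is antipodal to the projection centre")
    k = np.sqrt(2.0 / denom) * EARTH_RADIUS_KM
    x = k * np.cos(phi) * np.sin(dlam)
    y = k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam))
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def unproject(x, y, spec: GridSpec):
    """LAEA inverse projection, planar km -> degrees (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lam0, phi0 = np.radians(spec.center[0]), np.radians(spec.center[1])
    rho = np.hypot(x, y)
    rho_safe = np.where(rho == 0.0, 1.0, rho)
    c = 2.0 * np.arcsin(np.clip(rho / (2.0 * EARTH_RADIUS_KM), -1.0, 1.0))
    phi = np.arcsin(np.cos(c) * np.sin(phi0) + y * np.sin(c) * np.cos(phi0) / rho_safe)
    lam = lam0 + np.arctan2(
        x * np.sin(c), rho_safe * np.cos(c) * np.cos(phi0) - y * np.sin(c) * np.sin(phi0)
    )
    lon = np.degrees(np.where(rho == 0.0, lam0, lam))
    lat = np.degrees(np.where(rho == 0.0, phi0, phi))
    lon = (lon + 180.0) % 360.0 - 180.0
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def cell_of(x_km: float, y_km: float, spec: GridSpec) -> tuple[int, int] | None:
    """Half-open binning of a planar point; None when off-grid.

    Cell (r, c) covers [x0 + c*cell, x0 + (c+1)*cell) x [y0 + r*cell,
    y0 + (r+1)*cell), so a point on an interior edge belongs to the
    higher-index cell.
    """
    c = math.floor((x_km - spec.x0) / spec.cell_km)
    r = math.floor((y_km - spec.y0) / spec.cell_km)
    if 0 <= r < spec.nrows and 0 <= c < spec.ncols:
        return (r, c)
    return None


def cell_centroid(r: int, c: int, spec: GridSpec) -> tuple[float, float]:
    """Planar (x, y) centre of a cell, km."""
    return (
        spec.x0 + (c + 0.5) * spec.cell_km,
        spec.y0 + (r + 0.5) * spec.cell_km,
    )


def cell_centroid_lonlat(r: int, c: int, spec: GridSpec) -> tuple[float, float]:
    x, y = cell_centroid(r, c, spec)
    return unproject(x, y, spec)


def bin_points(lons: np.ndarray, lats: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Count points per cell; off-grid points are excluded. Returns (nrows, ncols)."""
    counts = np.zeros((spec.nrows, spec.ncols), dtype=np.int64)
    if len(np.atleast_1d(lons)) == 0:
        return counts
    x, y = project(np.atleast_1d(lons), np.atleast_1d(lats), spec)
    cc = np.floor((np.atleast_1d(x) - spec.x0) / spec.cell_km).astype(np.int64)
    rr = np.floor((np.atleast_1d(y) - spec.y0) / spec.cell_km).astype(np.int64)
    inside = (rr >= 0) & (rr < spec.nrows) & (cc >= 0) & (cc < spec.ncols)
    np.add.at(counts, (rr[inside], cc[inside]), 1)
    return counts


@dataclass
class OtuDistribution:
    """Binarized gridded range of one OTU (cells with >= 2 pooled records)."""

    otu_id: str
    positive_cells: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __bool__(self) -> bool:
        return bool(self.positive_cells)


@dataclass
class GridSurface:
    """Per-cell fraction of a sample's mapped OTUs positive in that cell."""

    spec: GridSpec
    values: dict[tuple[int, int], float]
    n_otus: int

    def to_array(self) -> np.ndarray:
        """Dense (nrows, ncols) array; cells absent from ``values`` are 0."""
        arr = np.zeros((self.spec.nrows, self.spec.ncols))
        for (r, c), v in self.values.items():
            arr[r, c] = v
        return arr

    def counts(self) -> dict[tuple[int, int], int]:
        """Integer OTU counts per cell (fraction x n_otus)."""
        return {cell: int(round(v * self.n_otus)) for cell, v in self.values.items()}


def otu_distribution(
    otu_id: str,
    species: set[str],
    store: OccurrenceStore,
    spec: GridSpec,
    seed: int = 0,
    min_cell_occurrences: int = 2,
) -> OtuDistribution:
    """Merge the occurrence records of an OTU's species and binarize.

    Records of all assigned species are pooled before thresholding, so two
    species each contributing one record to a cell make it positive.  An OTU
    with no cell reaching the threshold yields an empty distribution and does
    not count as mapped.
    """
    counts = np.zeros((spec.nrows, spec.ncols), dtype=np.int64)
    for name in sorted(species):
        coords = store.query_coords(name, tsn=store.tsn_of(name), seed=species_query_seed(seed, name))
        if len(coords):
            counts += bin_points(coords[:, 0], coords[:, 1], spec)
    rr, cc = np.nonzero(counts >= min_cell_occurrences)
    return OtuDistribution(otu_id, frozenset(zip(rr.tolist(), cc.tolist())))


def overlay(distributions: list[OtuDistribution], spec: GridSpec) -> GridSurface:
    """Overlay the binarized distributions of a sample's mapped OTUs.

    value(cell) = (# mapped OTUs positive in cell) / (# mapped OTUs); OTUs
    with empty distributions are excluded from both numerator and denominator.
    """
    mapped = [d for d in distributions if d.positive_cells]
    if not mapped:
        raise NoMappedOtusError("no mapped OTUs: every distribution is empty")
    counts = np.zeros((spec.nrows, spec.ncols), dtype=np.int64)
    for d in mapped:
        for r, c in d.positive_cells:
            counts[r, c] += 1
    n = len(mapped)
    rr, cc = np.nonzero(counts)
    values = {(int(r), int(c)): counts[r, c] / n for r, c in zip(rr, cc)}
    return GridSurface(spec=spec, values=values, n_otus=n)


def surface_to_dataframe(surface: GridSurface) -> pd.DataFrame:
    """Flat table of nonzero cells: row, col, centroid lon/lat, fraction, count."""
    rows = []
    for (r, c), v in sorted(surface.values.items()):
        lon, lat = cell_centroid_lonlat(r, c, surface.spec)
        rows.append(
            {
                "row": r,
                "col": c,
                "centroid_lon": round(lon, 6),
                "centroid_lat": round(lat, 6),
                "fraction": v,
                "count": int(round(v * surface.n_otus)),
            }
        )
    return pd.DataFrame(rows, columns=["row", "col", "centroid_lon", "centroid_lat", "fraction", "count"])


def surface_to_geojson(surface: GridSurface) -> dict:
    """GeoJSON FeatureCollection of nonzero cells (polygon corners unprojected)."""
    spec = surface.spec
    features = []
    for (r, c), v in sorted(surface.values.items()):
        xs = [spec.x0 + c * spec.cell_km, spec.x0 + (c + 1) * spec.cell_km]
        ys = [spec.y0 + r * spec.cell_km, spec.y0 + (r + 1) * spec.cell_km]
        corners = [(xs[0], ys[0]), (xs[1], ys[0]), (xs[1], ys[1]), (xs[0], ys[1]), (xs[0], ys[0])]
        ring = [list(unproject(x, y, spec)) for x, y in corners]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "row": r,
                    "col": c,
                    "fraction": v,
                    "count": int(round(v * surface.n_otus)),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_surface_geojson(surface: GridSurface, path) -> None:
    with open(path, "w") as fh:
        json.dump(surface_to_geojson(surface), fh)
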