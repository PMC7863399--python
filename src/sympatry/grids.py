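"""Raster grid geometry and the landscape covariate stack.

All rasters in a study share a single square-cell grid (30 m cells by
default, matching the resolution of categorical land-cover products).
Arrays are stored row-major with row 0 at the *northern* edge, the
convention of the ESRI ASCII grid format used for on-disk exchange.
Coordinates are assumed already projected to a metric CRS; no geodesy is
performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The seven land-cover classes used throughout; "deciduous" is the
#: reference class in every regression design.
LAND_COVER_CLASSES = (
    "deciduous",
    "mixed",
    "evergreen",
    "woody_wetland",
    "open_water",
    "grassland_shrub",
    "developed",
)

#: Continuous covariate layers a full stack may carry.
CONTINUOUS_LAYERS = (
    "patch_size",
    "dist_road",
    "dist_water",
    "dist_edge",
    "hare_density",
    "grouse_density",
    "deer_adult_occ",
    "deer_fawn_occ",
    "wolf_occ",
)


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular square-cell grid.

    ``x_min``/``y_min`` are the coordinates of the grid's lower-left
    corner (not the first cell center); ``cell`` is the cell side in
    meters.
    """

    x_min: float
    y_min: float
    cell: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell <= 0 or self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive cell size and dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x_max(self) -> float:
        return self.x_min + self.cell * self.n_cols

    @property
    def y_max(self) -> float:
        return self.y_min + self.cell * self.n_rows

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (n_rows, n_cols)."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        """Cell-center y coordinates by row (row 0 = north)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell


@dataclass
class LandscapeStack:
    """Named covariate rasters sharing one :class:`GridGeometry`.

    ``land_cover`` is an integer-coded categorical layer indexing into
    :data:`LAND_COVER_CLASSES`; all other layers are float arrays.
    """

    geometry: GridGeometry
    land_cover: np.ndarray | None = None
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        if self.land_cover is not None:
            lc = np.asarray(self.land_cover)
            if lc.shape != shape:
                raise ValueError("land_cover shape does not match grid geometry")
            if lc.min() < 0 or lc.max() >= len(LAND_COVER_CLASSES):
                raise ValueError("land_cover codes outside the seven-class range")
            self.land_cover = lc.astype(np.int16)
        for name, arr in self.layers.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != shape:
                raise ValueError(f"layer {name!r} shape does not match grid geometry")
            self.layers[name] = a

    def __contains__(self, name: str) -> bool:
        return name in self.layers or (name == "land_cover" and self.land_cover is not None)

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "land_cover":
            if self.land_cover is None:
                raise KeyError("land_cover")
            return self.land_cover
        return self.layers[name]

    def continuous_names(self) -> list[str]:
        return list(self.layers)

    def with_layer(self, name: str, values: np.ndarray) -> "LandscapeStack":
        """Return a copy of the stack with ``name`` added or replaced."""
        layers = dict(self.layers)
        layers[name] = np.asarray(values, dtype=float)
        return LandscapeStack(self.geometry, self.land_cover, layers)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path: str | Path, geometry: GridGeometry, values: np.ndarray,
                     nodata: float = -9999.0) -> None:
    """Write one raster layer as an ESRI ASCII grid (plain text)."""
    values = np.asarray(values)
    if values.shape != geometry.shape:
        raise ValueError("values shape does not match geometry")
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {geometry.x_min!r}\n"
        f"yllcorner {geometry.y_min!r}\n"
        f"cellsize {geometry.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = values.astype(float)
    body = np.where(np.isfinite(body), body, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[GridGeometry, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    geom = GridGeometry(
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        cell=header["cellsize"],
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
    )
    values = np.atleast_2d(values)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return geom, values


def write_stack(directory: str | Path, stack: LandscapeStack) -> None:
    """Write every layer of a stack as ``<directory>/<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stack.land_cover is not None:
        write_ascii_grid(directory / "land_cover.asc", stack.geometry,
                         stack.land_cover.astype(float))
    for name, arr in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", stack.geometry, arr)


def read_stack(directory: str | Path) -> LandscapeStack:
    """Read every ``.asc`` layer in a directory into one stack."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.asc"))
    if not paths:
        raise FileNotFoundError(f"no .asc rasters in {directory}")
    geom: GridGeometry | None = None
    land_cover = None
    layers: dict[str, np.ndarray] = {}
    for p in paths:
        g, vals = read_ascii_grid(p)
        if geom is None:
            geom = g
        elif g != geom:
            raise ValueError(f"layer {p.name} geometry differs from the stack")
        if p.stem == "land_cover":
            land_cover = vals.astype(np.int16)
        else:
            layers[p.stem] = vals
    assert geom is not None
    return LandscapeStack(geom, land_cover, layers)
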