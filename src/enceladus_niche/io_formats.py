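"""Readers and writers for the formats the pipeline touches.

Occurrence tables are plain CSV (comma-separated, UTF-8, header row
required).  Environmental rasters are single-band grids in either GeoTIFF
or ESRI ASCII grid form; all layers of a stack must be co-registered (same
shape, transform and nodata mask) — mismatches are an error, never silently
aligned.  Every other module consumes only the in-memory types defined
here.

Grid convention: row 0 is the northernmost row, values are cell averages,
points are sampled by the cell that contains them (cell-centre convention),
coordinates are WGS84 decimal degrees.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

__all__ = [
    "GridTransform",
    "OccurrenceTable",
    "EnvStack",
    "read_occurrences",
    "write_occurrences",
    "read_env_stack",
    "write_env_stack",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "write_suitability_raster",
]


@dataclass(frozen=True)
class GridTransform:
    """Affine north-up grid geometry.

    ``x_origin``/``y_origin`` are the coordinates of the *outer corner* of
    the top-left cell (west edge, north edge); ``cell_size`` is the square
    cell edge in decimal degrees.
    """

    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell size must be > 0, got {self.cell_size}")

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell ``(row, col)``."""
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point (no bounds check)."""
        col = int(math.floor((lon - self.x_origin) / self.cell_size))
        row = int(math.floor((self.y_origin - lat) / self.cell_size))
        return row, col

    def almost_equal(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class OccurrenceTable:
    """Point records (longitude, latitude) for one taxon.

    The reader keeps duplicates — deduplication is a modelling decision
    that happens in :func:`enceladus_niche.niche_envelope.clean_and_split`.
    """

    taxon: str
    records: list[tuple[float, float]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)


@dataclass
class EnvStack:
    """A set of co-registered environmental raster layers.

    ``layers`` maps variable name -> 2-D float array (nodata cells hold
    ``nodata``); ``units`` maps variable name -> unit string.  All layers
    share ``transform``, shape and nodata mask.
    """

    layers: dict[str, np.ndarray]
    transform: GridTransform
    nodata: float = DEFAULT_NODATA
    units: dict[str, str] = field(default_factory=dict)
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers disagree on grid shape: {shapes}")
        names = list(self.layers)
        if len(names) >= 2:
            ref = self.mask_for(names[0])
            for name in names[1:]:
                if not np.array_equal(ref, self.mask_for(name)):
                    raise ValueError(
                        f"nodata masks differ between layers "
                        f"{names[0]!r} and {name!r}"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def mask_for(self, name: str) -> np.ndarray:
        """Boolean mask, True where the layer is valid (not nodata)."""
        arr = self.layers[name]
        return ~np.isclose(arr, self.nodata) & ~np.isnan(arr)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.mask_for(self.names[0])

    def extract(self, lons: np.ndarray, lats: np.ndarray) -> "pd.DataFrame":
        """Sample every layer at the cells containing the given points.

        Returns a DataFrame with one column per layer; cells outside the
        grid or on nodata come back as NaN.
        """
        import pandas as pd

        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        nrow, ncol = self.shape
        cols = np.floor((lons - self.transform.x_origin) / self.transform.cell_size)
        rows = np.floor((self.transform.y_origin - lats) / self.transform.cell_size)
        inside = (rows >= 0) & (rows < nrow) & (cols >= 0) & (cols < ncol)
        out = {}
        r = rows[inside].astype(int)
        c = cols[inside].astype(int)
        for name, arr in self.layers.items():
            vals = np.full(lons.shape, np.nan)
            sampled = arr[r, c]
            sampled = np.where(np.isclose(sampled, self.nodata), np.nan, sampled)
            vals[inside] = sampled
            out[name] = vals
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# occurrence CSV


def read_occurrences(
    path: str | Path,
    lon_col: str = "longitude",
    lat_col: str = "latitude",
    taxon_col: str | None = "taxon",
) -> OccurrenceTable:
    """Read an occurrence CSV into an :class:`OccurrenceTable`.

    Rows with unparseable or out-of-range coordinates (|lon| > 180,
    |lat| > 90) are skipped with a logged warning; duplicates are kept.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If a named column is missing, or no row yields a valid record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"occurrence file not found: {path}")
    records: list[tuple[float, float]] = []
    taxon = ""
    skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for needed in (lon_col, lat_col):
            if needed not in header:
                raise ValueError(
                    f"column {needed!r} not in {path.name}; available: {header}"
                )
        for row in reader:
            try:
                lon = float(row[lon_col])
                lat = float(row[lat_col])
            except (TypeError, ValueError):
                skipped += 1
                continue
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                skipped += 1
                logger.warning(
                    "skipping out-of-range coordinate (%s, %s) in %s",
                    row[lon_col], row[lat_col], path.name,
                )
                continue
            records.append((lon, lat))
            if taxon_col and not taxon:
                taxon = (row.get(taxon_col) or "").strip()
    if skipped:
        logger.warning("%d malformed row(s) skipped in %s", skipped, path.name)
    if not records:
        raise ValueError(f"zero valid rows in {path}")
    return OccurrenceTable(taxon=taxon or path.stem, records=records, source=str(path))


def write_occurrences(table: OccurrenceTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "longitude", "latitude"])
        for lon, lat in table.records:
            writer.writerow([table.taxon, repr(lon), repr(lat)])


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform, float]:
    """Read a single-band ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for needed in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if needed not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {needed!r}")
    arr = np.array([v for row in rows for v in row], dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.size != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} values, found {arr.size}"
        )
    arr = arr.reshape(nrows, ncols)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
        cell_size=header["cellsize"],
    )
    return arr, transform, nodata


def write_ascii_grid(
    arr: np.ndarray, transform: GridTransform, nodata: float, path: str | Path
) -> None:
    nrows, ncols = arr.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {transform.x_origin!r}\n")
        fh.write(
            f"yllcorner {transform.y_origin - nrows * transform.cell_size!r}\n"
        )
        fh.write(f"cellsize {transform.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in arr:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GeoTIFF via tifffile
#
# Geometry is carried by the standard GeoTIFF tags ModelPixelScaleTag
# (33550) and ModelTiepointTag (33922); nodata by the GDAL_NODATA ASCII
# tag (42113).  Single band, float32.

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(
    arr: np.ndarray, transform: GridTransform, nodata: float, path: str | Path
) -> None:
    import tifffile

    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3,
         (transform.cell_size, transform.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, transform.x_origin, transform.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, arr.astype(np.float32), extratags=extratags)


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridTransform, float]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: not a GeoTIFF (geo tags absent)")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    transform = GridTransform(
        x_origin=float(tie[3]), y_origin=float(tie[4]), cell_size=float(scale[0])
    )
    return arr, transform, nodata


def _read_raster(path: Path) -> tuple[np.ndarray, GridTransform, float]:
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        return read_ascii_grid(path)
    return read_geotiff(path)


def read_env_stack(
    paths: Sequence[str | Path],
    names: Sequence[str] | None = None,
    units: Mapping[str, str] | None = None,
) -> EnvStack:
    """Load co-registered single-band rasters into an :class:`EnvStack`.

    Grids must already agree on shape, transform and nodata mask; any
    mismatch is fatal and names the offending pair.
    """
    paths = [Path(p) for p in paths]
    if names is None:
        names = [p.stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("names and paths must have equal length")
    layers: dict[str, np.ndarray] = {}
    transform: GridTransform | None = None
    nodata: float | None = None
    first_name = None
    for name, path in zip(names, paths):
        arr, tf, nd = _read_raster(path)
        if transform is None:
            transform, nodata, first_name = tf, nd, name
        else:
            if arr.shape != next(iter(layers.values())).shape:
                raise ValueError(
                    f"grid shape mismatch between layers {first_name!r} "
                    f"{next(iter(layers.values())).shape} and {name!r} {arr.shape}"
                )
            if not transform.almost_equal(tf):
                raise ValueError(
                    f"transform mismatch between layers {first_name!r} and {name!r}"
                )
            if nd != nodata:
                arr = np.where(np.isclose(arr, nd), nodata, arr)
        layers[name] = arr
    assert transform is not None and nodata is not None
    return EnvStack(
        layers=layers,
        transform=transform,
        nodata=nodata,
        units=dict(units or {}),
    )


def write_env_stack(stack: EnvStack, outdir: str | Path, fmt: str = "asc") -> list[Path]:
    """Write each layer of a stack as ``<outdir>/<name>.<fmt>``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in stack.layers.items():
        path = outdir / f"{name}.{fmt}"
        if fmt == "asc":
            write_ascii_grid(arr, stack.transform, stack.nodata, path)
        elif fmt in {"tif", "tiff"}:
            write_geotiff(arr, stack.transform, stack.nodata, path)
        else:
            raise ValueError(f"unknown raster format {fmt!r}")
        written.append(path)
    return written


def write_suitability_raster(
    grid: np.ndarray, template: EnvStack, path: str | Path
) -> None:
    """Write a suitability grid with the template's geometry and nodata.

    Valid values must lie in [0, 1]; nodata cells of the template become
    nodata in the output.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != template.shape:
        raise ValueError(
            f"grid shape {grid.shape} does not match template {template.shape}"
        )
    out = np.where(template.valid_mask, grid, template.nodata)
    valid = out[template.valid_mask]
    if valid.size and (valid.min() < -1e-9 or valid.max() > 1 + 1e-9):
        raise ValueError("suitability values must lie in [0, 1]")
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt", ".grd"}:
        write_ascii_grid(out, template.transform, template.nodata, path)
    else:
        write_geotiff(out, template.transform, template.nodata, path)
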