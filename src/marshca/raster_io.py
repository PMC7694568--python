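"""Categorical landscape rasters and their class scheme.

A landscape map is a 2-D lattice of small integer class codes with a fixed
square cell size, a calendar year, and a *baseline edge*: the raster edge
that represents the seawall from which all zonation distances are measured,
increasing seaward.  Two on-disk formats are supported: single-band integer
GeoTIFF (via :mod:`tifffile`) and the plain-text ESRI ASCII grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

EDGES = ("north", "south", "west", "east")

__all__ = [
    "ClassScheme",
    "LandscapeGrid",
    "read_grid",
    "write_grid",
    "class_areas",
    "load_scheme",
]


@dataclass(frozen=True)
class ClassScheme:
    """Ordered class codebook: (code, name, dynamic) plus a nodata code.

    Dynamic classes take part in Markov transitions and CA allocation;
    static classes (water, roads, aquaculture ponds) are frozen in place.
    """

    classes: tuple[tuple[int, str, bool], ...]
    nodata_code: int = -1

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate class codes: {sorted(codes)}")
        if any(c < 0 for c in codes):
            raise ValueError("class codes must be non-negative")
        if self.nodata_code in codes:
            raise ValueError(f"nodata_code {self.nodata_code} collides with a class code")
        if not any(dyn for _, _, dyn in self.classes):
            raise ValueError("scheme needs at least one dynamic class")

    @property
    def codes(self) -> list[int]:
        return [c for c, _, _ in self.classes]

    @property
    def dynamic_codes(self) -> list[int]:
        return [c for c, _, dyn in self.classes if dyn]

    @property
    def static_codes(self) -> list[int]:
        return [c for c, _, dyn in self.classes if not dyn]

    @property
    def names(self) -> dict[int, str]:
        return {c: n for c, n, _ in self.classes}

    def name_of(self, code: int) -> str:
        return self.names.get(code, f"class_{code}")


@dataclass
class LandscapeGrid:
    """A dated categorical raster referenced to a seawall baseline edge.

    ``values`` holds integer class codes (row 0 is the top of the raster);
    ``baseline_edge`` names the raster edge standing in for the seawall.
    A cell of size 30 m covers exactly 0.09 ha.
    """

    values: np.ndarray
    cell_size: float
    date: int
    scheme: ClassScheme
    baseline_edge: str = "west"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError(f"grid values must be integers, got {self.values.dtype}")
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(f"grid must be a non-empty 2-D lattice, got shape {self.values.shape}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.baseline_edge not in EDGES:
            raise ValueError(f"baseline_edge must be one of {EDGES}, got {self.baseline_edge!r}")
        allowed = set(self.scheme.codes) | {self.scheme.nodata_code}
        bad = sorted(set(np.unique(self.values).tolist()) - allowed)
        if bad:
            raise ValueError(f"grid contains codes not in scheme: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    def valid_mask(self) -> np.ndarray:
        return self.values != self.scheme.nodata_code

    def oriented(self) -> np.ndarray:
        """Values rotated/flipped so the baseline lies along row 0.

        In the canonical frame a cell's seaward distance is
        ``(row + 0.5) * cell_size`` and baseline-perpendicular transects
        run down the columns.
        """
        v = self.values
        if self.baseline_edge == "north":
            return v
        if self.baseline_edge == "south":
            return v[::-1, :]
        if self.baseline_edge == "west":
            return v.T
        return v.T[::-1, :]  # east

    def with_values(self, values: np.ndarray, date: int | None = None) -> "LandscapeGrid":
        return LandscapeGrid(
            values=values,
            cell_size=self.cell_size,
            date=self.date if date is None else date,
            scheme=self.scheme,
            baseline_edge=self.baseline_edge,
        )


def check_compatible(a: LandscapeGrid, b: LandscapeGrid) -> None:
    """Grids entering any pairwise operation must share frame and cell size."""
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if a.cell_size != b.cell_size:
        raise ValueError(f"cell size mismatch: {a.cell_size} vs {b.cell_size}")


# ---------------------------------------------------------------------------
# on-disk formats


def _write_ascii(values: np.ndarray, path: Path, cell_size: float, nodata: int) -> None:
    rows, cols = values.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner 0.0\n"
        f"yllcorner 0.0\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%d")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, int | None]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: ASCII grid holds non-integer values")
    values = data.astype(np.int64)
    rows = int(header.get("nrows", values.shape[0]))
    cols = int(header.get("ncols", values.shape[1]))
    if values.shape != (rows, cols):
        raise ValueError(f"{path}: header says {rows}x{cols}, body is {values.shape}")
    nodata = int(header["nodata_value"]) if "nodata_value" in header else None
    return values, float(header.get("cellsize", 1.0)), nodata


def _write_tiff(values: np.ndarray, path: Path, cell_size: float) -> None:
    import tifffile

    # cell size is recoverable from the resolution tag (cells per metre)
    tifffile.imwrite(
        path,
        values.astype(np.int32),
        resolution=(1.0 / cell_size, 1.0 / cell_size),
        resolutionunit="NONE",
        metadata={"cell_size_m": cell_size},
    )


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        cell = None
        meta = tif.shaped_metadata
        if meta and "cell_size_m" in meta[0]:
            cell = float(meta[0]["cell_size_m"])
        else:
            try:
                xres = page.tags["XResolution"].value
                cell = xres[1] / xres[0]
            except (KeyError, ZeroDivisionError, TypeError):
                pass
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: TIFF band is not integer-valued")
        data = np.round(data)
    return data.astype(np.int64), cell


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return "geotiff"
    return "ascii"


def read_grid(
    path: str | Path,
    scheme: ClassScheme,
    date: int,
    baseline_edge: str = "west",
    cell_size: float | None = None,
) -> LandscapeGrid:
    """Read a categorical raster and validate it against *scheme*.

    Format is inferred from the suffix (``.tif``/``.tiff`` → GeoTIFF,
    anything else → ESRI ASCII grid).  Unknown codes raise with the
    offending codes listed.  ``cell_size`` overrides whatever the file
    records (ASCII grids record it in the header; TIFFs in the
    resolution tag).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _detect_format(path) == "geotiff":
        values, file_cell = _read_tiff(path)
    else:
        values, file_cell, _ = _read_ascii(path)
    cs = cell_size if cell_size is not None else (file_cell or 1.0)
    return LandscapeGrid(values=values, cell_size=cs, date=date,
                         scheme=scheme, baseline_edge=baseline_edge)


def write_grid(grid: LandscapeGrid, path: str | Path, format: str | None = None) -> None:
    """Write *grid* as GeoTIFF or ASCII; ``read_grid`` round-trips it exactly."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt not in {"geotiff", "ascii"}:
        raise ValueError(f"unknown format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "geotiff":
        _write_tiff(grid.values, path, grid.cell_size)
    else:
        _write_ascii(grid.values, path, grid.cell_size, grid.scheme.nodata_code)


def class_areas(grid: LandscapeGrid, include_zero: bool = True) -> dict[int, float]:
    """Hectares per class code: cell count x cell area, nodata excluded."""
    out: dict[int, float] = {}
    codes, counts = np.unique(grid.values[grid.valid_mask()], return_counts=True)
    tally = dict(zip(codes.tolist(), counts.tolist()))
    for code in grid.scheme.codes:
        n = tally.get(code, 0)
        if n or include_zero:
            out[code] = n * grid.cell_area_ha
    return out


def load_scheme(path: str | Path) -> ClassScheme:
    """Load a class scheme from YAML or JSON.

    Expected layout::

        nodata: -1
        classes:
          - {code: 1, name: "P. australis", dynamic: true}
          - {code: 5, name: "water", dynamic: false}
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    classes = tuple(
        (int(c["code"]), str(c["name"]), bool(c.get("dynamic", True)))
        for c in raw["classes"]
    )
    return ClassScheme(classes=classes, nodata_code=int(raw.get("nodata", -1)))


def dump_scheme(scheme: ClassScheme, path: str | Path) -> None:
    raw = {
        "nodata": scheme.nodata_code,
        "classes": [
            {"code": c, "name": n, "dynamic": d} for c, n, d in scheme.classes
        ],
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))
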