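"""ESRI ASCII grid raster container and I/O.

The grid dialect is the plain-text one used by GIS index interpolators:
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major cell values with the northernmost row
first.  Reading then writing (or vice versa) is the identity on values,
geometry and the nodata mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    """A georeferenced grid of cell values with a nodata sentinel.

    ``values`` is stored with the northernmost row first (the on-disk
    order); cells equal to ``nodata`` are missing and are never computed on.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is nodata."""
        return self.values == self.nodata

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid with this geometry and the given values (nodata kept)."""
        out = np.where(self.mask, self.nodata, values)
        return RasterGrid(out, self.xllcorner, self.yllcorner, self.cellsize, self.nodata)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid, rejecting malformed headers and ragged rows."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and len(header) < 6:
        parts = lines[i].split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: malformed header line {lines[i]!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise ValueError(f"{path}:{i + 1}: unknown header key {parts[0]!r}")
        try:
            header[key] = float(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: non-numeric header value {parts[1]!r}")
        i += 1
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keys {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for j, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != ncols:
            raise ValueError(f"{path}:{j}: expected {ncols} values, got {len(vals)}")
        rows.append([float(v) for v in vals])
    if len(rows) != nrows:
        raise ValueError(f"{path}: expected {nrows} data rows, got {len(rows)}")
    return RasterGrid(
        np.asarray(rows, float),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header["nodata_value"],
    )


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write a grid in the ESRI ASCII dialect (north row first)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
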