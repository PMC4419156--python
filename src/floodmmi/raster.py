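"""Categorical raster container and plain-format I/O.

A :class:`CategoricalRaster` is the common currency of every analysis stage:
a 2-D integer grid of class codes with an explicit nodata code.  Rasters are
read and written as ESRI ASCII grids (``.asc``, a self-describing text
format) or single-band TIFF (``.tif``/``.tiff``).  No coordinate reference
system is carried: pixel size is metadata the analysis never needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999


@dataclass(frozen=True)
class CategoricalRaster:
    """Integer-coded 2-D grid with a nodata sentinel.

    Parameters
    ----------
    data:
        2-D integer array of class codes.
    nodata:
        Code marking pixels outside the valid area.  May be absent from
        ``data`` entirely.
    """

    data: np.ndarray
    nodata: int = DEFAULT_NODATA

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"raster must be integer-coded, got {arr.dtype}")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the pixel carries a real class."""
        return self.data != self.nodata

    def classes(self) -> np.ndarray:
        """Sorted unique class codes, nodata excluded."""
        vals = np.unique(self.data)
        return vals[vals != self.nodata]

    def with_data(self, data: np.ndarray) -> "CategoricalRaster":
        """New raster sharing this raster's nodata code."""
        return CategoricalRaster(data, nodata=self.nodata)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CategoricalRaster):
            return NotImplemented
        return self.nodata == other.nodata and np.array_equal(self.data, other.data)


def read_raster(path: str | Path) -> CategoricalRaster:
    """Read a raster from an ESRI ASCII grid or single-band TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_ascii_grid(path)
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
        return CategoricalRaster(np.asarray(arr, dtype=np.int32))
    raise ValueError(f"unsupported raster format: {path.name!r} (use .asc or .tif)")


def write_raster(raster: CategoricalRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid or single-band TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii_grid(raster, path)
    elif suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, raster.data.astype(np.int32))
    else:
        raise ValueError(f"unsupported raster format: {path.name!r} (use .asc or .tif)")


def _read_ascii_grid(path: Path) -> CategoricalRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: empty or truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, dtype=np.int64)
    body = np.atleast_2d(body)
    nrows = int(header.get("nrows", body.shape[0]))
    ncols = int(header.get("ncols", body.shape[-1]))
    data = body.reshape(nrows, ncols).astype(np.int32)
    nodata = int(header.get("nodata_value", DEFAULT_NODATA))
    return CategoricalRaster(data, nodata=nodata)


def _write_ascii_grid(raster: CategoricalRaster, path: Path) -> None:
    rows, cols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write("cellsize 30.0\n")
        fh.write(f"nodata_value {raster.nodata}\n")
        for row in raster.data:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/1 mask raster as a boolean grid."""
    raster = read_raster(path)
    return raster.data == 1


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean grid as a 0/1 raster."""
    write_raster(CategoricalRaster(mask.astype(np.int32), nodata=DEFAULT_NODATA), path)
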