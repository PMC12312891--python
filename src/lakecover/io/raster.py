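"""Georeferenced raster I/O built on TIFF plus a JSON sidecar.

Rasters are stored as plain TIFF (float32 reflectance stacks, 8-bit
class maps with an embedded color table) with the affine transform, CRS
and nodata value in a ``<name>.tif.json`` sidecar, so the files remain
readable by any TIFF stack while round-tripping the georeferencing this
package needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from ..grids import (
    CLASS_PALETTE,
    ClassMap,
    NODATA,
    RasterHeader,
    ShapeError,
    SpectralImage,
    ValidationError,
)


class RasterIOError(ValidationError):
    """Unreadable, unparseable or inconsistent raster file."""


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _palette_colormap() -> np.ndarray:
    cmap = np.zeros((3, 256), dtype=np.uint16)
    for code, (r, g, b) in CLASS_PALETTE.items():
        cmap[:, code] = [r * 257, g * 257, b * 257]
    return cmap


def write_raster(values: np.ndarray, header: RasterHeader, path: str | Path,
                 date: str = "") -> Path:
    """Write a grid and its header; returns the written path.

    2-D uint8 grids are written as palette class maps; everything else as
    float32 band stacks (bands as the leading TIFF axis).
    """
    path = Path(path)
    values = np.asarray(values)
    if values.ndim == 2:
        rows, cols = values.shape
        bands = 1
    elif values.ndim == 3:
        rows, cols, bands = values.shape
    else:
        raise ShapeError("raster values must be 2-D or 3-D")
    if (rows, cols, bands) != (header.rows, header.cols, header.bands):
        raise ShapeError(
            f"values shape {(rows, cols, bands)} does not match header "
            f"{(header.rows, header.cols, header.bands)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if header.dtype == "uint8" and values.ndim == 2:
        tifffile.imwrite(path, values.astype(np.uint8),
                         colormap=_palette_colormap(),
                         photometric="palette")
    else:
        data = np.moveaxis(values.astype(np.float32), -1, 0)
        tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "rows": header.rows, "cols": header.cols, "bands": header.bands,
        "dtype": header.dtype, "nodata": header.nodata,
        "transform": list(header.transform), "crs": header.crs,
        "date": date,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, RasterHeader, str]:
    """Read values, header and date written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RasterIOError(f"missing georeferencing sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise RasterIOError(f"cannot parse TIFF {path}: {exc}") from exc
    header = RasterHeader(
        rows=meta["rows"], cols=meta["cols"], bands=meta["bands"],
        dtype=meta["dtype"], nodata=meta["nodata"],
        transform=tuple(meta["transform"]), crs=meta["crs"])
    if data.ndim == 3:
        values = np.moveaxis(data, 0, -1)
    else:
        values = data
    expect = ((header.rows, header.cols) if header.bands == 1
              else (header.rows, header.cols, header.bands))
    if values.shape != expect:
        raise RasterIOError(
            f"data shape {values.shape} disagrees with sidecar {expect}")
    return values, header, meta.get("date", "")


def read_class_map(path: str | Path) -> ClassMap:
    values, header, date = read_raster(path)
    return ClassMap(values, date=date, header=header)


def read_spectral_image(path: str | Path) -> SpectralImage:
    values, header, date = read_raster(path)
    if values.ndim == 2:
        values = values[:, :, None]
    mask = None
    if header.nodata is not None:
        mask = np.all(values == header.nodata, axis=-1)
    return SpectralImage(values, date=date, mask=mask, header=header)


def write_class_map(class_map: ClassMap, path: str | Path) -> Path:
    header = class_map.header
    if header.dtype != "uint8":
        header = header.with_bands(1, "uint8")
    return write_raster(class_map.labels, header, path, date=class_map.date)


def write_spectral_image(image: SpectralImage, path: str | Path) -> Path:
    values = image.values.astype(np.float32)
    if image.mask.any():
        nodata = image.header.nodata if image.header.nodata is not None else -9999.0
        values = values.copy()
        values[image.mask] = nodata
    return write_raster(values, image.header, path, date=image.date)
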