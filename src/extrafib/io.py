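"""TIFF and CSV I/O with physical pixel-size metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import CountMap, ProjectionImage

__all__ = ["write_image", "read_image", "write_count_map", "read_count_map"]


def write_image(path: str | Path, image: ProjectionImage) -> None:
    """Write a projection image as 32-bit float TIFF with JSON metadata."""
    meta = {
        "pixel_size_nm": image.pixel_size,
        "axis": list(image.axis),
        "modality": image.modality,
        "axes": list(image.axes),
    }
    tifffile.imwrite(
        str(path),
        image.pixels.astype(np.float32),
        description=json.dumps(meta),
    )


def read_image(path: str | Path) -> ProjectionImage:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        pixels = page.asarray().astype(np.float64)
        meta = json.loads(page.tags["ImageDescription"].value)
    return ProjectionImage(
        pixels=pixels,
        pixel_size=float(meta["pixel_size_nm"]),
        axis=tuple(meta["axis"]),
        modality=meta.get("modality", "mass-thickness"),
        axes=tuple(meta.get("axes", ("x", "z"))),
    )


def write_count_map(path: str | Path, cmap: CountMap) -> None:
    meta = {
        "probe_area_nm2": cmap.probe_area,
        "bin_px": cmap.bin_px,
        "dose_scale": cmap.dose_scale,
        "pixel_size_nm": cmap.pixel_size,
    }
    tifffile.imwrite(
        str(path), cmap.counts.astype(np.float32), description=json.dumps(meta)
    )


def read_count_map(path: str | Path) -> CountMap:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        counts = page.asarray().astype(np.float64)
        meta = json.loads(page.tags["ImageDescription"].value)
    return CountMap(
        counts=counts,
        probe_area=float(meta["probe_area_nm2"]),
        bin_px=int(meta["bin_px"]),
        dose_scale=float(meta["dose_scale"]),
        pixel_size=float(meta["pixel_size_nm"]),
    )
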