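"""Serialization: images (PNG/TIFF + JSON sidecars), contour CSVs.

Height fields go to 16-bit grayscale TIFF, linearly scaled to the full
integer range with the scale recorded in a JSON sidecar; binary masks
to 0/255 PNG; shaded images to 8-bit PNG for display or 16-bit TIFF for
archival.  Contour pixel sets round-trip through the CSV schema
``x, y, orientation_deg, intensity, valid``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .contours import ContourPixelSet
from .shading import ShadedImage
from .terrain import HeightField, LevelCutMask

__all__ = [
    "write_height_field",
    "read_height_field",
    "write_mask",
    "read_mask",
    "write_image",
    "read_image",
    "write_contours",
    "read_contours",
]


def write_height_field(h: HeightField, path: str | Path) -> None:
    """16-bit TIFF plus ``<path>.json`` sidecar with the linear scaling."""
    path = Path(path)
    lo, hi = float(h.heights.min()), float(h.heights.max())
    span = hi - lo if hi > lo else 1.0
    data = np.round((h.heights - lo) / span * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {
        "min_height": lo,
        "max_height": hi,
        "pixel_pitch": h.pixel_pitch,
        "seed": h.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_height_field(path: str | Path) -> HeightField:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = tifffile.imread(path).astype(float) / 65535.0
    heights = meta["min_height"] + data * (meta["max_height"] - meta["min_height"])
    return HeightField(heights, pixel_pitch=meta["pixel_pitch"], seed=meta["seed"])


def write_mask(m: LevelCutMask, path: str | Path) -> None:
    """0/255 PNG plus sidecar recording depth, polarity, rotation."""
    path = Path(path)
    iio.imwrite(path, (m.mask * np.uint8(255)))
    sidecar = {"cut_depth": m.cut_depth, "polarity": m.polarity, "rotated": m.rotated}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_mask(path: str | Path) -> LevelCutMask:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mask = np.asarray(iio.imread(path)) > 127
    return LevelCutMask(mask=mask, **meta)


def write_image(
    img: ShadedImage, path: str | Path, metadata: dict | None = None
) -> None:
    """8-bit PNG or 16-bit TIFF by extension, with optional JSON sidecar."""
    path = Path(path)
    clipped = np.clip(img.luminance, 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(clipped * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(clipped * 255).astype(np.uint8))
    if metadata is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(metadata, indent=2))


def read_image(path: str | Path) -> ShadedImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float) / 65535.0
        return ShadedImage(data, bit_depth=16)
    data = np.asarray(iio.imread(path)).astype(float) / 255.0
    return ShadedImage(data, bit_depth=8)


def write_contours(pixels: ContourPixelSet, path: str | Path) -> None:
    pixels.to_frame().to_csv(path, index=False)


def read_contours(path: str | Path) -> ContourPixelSet:
    return ContourPixelSet.from_frame(pd.read_csv(path))
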