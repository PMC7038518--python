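"""Thin PNG/TIFF image I/O: float [0,1] in memory, 8-bit (or 16-bit) on disk."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def save_image(path, pixels: np.ndarray, bits: int = 8) -> None:
    px = np.asarray(pixels)
    if np.issubdtype(px.dtype, np.floating):
        if bits == 16:
            px = np.clip(np.round(px * 65535.0), 0, 65535).astype(np.uint16)
        else:
            px = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), px)


def load_image(path) -> np.ndarray:
    px = iio.imread(Path(path))
    if px.dtype == np.uint8:
        return (px.astype(np.float32) / 255.0)
    if px.dtype == np.uint16:
        return (px.astype(np.float32) / 65535.0)
    return px.astype(np.float32)
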