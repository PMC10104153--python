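"""Image reading helpers (TIFF via tifffile, PNG and friends via Pillow)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from incisure.errors import InvalidInputError

__all__ = ["read_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale raster; multichannel images are averaged to gray."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise InvalidInputError(f"{path}: expected a 2-D image, got {arr.shape}")
    return arr
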