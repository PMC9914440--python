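"""File I/O helpers: single-channel TIFF masks/images, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), mask.astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_image_tiff(img: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), img)


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_counts_tiff(counts: np.ndarray, path) -> None:
    """Rendered STORM images are written as 32-bit count images."""
    tifffile.imwrite(str(path), counts.astype(np.float32))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
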