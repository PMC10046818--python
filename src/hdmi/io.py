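"""File formats: TIFF/PNG images, multi-frame TIFF stacks, CSV, graph JSON.

Binary masks and 16-bit intensity images round-trip losslessly. Pixel size
(µm/pixel) is carried in a JSON sidecar (``<image>.meta.json``) since PNG and
plain TIFF lack a reliable physical-units field.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import PowerImage, RoiMask, SlowTimeStack, VesselMask

__all__ = [
    "read_image", "write_image", "read_stack", "write_stack",
    "read_roi", "write_cohort", "read_cohort",
]

COHORT_COLUMNS = [
    "id", "label", "NB", "NV", "VD", "D_max_um", "VDR", "tau_max",
    "tau_mean", "mvFD", "BA_mean", "BA_max", "MD_mean", "MD_max", "SVP",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_meta(path: Path, pixel_size: float, kind: str) -> None:
    _sidecar(path).write_text(json.dumps({"pixel_size_um": pixel_size, "kind": kind}))


def _read_meta(path: Path, default_pixel_size: float = 1.0) -> dict:
    side = _sidecar(path)
    if side.exists():
        return json.loads(side.read_text())
    return {"pixel_size_um": default_pixel_size, "kind": "unknown"}


def write_image(path, img, pixel_size: float | None = None) -> None:
    """Write a 2-D image (mask, intensity, or power) as TIFF or PNG.

    Masks are stored as uint8 {0, 255}; float intensity images are stored
    as float32 TIFF (or rescaled uint16 for PNG).
    """
    path = Path(path)
    if isinstance(img, VesselMask):
        data, px, kind = img.data, img.pixel_size, "mask"
    elif isinstance(img, PowerImage):
        data, px, kind = img.values, img.pixel_size, "intensity"
    else:
        data = np.asarray(img)
        px = pixel_size if pixel_size is not None else 1.0
        kind = "mask" if data.dtype == bool else "intensity"
    if pixel_size is not None:
        px = pixel_size

    if data.dtype == bool:
        out = (data.astype(np.uint8)) * 255
    elif path.suffix.lower() == ".png":
        if data.dtype not in (np.uint8, np.uint16):
            peak = float(np.max(data)) or 1.0
            out = np.round(data / peak * 65535).astype(np.uint16)
        else:
            out = data
    else:
        out = data.astype(np.float32) if data.dtype.kind == "f" else data

    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, out)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    _write_meta(path, px, kind)


def read_image(path, kind: str = "intensity", default_pixel_size: float = 1.0):
    """Read a 2-D image. ``kind``: "mask" normalizes {0, 255} to bool;
    "intensity" returns a PowerImage."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if data.ndim != 2:
        raise ValueError("expected a single-frame 2-D image")
    meta = _read_meta(path, default_pixel_size)
    px = float(meta.get("pixel_size_um", default_pixel_size))
    if kind == "mask":
        return data > (data.max() / 2 if data.max() > 1 else 0)
    if kind == "intensity":
        return PowerImage(values=np.abs(np.asarray(data, dtype=float)), pixel_size=px)
    raise ValueError(f"unknown image kind {kind!r}")


def read_roi(path, pixel_size: float | None = None, provenance: str = "manual") -> RoiMask:
    path = Path(path)
    data = read_image(path, kind="mask")
    meta = _read_meta(path)
    px = pixel_size if pixel_size is not None else float(meta["pixel_size_um"])
    return RoiMask(data=data, pixel_size=px, provenance=provenance)


def write_stack(path, stack: SlowTimeStack) -> None:
    """Multi-frame TIFF, frames first (frames, rows, cols), lossless float32/64."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0))
    _sidecar(path).write_text(json.dumps({
        "pixel_size_um": stack.pixel_size,
        "frame_rate_hz": stack.frame_rate,
        "kind": "stack",
    }))


def read_stack(path, default_pixel_size: float = 100.0) -> SlowTimeStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 3:
        raise ValueError("expected a multi-frame TIFF stack")
    meta = _read_meta(path, default_pixel_size)
    return SlowTimeStack(
        data=np.moveaxis(data, 0, 2),
        frame_rate=float(meta.get("frame_rate_hz", 1000.0)),
        pixel_size=float(meta.get("pixel_size_um", default_pixel_size)),
    )


def write_cohort(path, cohort: pd.DataFrame) -> None:
    """Cohort CSV with the canonical column order first, extras after."""
    first = [c for c in COHORT_COLUMNS if c in cohort.columns]
    rest = [c for c in cohort.columns if c not in first]
    cohort[first + rest].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("cohort CSV must have a 'label' column")
    return df
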