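"""Image and table I/O."""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .colorspace import RasterImage
from .morphometry import SectionMeasurements

__all__ = ["load_image", "save_mask_png", "save_image",
           "measurements_to_row", "SECTION_COLUMNS"]


def load_image(path: str | Path, pixel_size: float = 1.0) -> RasterImage:
    """Read an 8- or 16-bit RGB(A) TIFF or PNG.

    Alpha is dropped with a warning; 16-bit data is scaled to [0, 1];
    grayscale images are rejected (the color pipeline needs RGB).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = iio.imread(path)
        else:
            raise ValueError(
                f"unsupported format {suffix!r}: expected TIFF or PNG")
    except ValueError:
        raise
    except Exception as exc:  # unreadable/corrupt file
        raise ValueError(f"could not read {path} as {suffix}: {exc}") from exc

    if arr.ndim == 2:
        raise ValueError(
            f"{path} is grayscale; the pipeline requires an RGB image")
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: unsupported shape {arr.shape}")
    if arr.shape[2] == 4:
        warnings.warn(f"{path.name}: alpha channel dropped", stacklevel=2)
        arr = arr[..., :3]

    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(np.float64)
        if pixels.min() < 0 or pixels.max() > 1:
            raise ValueError(f"{path}: float pixels must lie in [0, 1]")
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    return RasterImage(pixels=pixels, pixel_size=pixel_size, id=path.stem)


def save_image(image: RasterImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG or TIFF."""
    path = Path(path)
    arr = np.round(image.pixels * 255.0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = inside)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


#: Fixed column order for per-section CSV rows.
SECTION_COLUMNS = [
    "image_id", "placenta_id", "total_area", "lz_area", "jz_area",
    "decidua_area", "lz_tissue_pct", "jz_tissue_pct", "decidua_tissue_pct",
    "border_length", "tortuosity", "excluded_area", "pixel_size",
    "seed", "config_hash", "session_hash", "warnings",
]


def measurements_to_row(
    meas: SectionMeasurements,
    placenta_id: str = "",
    warnings_text: str = "",
) -> dict:
    return {
        "image_id": meas.image_id,
        "placenta_id": placenta_id,
        "total_area": meas.total_area,
        "lz_area": meas.lz_area,
        "jz_area": meas.jz_area,
        "decidua_area": meas.decidua_area,
        "lz_tissue_pct": meas.lz_tissue_pct,
        "jz_tissue_pct": meas.jz_tissue_pct,
        "decidua_tissue_pct": meas.decidua_tissue_pct,
        "border_length": meas.border_length,
        "tortuosity": meas.tortuosity,
        "excluded_area": meas.excluded_area,
        "pixel_size": meas.pixel_size,
        "seed": meas.provenance.get("seed", ""),
        "config_hash": meas.provenance.get("config_hash", ""),
        "session_hash": meas.provenance.get("session_hash", ""),
        "warnings": warnings_text,
    }


def write_section_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=SECTION_COLUMNS).to_csv(path, index=False)
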