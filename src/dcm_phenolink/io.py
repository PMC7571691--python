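"""File I/O for images and traces: 16-bit TIFF + JSON sidecar, CSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from dcm_phenolink.synth.images import SarcomereImage

__all__ = ["write_image", "read_image", "write_trace_csv", "read_trace_csv"]


def write_image(image: SarcomereImage, path: str | Path) -> None:
    """Write a 16-bit grayscale TIFF plus a ``.json`` sidecar with pixel size.

    Intensities are linearly rescaled into the uint16 range; the scale and
    offset are recorded in the sidecar so the float image round-trips.
    """
    path = Path(path)
    img = image.intensity
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quantized = np.round((img - lo) / scale).astype(np.uint16)
    tifffile.imwrite(path, quantized)
    sidecar = {"pixel_size_um": image.pixel_size_um, "offset": lo, "scale": scale}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_image(path: str | Path, pixel_size_um: float | None = None) -> SarcomereImage:
    """Read a TIFF/PNG image; pixel size comes from the sidecar unless given."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    offset, scale = 0.0, 1.0
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size_um = pixel_size_um or sidecar.get("pixel_size_um")
        offset = sidecar.get("offset", 0.0)
        scale = sidecar.get("scale", 1.0)
    if pixel_size_um is None:
        raise ValueError(f"no pixel size for {path}: provide it or write a JSON sidecar")
    return SarcomereImage(intensity=arr * scale + offset, pixel_size_um=pixel_size_um)


def write_trace_csv(time_s: np.ndarray, value: np.ndarray, path: str | Path, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": time_s, value_name: value}).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path} must have a time_s column")
    return df
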