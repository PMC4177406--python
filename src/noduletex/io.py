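"""File formats: 16-bit PNG, single-frame DICOM (read-only), CSV tables,
and the subband archive."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
from PIL import Image

from noduletex.contourlet import SubbandSet, TransformConfig

__all__ = [
    "write_png16",
    "read_png16",
    "read_dicom_frame",
    "write_subband_archive",
    "read_subband_archive",
    "write_feature_matrix",
    "read_feature_matrix",
]

# Gray values are stored as 16-bit PNG with a fixed linear map (value *
# _PNG_SCALE), a Hounsfield-like convention recorded here for round-trips.
_PNG_SCALE = 64.0


def write_png16(path: str | Path, pixels: np.ndarray,
                scale: float = _PNG_SCALE) -> None:
    arr = np.clip(np.asarray(pixels, dtype=float) * scale, 0, 65535)
    Image.fromarray(arr.astype(np.uint16)).save(str(path))


def read_png16(path: str | Path, scale: float = _PNG_SCALE) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)), dtype=float)
    return arr / scale


def read_dicom_frame(path: str | Path) -> Tuple[np.ndarray, float]:
    """Pixel data and in-plane pixel spacing (mm) of a single-frame DICOM."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array.astype(float)
    if pixels.ndim != 2:
        raise ValueError("expected a single-frame (2-D) DICOM image")
    spacing = getattr(ds, "PixelSpacing", None)
    pixel_size = float(spacing[0]) if spacing is not None else 1.0
    return pixels, pixel_size


def write_subband_archive(sb: SubbandSet, outdir: str | Path) -> Path:
    """Directory of 32-bit float arrays plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {
        "config": {
            "levels": sb.config.levels,
            "directions_per_level": sb.config.directions_per_level,
            "lp_filter": sb.config.lp_filter,
            "dfb_filter": sb.config.dfb_filter,
            "boundary": sb.config.boundary,
        },
        "lowpass": {"file": "lowpass.f32", "shape": list(sb.lowpass.shape)},
        "subbands": [],
    }
    sb.lowpass.astype(np.float32).tofile(outdir / "lowpass.f32")
    for (level, direction), band in sorted(sb.subbands.items()):
        name = f"L{level}_D{direction}.f32"
        band.astype(np.float32).tofile(outdir / name)
        index["subbands"].append(
            {"level": level, "direction": direction, "file": name,
             "shape": list(band.shape)})
    (outdir / "index.json").write_text(json.dumps(index, indent=1))
    return outdir


def read_subband_archive(indir: str | Path) -> SubbandSet:
    indir = Path(indir)
    index = json.loads((indir / "index.json").read_text())
    config = TransformConfig(**index["config"])
    lowpass = np.fromfile(indir / index["lowpass"]["file"],
                          dtype=np.float32).reshape(index["lowpass"]["shape"])
    subbands = {}
    for e in index["subbands"]:
        arr = np.fromfile(indir / e["file"], dtype=np.float32)
        subbands[(e["level"], e["direction"])] = arr.reshape(e["shape"]).astype(float)
    return SubbandSet(lowpass=lowpass.astype(float), subbands=subbands,
                      config=config)


def write_feature_matrix(path: str | Path, frame: pd.DataFrame) -> None:
    """Feature matrix CSV: roi_id, patient_id, label, diameter_mm, then the
    canonical feature columns."""
    lead = ["roi_id", "patient_id", "label", "diameter_mm"]
    cols = lead + [c for c in frame.columns if c not in lead]
    frame[cols].to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
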