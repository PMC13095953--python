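"""Reading and writing the pipeline's on-disk formats.

Images are single-channel TIFF (16-bit) or PNG (8-bit); tabular outputs
(detections, per-bead measurements, dilution series) are plain CSV with
documented headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detect import Detection
from .errors import ValidationError
from .quantify import BeadMeasurement
from .synthetic import CalibrationDataset, Micrograph

DETECTION_COLUMNS = ["image", "x", "y", "radius", "x0", "y0", "x1", "y1", "confidence"]
MEASUREMENT_COLUMNS = ["bead_id", "x", "y", "radius", "zone", "mean_fl",
                       "n_pixels", "saturated_fraction"]


def read_micrograph(path: str | Path, pixel_size: float = 0.5,
                    channel: str = "bright-field") -> Micrograph:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 2:
        raise ValidationError(f"{path.name}: expected a single-channel image")
    bit_depth = 16 if data.dtype.itemsize > 1 else 8
    return Micrograph(data, pixel_size, bit_depth, channel)


def write_micrograph(path: str | Path, image: Micrograph) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.data)
    else:
        iio.imwrite(path, image.data)


def detections_to_frame(detections: Sequence[Detection],
                        image: str = "") -> pd.DataFrame:
    rows = [
        {
            "image": image,
            "x": d.center[0],
            "y": d.center[1],
            "radius": d.radius,
            "x0": d.bbox[0],
            "y0": d.bbox[1],
            "x1": d.bbox[2],
            "y1": d.bbox[3],
            "confidence": d.confidence,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detections_from_frame(frame: pd.DataFrame) -> list[Detection]:
    return [
        Detection(
            center=(row.x, row.y),
            radius=row.radius,
            bbox=(int(row.x0), int(row.y0), int(row.x1), int(row.y1)),
            confidence=row.confidence,
        )
        for row in frame.itertuples()
    ]


def measurements_to_frame(measurements: Sequence[BeadMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "bead_id": m.bead_id,
            "x": m.center[0],
            "y": m.center[1],
            "radius": m.radius,
            "zone": m.zone,
            "mean_fl": m.mean_fl,
            "n_pixels": m.n_pixels,
            "saturated_fraction": m.saturated_fraction,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def read_dilution_series(path: str | Path) -> CalibrationDataset:
    """Read a dilution-series CSV (concentration, signal, replicate, is_blank)."""
    frame = pd.read_csv(path)
    required = {"concentration", "signal", "is_blank"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"dilution series is missing columns: {sorted(missing)}")
    if "replicate" not in frame.columns:
        frame["replicate"] = 0
    return CalibrationDataset.from_frame(frame)
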