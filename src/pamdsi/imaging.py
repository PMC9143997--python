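"""Per-AOI extraction from Imaging-PAM parameter maps.

An Imaging-PAM instrument reports each fluorescence quantity as a
single-channel parameter image (640 x 480 pixels for the MAXI head).
Measurements are taken as the mean over circular areas of interest
(AOIs) placed on each leaflet.  Necrotic tissue appears as black
(near-zero) pixels in the parameter maps and must be excluded before
averaging, otherwise lesions drag AOI means toward zero.

Pixel-in-circle rule: a pixel belongs to an AOI when its centre (integer
0-based coordinates) lies within Euclidean distance ``radius`` of the
circle centre.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "AOICircle",
    "circular_mask",
    "mask_necrosis",
    "extract_aoi_values",
    "default_necrosis_threshold",
    "write_stack",
    "read_stack",
    "write_aois",
    "read_aois",
]


@dataclass
class AOICircle:
    """Circular area of interest in pixel coordinates (0-based)."""

    center_x: float
    center_y: float
    radius: float
    leaflet_id: int = 0
    aoi_index: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class ImageStack:
    """Co-registered single-channel parameter images.

    ``channels`` maps a quantity name (e.g. ``"fvfm"``) to a 2-D array;
    all channels share one shape.  ``valid`` is an optional boolean mask
    of pixels usable for statistics (False = necrotic/flagged).
    """

    channels: dict[str, np.ndarray]
    pixel_scale: float | None = None  # mm per pixel
    valid: np.ndarray | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative values")
        if self.valid is not None and self.valid.shape != self.shape:
            raise ValueError("valid mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]


def circular_mask(circle: AOICircle, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the circle.

    Raises if the circle is not entirely within the image bounds.
    """
    h, w = shape
    if (
        circle.center_x - circle.radius < -0.5
        or circle.center_y - circle.radius < -0.5
        or circle.center_x + circle.radius > w - 0.5
        or circle.center_y + circle.radius > h - 0.5
    ):
        raise ValueError(
            f"AOI circle (x={circle.center_x}, y={circle.center_y}, "
            f"r={circle.radius}) exceeds image bounds {h}x{w}"
        )
    yy, xx = np.ogrid[:h, :w]
    return (xx - circle.center_x) ** 2 + (yy - circle.center_y) ** 2 <= circle.radius**2


def default_necrosis_threshold(stack: ImageStack, reference_channel: str) -> float:
    """2% of the 99th percentile of the reference channel's signal.

    Separates true (necrotic) zeros from genuine low signal without
    assuming absolute fluorescence units.  The percentile is taken over
    positive pixels so that a large zero background (small leaf in the
    frame) cannot drag the threshold to zero.
    """
    ref = stack.channels[reference_channel]
    signal = ref[ref > 0]
    if signal.size == 0:
        return 0.0
    return 0.02 * float(np.percentile(signal, 99))


def mask_necrosis(
    stack: ImageStack, reference_channel: str, threshold: float | None = None
) -> ImageStack:
    """Flag necrotic pixels (reference value below threshold) as invalid.

    Returns a new stack whose ``valid`` mask excludes flagged pixels from
    downstream statistics; an existing mask is intersected.
    """
    if reference_channel not in stack.channels:
        raise ValueError(f"no channel {reference_channel!r} in stack")
    if threshold is None:
        threshold = default_necrosis_threshold(stack, reference_channel)
    valid = stack.channels[reference_channel] >= threshold
    if stack.valid is not None:
        valid &= stack.valid
    return ImageStack(dict(stack.channels), pixel_scale=stack.pixel_scale, valid=valid)


def extract_aoi_values(
    stack: ImageStack, aois: list[AOICircle], statistic: str = "mean"
) -> pd.DataFrame:
    """Per-AOI summary of every channel over valid pixels.

    Returns one row per AOI with columns ``leaflet_id``, ``aoi_index``,
    ``n_valid_pixels`` and one column per channel.  An AOI with no valid
    pixels (fully necrotic) reports NaN, never 0.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    reduce = np.mean if statistic == "mean" else np.median
    rows = []
    for circle in aois:
        mask = circular_mask(circle, stack.shape)
        if stack.valid is not None:
            mask = mask & stack.valid
        row = {
            "leaflet_id": circle.leaflet_id,
            "aoi_index": circle.aoi_index,
            "n_valid_pixels": int(mask.sum()),
        }
        for name, arr in stack.channels.items():
            row[name] = float(reduce(arr[mask])) if mask.any() else np.nan
        rows.append(row)
    columns = ["leaflet_id", "aoi_index", "n_valid_pixels", *stack.channels]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# IO: one single-channel 32-bit TIFF per quantity + a JSON AOI side-car.

def write_stack(stack: ImageStack, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.channels.items():
        tifffile.imwrite(directory / f"{name}.tif", arr.astype(np.float32))


def read_stack(directory: str | Path) -> ImageStack:
    directory = Path(directory)
    channels = {
        p.stem: tifffile.imread(p).astype(float)
        for p in sorted(directory.glob("*.tif"))
    }
    if not channels:
        raise FileNotFoundError(f"no .tif channels under {directory}")
    return ImageStack(channels)


def write_aois(aois: list[AOICircle], path: str | Path) -> None:
    payload = [
        {
            "center_x": c.center_x,
            "center_y": c.center_y,
            "radius": c.radius,
            "leaflet_id": c.leaflet_id,
            "aoi_index": c.aoi_index,
        }
        for c in aois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_aois(path: str | Path) -> list[AOICircle]:
    payload = json.loads(Path(path).read_text())
    return [AOICircle(**entry) for entry in payload]
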