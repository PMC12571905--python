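"""Core containers and file I/O.

Image stacks are plain numpy arrays wrapped with their physical calibration
(pixel size, frame interval, optional z spacing).  Stacks are written as
OME-TIFF with axes ``TYX`` or ``TZYX``; regions of interest and ground-truth
event tables travel as CSV.  Time is measured in minutes from frame 0
(0-based frame index, ``time = frame * frame_interval``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = ["ImageStack", "CellROI", "read_stack", "write_stack",
           "read_rois", "write_rois"]


@dataclass
class ImageStack:
    """A time-ordered (optionally z-resolved) pixel array for one channel.

    Parameters
    ----------
    data:
        ``(T, Y, X)`` or ``(T, Z, Y, X)`` float array.
    pixel_size:
        Lateral calibration in µm/px.
    frame_interval:
        Minutes per frame.
    z_step:
        Axial spacing in µm (``None`` for 2-D stacks).
    channel:
        Channel name, e.g. ``"phase"`` or ``"dibac"``.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    z_step: float | None = None
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("ImageStack data must be (T,Y,X) or (T,Z,Y,X)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.data.ndim == 4 and (self.z_step is None or self.z_step <= 0):
            raise ValueError("z-resolved stacks need a positive z_step")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def time(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Minutes elapsed at a 0-based frame index."""
        return frame * self.frame_interval

    def frame_at(self, t: float) -> int:
        """First frame whose acquisition time is >= ``t`` minutes."""
        return int(np.ceil(t / self.frame_interval - 1e-9))


@dataclass
class CellROI:
    """A tracked cell region (pixel bounding box, half-open, 0-based).

    ``frame_last`` is the last frame at which the cell is present in the
    monolayer; for extruding cells this is the frame at which the extrusion
    becomes visible, which downstream analysis treats as the observed
    extrusion time.
    """

    cell_id: int
    frame_first: int
    frame_last: int
    x_min: int
    y_min: int
    x_max: int
    y_max: int
    centroid_x: float
    centroid_y: float

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return self.y_min, self.x_min, self.y_max, self.x_max

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def width(self) -> int:
        return self.x_max - self.x_min


ROI_COLUMNS = ["cell_id", "frame_first", "frame_last", "x_min", "y_min",
               "x_max", "y_max", "centroid_x", "centroid_y"]


def write_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a stack as OME-TIFF with axes and calibration metadata."""
    path = Path(path)
    axes = "TYX" if stack.data.ndim == 3 else "TZYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": stack.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size,
        "PhysicalSizeYUnit": "µm",
        "TimeIncrement": stack.frame_interval,
        "TimeIncrementUnit": "min",
        "Channel": {"Name": [stack.channel or "channel0"]},
    }
    if stack.z_step is not None:
        metadata["PhysicalSizeZ"] = stack.z_step
        metadata["PhysicalSizeZUnit"] = "µm"
    try:
        tifffile.imwrite(path, stack.data, ome=True, metadata=metadata)
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed to write stack to {path}: {exc}") from exc
    return path


def read_stack(path: str | Path, channel: str = "") -> ImageStack:
    """Read an OME-TIFF written by :func:`write_stack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.ome_metadata or ""
    pixel_size = _ome_float(meta, "PhysicalSizeX", default=1.0)
    frame_interval = _ome_float(meta, "TimeIncrement", default=1.0)
    z_step = _ome_float(meta, "PhysicalSizeZ", default=0.0) or None
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_size=pixel_size,
                      frame_interval=frame_interval, z_step=z_step,
                      channel=channel or path.stem)


def _ome_float(xml: str, key: str, default: float) -> float:
    marker = f'{key}="'
    i = xml.find(marker)
    if i < 0:
        return default
    j = xml.index('"', i + len(marker))
    return float(xml[i + len(marker):j])


def write_rois(path: str | Path, rois: Sequence[CellROI]) -> Path:
    path = Path(path)
    df = pd.DataFrame([{c: getattr(r, c) for c in ROI_COLUMNS} for r in rois],
                      columns=ROI_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_rois(path: str | Path) -> list[CellROI]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rois file {path} missing columns: {sorted(missing)}")
    return [CellROI(**{c: (float(row[c]) if c.startswith("centroid")
                           else int(row[c])) for c in ROI_COLUMNS})
            for _, row in df.iterrows()]
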