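"""Image-stack container and TIFF I/O.

Movies are held as a (frames, rows, cols) float or integer array together
with the two pieces of metadata every downstream stage needs: the pixel size
(μm/pixel) and the frame interval (s). Both are stored in the TIFF
ImageDescription as JSON so a round trip through disk preserves them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class ImageStack:
    data: np.ndarray  # (n_frames, ny, nx)
    pixel_size: float  # μm / pixel
    dt: float  # s / frame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("stack must be (frames, rows, cols)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]


def write_stack(path, stack: ImageStack) -> None:
    desc = json.dumps({"pixel_size_um": stack.pixel_size, "dt_s": stack.dt})
    tifffile.imwrite(path, stack.data, description=desc, photometric="minisblack")


def read_stack(path, pixel_size: float | None = None, dt: float | None = None) -> ImageStack:
    """Read a TIFF movie; metadata from the file unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt_ = dt if dt is not None else meta.get("dt_s")
    if px is None or dt_ is None:
        raise ValueError("pixel_size / dt not in TIFF metadata; pass them explicitly")
    return ImageStack(data=data, pixel_size=float(px), dt=float(dt_))
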