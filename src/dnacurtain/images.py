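"""Image-stack container with multi-page TIFF round trip.

Stacks carry their physical calibration (pixel size, frame interval) in a
YAML sidecar next to the TIFF so downstream stages never guess units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml


@dataclass
class ImageStack:
    """A (n_frames, ny, nx) stack with physical calibration."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image stack must be 3D (frames, y, x)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        sidecar = {
            "pixel_size_um": float(self.pixel_size_um),
            "frame_interval_s": float(self.frame_interval_s),
            **{k: v for k, v in self.metadata.items()},
        }
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        sidecar_path = path.with_suffix(path.suffix + ".yaml")
        meta: dict = {}
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                meta = yaml.safe_load(fh) or {}
        pixel = float(meta.pop("pixel_size_um", float("nan")))
        dt = float(meta.pop("frame_interval_s", float("nan")))
        return cls(data=data, pixel_size_um=pixel, frame_interval_s=dt, metadata=meta)
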