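"""The in-memory container shared by the simulator, loader and trainer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FundusSample:
    """A fundus image with paired vessel and field-of-view ground truth.

    ``image`` is H×W×3 float in [0,1]; ``vessel_mask`` and ``fov_mask`` are
    H×W uint8 in {0,1}.  Every vessel pixel lies inside the FOV disc.
    """

    image: np.ndarray
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    native_height: int
    native_width: int
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def validate(self) -> "FundusSample":
        h, w = self.image.shape[:2]
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H×W×3")
        if self.vessel_mask.shape != (h, w) or self.fov_mask.shape != (h, w):
            raise ValueError("mask shapes must match image")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0,1]")
        for name, m in (("vessel_mask", self.vessel_mask),
                        ("fov_mask", self.fov_mask)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} must be binary")
        if np.any(self.vessel_mask & ~self.fov_mask.astype(bool)):
            raise ValueError("vessel pixels found outside the FOV")
        return self
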