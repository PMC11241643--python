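"""Shared containers for the mucosa-slice analysis pipeline.

Images are plain :class:`numpy.ndarray` objects throughout (2D ``uint8``
intensity grids, boolean masks, or integer label maps with 0 = background),
following scikit-image conventions.  The classes here only bundle them with
the metadata the quantification steps need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Channel roles of one fluorescence field of view, in acquisition order.
FLUOR_CHANNELS = ("dapi", "p63", "edu", "tunel", "53bp1")


class UndefinedResultError(ValueError):
    """A ratio metric whose denominator is empty.

    Mirrors the exclusion rule for samples without healthy epithelium: the
    result is undefined rather than zero.  ``qc_flag`` names the failed
    quality-control condition so callers can record it.
    """

    def __init__(self, message: str, qc_flag: str):
        super().__init__(message)
        self.qc_flag = qc_flag


@dataclass(frozen=True)
class Condition:
    """Experimental condition attached to every measurement."""

    sample: str
    dose_gy: float = 0.0
    modality: str = "xray"  # "xray" | "proton"
    day: int = 0            # days of ex vivo culture after irradiation
    fov: int = 0            # field-of-view index within the condition

    def group_key(self) -> tuple:
        """Key for pooling FoVs of the same treatment arm and timepoint."""
        return (self.dose_gy, self.modality, self.day)

    def arm_label(self) -> str:
        return f"{self.dose_gy:g}Gy_{self.modality}"

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "dose_gy": self.dose_gy,
            "modality": self.modality,
            "day": self.day,
            "fov": self.fov,
        }


@dataclass
class MultiChannelImage:
    """Co-registered single-channel 8-bit images keyed by channel role."""

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self):
        shapes = {ch: img.shape for ch, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels are not co-registered: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def as_bool_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError(f"{name} must be a boolean array, got {mask.dtype}")
    if mask.ndim != 2:
        raise ValueError(f"{name} must be 2D")
    return mask


def check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"inputs are not co-registered: {sorted(shapes)}")
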