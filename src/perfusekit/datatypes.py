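"""Core data containers shared across the perfusion pipeline.

Axis convention: 4D series are ``(t, z, y, x)``; 3D maps are ``(z, y, x)``.
All times are seconds from the first acquired frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Any

import numpy as np

#: Recognised series modalities and their native units.
MODALITY_UNITS = {
    "iodine_density": "mg/mL",
    "conventional_hu": "HU",
}


class Region(IntEnum):
    """Voxel labels for the digital phantom.

    The myocardium-like tissue is split into three perfusion states
    (highly affected by the stenosis, unaffected, moderately affected);
    the blood pool is the homogeneous region the arterial input function
    is measured in.
    """

    BACKGROUND = 0
    HIGHLY = 1
    UNAFFECTED = 2
    MODERATE = 3
    BLOOD_POOL = 4


#: Labels belonging to perfused myocardium-like tissue.
TISSUE_REGIONS = (Region.HIGHLY, Region.UNAFFECTED, Region.MODERATE)


@dataclass
class TimeSeriesVolume:
    """A 4D dynamic acquisition: voxel values over time.

    Parameters
    ----------
    data : ndarray, shape (t, z, y, x)
        Voxel values in ``units``.
    timestamps : ndarray, shape (t,)
        Seconds from the first frame; strictly increasing.
    modality : {"iodine_density", "conventional_hu"}
    units : {"mg/mL", "HU"}
    meta : dict
        Free-form provenance (seed, config hash, ...).
    """

    data: np.ndarray
    timestamps: np.ndarray
    modality: str
    units: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"series data must be 4D (t, z, y, x); got ndim={self.data.ndim}"
            )
        if self.timestamps.ndim != 1 or len(self.timestamps) != self.data.shape[0]:
            raise ValueError(
                "timestamps length must equal the number of frames "
                f"({len(self.timestamps)} != {self.data.shape[0]})"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.modality not in MODALITY_UNITS:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.units:
            self.units = MODALITY_UNITS[self.modality]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class AIFCurve:
    """Arterial input function sampled at the acquisition time points."""

    times: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("AIF times and values must be 1D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("AIF times must be strictly increasing")


@dataclass
class RegionLabelMap:
    """Per-voxel ground-truth region labels, shape (z, y, x), dtype uint8."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D (z, y, x)")
        valid = {int(r) for r in Region}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label codes: {sorted(present - valid)}")

    def mask(self, *regions: Region) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.labels, [int(r) for r in regions])

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.mask(*TISSUE_REGIONS)

    def counts(self) -> dict[str, int]:
        return {
            r.name.lower(): int(np.count_nonzero(self.labels == int(r)))
            for r in Region
        }
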