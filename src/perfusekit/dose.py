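"""Radiation-dose arithmetic and temporal undersampling.

A dynamic perfusion protocol accumulates dose linearly in the number of
acquired time points: DLP = n * CTDIvol_per_timepoint * coverage, and
effective dose = DLP * anatomical conversion factor. Dropping frames
therefore reduces dose proportionally; the undersampling operation keeps
a uniform index subset (always including the first and last frame) of
all TACs including the AIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AIFCurve, TimeSeriesVolume

__all__ = [
    "AcquisitionProtocol",
    "undersample_indices",
    "undersample",
    "undersample_aif",
    "dlp",
    "effective_dose",
    "dose_reduction_fraction",
    "format_dose",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Dose-relevant facts of a dynamic CT perfusion protocol.

    Defaults match a 36-point myocardial perfusion protocol at 120 kVp,
    100 mAs per time point, 9 mGy CTDIvol per scan, 4 cm detector
    coverage, and the thorax conversion factor 0.015 mSv/(mGy*cm).
    """

    kvp: float = 120.0
    exposure_mas: float = 100.0
    ctdi_per_timepoint: float = 9.0       # mGy
    coverage_cm: float = 4.0              # cm
    n_timepoints: int = 36
    duration_s: float = 26.9              # s
    conversion_factor: float = 0.015      # mSv/(mGy*cm)

    def __post_init__(self) -> None:
        if min(self.kvp, self.exposure_mas, self.ctdi_per_timepoint,
               self.coverage_cm, self.duration_s, self.conversion_factor) <= 0:
            raise ValueError("all protocol quantities must be positive")
        if not (isinstance(self.n_timepoints, (int, np.integer))
                and self.n_timepoints >= 1):
            raise ValueError("n_timepoints must be an integer >= 1")


def undersample_indices(n: int, k: int) -> np.ndarray:
    """Uniform frame subset: round(linspace(0, n-1, k)), first and last kept."""
    if k < 2:
        raise ValueError("need at least 2 retained frames")
    if k > n:
        raise ValueError(f"cannot keep {k} of {n} frames")
    idx = np.round(np.linspace(0, n - 1, k)).astype(int)
    assert idx[0] == 0 and idx[-1] == n - 1 and np.all(np.diff(idx) > 0)
    return idx


def undersample(series: TimeSeriesVolume, k: int,
                strategy: str = "uniform") -> TimeSeriesVolume:
    """Temporally undersample a 4D series to ``k`` frames."""
    if strategy != "uniform":
        raise ValueError(f"unknown undersampling strategy {strategy!r}")
    idx = undersample_indices(series.n_timepoints, k)
    meta = dict(series.meta)
    meta["undersample_indices"] = idx.tolist()
    return TimeSeriesVolume(
        data=series.data[idx], timestamps=series.timestamps[idx],
        modality=series.modality, units=series.units, meta=meta,
    )


def undersample_aif(aif: AIFCurve, k: int, n: int | None = None) -> AIFCurve:
    """Apply the same uniform frame subset to an AIF curve."""
    n = len(aif.times) if n is None else n
    idx = undersample_indices(n, k)
    return AIFCurve(times=aif.times[idx], values=aif.values[idx],
                    source=aif.source)


def dlp(protocol: AcquisitionProtocol) -> float:
    """Dose-length product (mGy*cm) of the full protocol."""
    return protocol.n_timepoints * protocol.ctdi_per_timepoint * protocol.coverage_cm


def effective_dose(dlp_value: float, k_factor: float = 0.015) -> float:
    """Effective dose (mSv) from DLP and an anatomical conversion factor."""
    if dlp_value < 0 or k_factor < 0:
        raise ValueError("dlp and k_factor must be >= 0")
    return dlp_value * k_factor


def dose_reduction_fraction(n_full: int, n_reduced: int) -> float:
    """Dose reduction (%) achieved by keeping n_reduced of n_full frames."""
    if not 0 < n_reduced <= n_full:
        raise ValueError("require 0 < n_reduced <= n_full")
    return 100.0 * (1.0 - n_reduced / n_full)


def format_dose(msv: float) -> str:
    """Report a dose in mSv: integer above 10 mSv, one decimal below."""
    return f"{msv:.0f}" if msv >= 10 else f"{msv:.1f}"
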