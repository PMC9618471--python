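"""Quantitative perfusion parameter maps and region analyses.

From per-voxel one-compartment fits (A, lambda) the central volume
principle gives, for the exponential impulse response A*exp(-lambda*t):

    MTT             = 1 / lambda                 (s)
    volume fraction = 100 * A / lambda           (mL / 100 mL)
    blood flow      = 6000 * A                   (mL / min / 100 mL)

so that volume = flow * MTT / 60 holds identically wherever fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datatypes import Region, RegionLabelMap

__all__ = [
    "PerfusionMaps",
    "LineProfile",
    "derive_maps",
    "roi_snr",
    "line_profile",
    "classify_thresholds",
    "MTTBandClassifier",
    "region_stats",
]


@dataclass
class PerfusionMaps:
    """Derived perfusion maps, shape (z, y, x); NaN outside fitted voxels."""

    blood_flow: np.ndarray        # mL/min/100 mL
    volume_fraction: np.ndarray   # mL/100 mL
    mtt: np.ndarray               # s
    err_blood_flow: np.ndarray
    err_volume_fraction: np.ndarray
    err_mtt: np.ndarray
    mtt_unreliable: np.ndarray    # bool: lambda at its lower bound
    provenance: dict[str, Any] = field(default_factory=dict)


def derive_maps(fit_maps: dict[str, np.ndarray],
                provenance: dict[str, Any] | None = None,
                lam_lower_bound: float = 1e-3) -> PerfusionMaps:
    """Convert fitted (A, lambda) maps into perfusion parameter maps.

    Pure per-voxel transform. Error maps are first-order propagations of
    the per-parameter fit errors (covariance neglected). Voxels whose
    washout rate sits at the optimiser's lower bound are flagged: their
    MTT (= 1/lambda) is dominated by the bound, not the data.
    """
    A = np.asarray(fit_maps["A"], dtype=float)
    lam = np.asarray(fit_maps["lam"], dtype=float)
    err_A = np.asarray(fit_maps.get("err_A", np.full_like(A, np.nan)), dtype=float)
    err_lam = np.asarray(fit_maps.get("err_lam", np.full_like(A, np.nan)), dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = 1.0 / lam
        vol = 100.0 * A / lam
        bf = 6000.0 * A
        err_mtt = err_lam / lam ** 2
        err_bf = 6000.0 * err_A
        err_vol = 100.0 * np.sqrt((err_A / lam) ** 2 + (A * err_lam / lam ** 2) ** 2)

    unreliable = np.zeros(A.shape, dtype=bool)
    fitted = np.isfinite(lam)
    unreliable[fitted] = np.isclose(lam[fitted], lam_lower_bound,
                                    rtol=0.0, atol=1e-9)
    return PerfusionMaps(
        blood_flow=bf, volume_fraction=vol, mtt=mtt,
        err_blood_flow=err_bf, err_volume_fraction=err_vol, err_mtt=err_mtt,
        mtt_unreliable=unreliable, provenance=dict(provenance or {}),
    )


def roi_snr(values: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """ROI signal-to-noise ratio: mean over SD of the voxel values.

    Used on a homogeneous blood-pool region at the maximally enhanced
    time point. Returns +inf with a warning when the ROI SD is zero.
    """
    values = np.asarray(values, dtype=float)
    if roi_mask is not None:
        values = values[np.asarray(roi_mask, dtype=bool)]
    values = values.ravel()
    if values.size < 2:
        raise ValueError("ROI must contain at least 2 voxels")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn("constant ROI: SNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return float(np.mean(values)) / sd


@dataclass
class LineProfile:
    """Row-averaged MTT profile through the tissue, top to bottom."""

    distance: np.ndarray   # row index (voxels) or mm if spacing given
    mean_mtt: np.ndarray   # s
    n_averaged: np.ndarray # valid voxels per row


def line_profile(mtt_map: np.ndarray, slice_index: int = 0,
                 spacing_mm: float | None = None) -> LineProfile:
    """Average MTT along image rows of one axial slice.

    Rows are ordered top to bottom; only voxels with a valid positive MTT
    enter the average, and rows without any valid voxel are excluded.
    """
    mtt_map = np.asarray(mtt_map, dtype=float)
    if mtt_map.ndim == 3:
        if not 0 <= slice_index < mtt_map.shape[0]:
            raise IndexError(f"slice {slice_index} outside volume")
        sl = mtt_map[slice_index]
    elif mtt_map.ndim == 2:
        sl = mtt_map
    else:
        raise ValueError("mtt_map must be 2D or 3D")

    valid = np.isfinite(sl) & (sl > 0)
    n_per_row = valid.sum(axis=1)
    rows = np.nonzero(n_per_row > 0)[0]
    if rows.size == 0:
        warnings.warn("no valid MTT voxels: empty profile", RuntimeWarning,
                      stacklevel=2)
        return LineProfile(distance=np.array([]), mean_mtt=np.array([]),
                           n_averaged=np.array([], dtype=int))
    means = np.array([sl[r][valid[r]].mean() for r in rows])
    dist = rows.astype(float)
    if spacing_mm is not None:
        dist = dist * spacing_mm
    return LineProfile(distance=dist, mean_mtt=means,
                       n_averaged=n_per_row[rows].astype(int))


class MTTBandClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-threshold MTT band classifier.

    Assigns each voxel's MTT to one of three perfusion states:
    MTT > thr_high -> highly affected; thr_mod < MTT <= thr_high ->
    moderately affected; 0 < MTT <= thr_mod -> unaffected. Boundary
    values go to the lower (less affected) class. Thresholds default to
    the empirical 2.5 s / 2.0 s separating the phantom's tissue states
    on spectral MTT maps.
    """

    def __init__(self, thr_high: float = 2.5, thr_mod: float = 2.0) -> None:
        self.thr_high = thr_high
        self.thr_mod = thr_mod

    def fit(self, X=None, y=None) -> "MTTBandClassifier":
        if not self.thr_high > self.thr_mod > 0:
            raise ValueError("require thr_high > thr_mod > 0")
        self.classes_ = np.array(
            [int(Region.UNAFFECTED), int(Region.MODERATE), int(Region.HIGHLY)]
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Classify MTT values (any shape); 0 where MTT is invalid."""
        if not hasattr(self, "classes_"):
            self.fit()
        mtt = np.asarray(X, dtype=float)
        out = np.zeros(mtt.shape, dtype=np.uint8)
        valid = np.isfinite(mtt) & (mtt > 0)
        out[valid & (mtt > self.thr_high)] = int(Region.HIGHLY)
        out[valid & (mtt > self.thr_mod) & (mtt <= self.thr_high)] = int(Region.MODERATE)
        out[valid & (mtt <= self.thr_mod)] = int(Region.UNAFFECTED)
        return out


def classify_thresholds(mtt_map: np.ndarray, thr_high: float = 2.5,
                        thr_mod: float = 2.0) -> np.ndarray:
    """Threshold an MTT map into highly / moderately / unaffected classes.

    Thin wrapper over :class:`MTTBandClassifier`; returns Region codes,
    with 0 (background) where MTT is missing or non-positive.
    """
    return MTTBandClassifier(thr_high=thr_high, thr_mod=thr_mod).fit().predict(mtt_map)


def region_stats(value_map: np.ndarray,
                 labels: RegionLabelMap | np.ndarray,
                 regions: tuple[Region, ...] = (Region.HIGHLY,
                                                Region.MODERATE,
                                                Region.UNAFFECTED)) -> pd.DataFrame:
    """Per-region mean, SD and voxel count of a parameter map.

    Population SD (ddof=0), so a single-voxel region reports SD 0.
    Regions with no valid voxels are omitted with a warning; NaN voxels
    are excluded.
    """
    value_map = np.asarray(value_map, dtype=float)
    lab = labels.labels if isinstance(labels, RegionLabelMap) else np.asarray(labels)
    if lab.shape != value_map.shape:
        raise ValueError("labels and map must have the same shape")
    rows = []
    for region in regions:
        vals = value_map[lab == int(region)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"region {region.name} empty; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        sd = float(np.std(vals))
        rows.append({"region": region.name.lower(), "mean": float(vals.mean()),
                     "sd": sd, "n": int(vals.size)})
    return pd.DataFrame(rows, columns=["region", "mean", "sd", "n"])
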