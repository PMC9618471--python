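"""Readers and writers for series, label maps, parameter maps and tables.

Volumetric interchange uses NIfTI (x, y, z, t on disk, converted to the
internal (t, z, y, x) order at the boundary) with frame timestamps in a
JSON sidecar, or a lossless ``.npz`` container. Curves and tables go to
CSV; configuration and reports to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import AIFCurve, RegionLabelMap, TimeSeriesVolume

__all__ = [
    "write_series", "read_series",
    "write_labels", "read_labels",
    "write_maps", "read_maps",
    "write_aif_csv", "read_aif_csv",
    "write_json", "read_json",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(series: TimeSeriesVolume, path: str | Path) -> Path:
    """Write a 4D series as ``.npz`` or NIfTI (+ JSON timestamp sidecar)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path, data=series.data, timestamps=series.timestamps,
            modality=series.modality, units=series.units,
            meta=json.dumps(series.meta),
        )
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(
            np.ascontiguousarray(series.data.transpose(3, 2, 1, 0)), np.eye(4)
        )
        nib.save(img, path)
        sidecar = _sidecar_path(path)
        sidecar.write_text(json.dumps({
            "timestamps": series.timestamps.tolist(),
            "modality": series.modality,
            "units": series.units,
            "meta": series.meta,
        }, indent=2))
        return path
    raise ValueError(f"unrecognised series format: {path.name}")


def read_series(path: str | Path) -> TimeSeriesVolume:
    """Read a series written by :func:`write_series`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["data"]
            if data.ndim != 4:
                raise ValueError(f"expected a 4D series, got ndim={data.ndim}")
            return TimeSeriesVolume(
                data=data, timestamps=z["timestamps"],
                modality=str(z["modality"]), units=str(z["units"]),
                meta=json.loads(str(z["meta"])),
            )
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 4:
            raise ValueError(f"expected a 4D NIfTI series, got ndim={arr.ndim}")
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"timestamp sidecar {sidecar.name} missing next to {path.name}"
            )
        side = json.loads(sidecar.read_text())
        timestamps = np.asarray(side["timestamps"], dtype=float)
        if len(timestamps) != arr.shape[3]:
            raise ValueError(
                f"sidecar has {len(timestamps)} timestamps but the series "
                f"has {arr.shape[3]} frames"
            )
        return TimeSeriesVolume(
            data=arr.transpose(3, 2, 1, 0), timestamps=timestamps,
            modality=side["modality"], units=side.get("units", ""),
            meta=side.get("meta", {}),
        )
    raise ValueError(f"unrecognised series format: {path.name}")


def write_labels(labels: RegionLabelMap, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, labels=labels.labels)
        return path
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(
            np.ascontiguousarray(labels.labels.transpose(2, 1, 0)), np.eye(4),
            dtype=np.uint8,
        )
        nib.save(img, path)
        return path
    raise ValueError(f"unrecognised label format: {path.name}")


def read_labels(path: str | Path) -> RegionLabelMap:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return RegionLabelMap(labels=z["labels"])
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D label map, got ndim={arr.ndim}")
    return RegionLabelMap(labels=arr.transpose(2, 1, 0))


def write_maps(maps: dict[str, np.ndarray], path: str | Path,
               meta: dict[str, Any] | None = None) -> Path:
    """Write a dict of (z, y, x) maps as a multi-array ``.npz``."""
    path = Path(path)
    payload = {k: np.asarray(v) for k, v in maps.items()}
    payload["__meta__"] = np.array(json.dumps(meta or {}))
    np.savez(path, **payload)
    return path


def read_maps(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, Any]]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"])) if "__meta__" in z else {}
        maps = {k: z[k] for k in z.files if k != "__meta__"}
    return maps, meta


def write_aif_csv(aif: AIFCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": aif.times, "value": aif.values}).to_csv(
        path, index=False
    )
    return path


def read_aif_csv(path: str | Path, source: str = "csv") -> AIFCurve:
    df = pd.read_csv(path)
    return AIFCurve(times=df["time_s"].to_numpy(),
                    values=df["value"].to_numpy(), source=source)


def write_json(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))
    return path


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
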