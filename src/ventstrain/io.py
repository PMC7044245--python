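"""File IO: MetaImage/NIfTI volumes and vector fields, waveform CSV, JSON.

Volumes are stored with axis order (right-left, dorsal-ventral,
caudal-rostral) and world coordinate = index * spacing.  SimpleITK handles
the on-disk formats; arrays round-trip bit-exactly including spacing.
Waveforms are CSV with columns ``time_s, paw_cmH2O, flow_Lps, vol_L`` plus a
JSON sidecar carrying modality, f0 and sampling rate.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .ventgas import WaveformRecord

SUPPORTED_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")

WAVEFORM_COLUMNS = ["time_s", "paw_cmH2O", "flow_Lps", "vol_L"]


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported volume format {path.name!r}; use one of "
            f"{SUPPORTED_SUFFIXES}"
        )


def write_volume(path, array: np.ndarray, spacing) -> None:
    """Write a scalar volume or a 3-component displacement field."""
    path = Path(path)
    _check_suffix(path)
    array = np.asarray(array)
    spacing = np.asarray(spacing, dtype=float)
    if array.ndim == 4:
        if array.shape[-1] != 3:
            raise ValueError("vector fields must have 3 components")
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(array, (2, 1, 0, 3))), isVector=True
        )
    elif array.ndim == 3:
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(array, (2, 1, 0))))
    else:
        raise ValueError("array must be 3D scalar or 3D + 3-component vector")
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def read_volume(path):
    """Read a volume; returns ``(array, spacing)``.

    Scalar images come back as (nx, ny, nz); vector fields as
    (nx, ny, nz, 3).  Files with a component count other than 1 or 3 are
    rejected.
    """
    path = Path(path)
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    ncomp = img.GetNumberOfComponentsPerPixel()
    arr = sitk.GetArrayFromImage(img)
    if ncomp == 1:
        arr = np.transpose(arr, (2, 1, 0))
    elif ncomp == 3:
        arr = np.transpose(arr, (2, 1, 0, 3))
    else:
        raise ValueError(f"{path.name}: {ncomp}-component images are not supported")
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    return arr, spacing


def check_matching_spacing(spacing_a, spacing_b, what="paired volumes") -> None:
    if not np.allclose(spacing_a, spacing_b, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{what} have mismatched spacing: {spacing_a} vs {spacing_b}")


def write_waveform(path, record: WaveformRecord) -> None:
    """Waveform CSV plus a JSON metadata sidecar (same stem, .json)."""
    path = Path(path)
    df = pd.DataFrame(
        dict(zip(WAVEFORM_COLUMNS, [record.time, record.paw, record.flow, record.volume]))
    )
    df.to_csv(path, index=False)
    meta = {"modality": record.modality, "f0_hz": record.f0, "fs_hz": record.fs}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_waveform(path) -> WaveformRecord:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform CSV missing columns {sorted(missing)}")
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        dt = float(np.median(np.diff(df["time_s"])))
        meta = {"modality": "CMV", "f0_hz": np.nan, "fs_hz": 1.0 / dt}
    return WaveformRecord(
        time=df["time_s"].to_numpy(),
        paw=df["paw_cmH2O"].to_numpy(),
        flow=df["flow_Lps"].to_numpy(),
        volume=df["vol_L"].to_numpy(),
        modality=meta["modality"],
        f0=meta["f0_hz"],
        fs=meta["fs_hz"],
    )


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
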