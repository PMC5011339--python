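"""On-disk formats: NIfTI frame series, sonication logs, provenance.

A frame series is a directory holding paired magnitude and phase NIfTI
stacks (x, y, frame) plus a JSON sidecar carrying the acquisition metadata
(TE, field strength, FOV, frame period, dummy-frame count, timestamps).
This replaces scanner-proprietary raw formats with standard neuroimaging
containers; a vendor raw-file reader would slot in behind the same
``read_frame_series`` interface.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__ as _version
from .controller import SonicationLog
from .thermometry import ComplexFrame, TemperatureMap

SIDECAR_NAME = "series.json"
MAGNITUDE_NAME = "magnitude.nii.gz"
PHASE_NAME = "phase.nii.gz"


def write_frame_series(frames: list[ComplexFrame], path: str | Path) -> Path:
    """Write a frame series (magnitude + phase stacks + JSON sidecar)."""
    if not frames:
        raise ValueError("no frames to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    first = frames[0]
    for f in frames:
        if f.data.shape != first.data.shape:
            raise ValueError("frames in a series must share one shape")
        if f.te_s != first.te_s or f.b0_T != first.b0_T or f.fov_mm != first.fov_mm:
            raise ValueError("frames in a series must share acquisition metadata")
    mag = np.stack([np.abs(f.data) for f in frames], axis=-1)
    phase = np.stack([np.angle(f.data) for f in frames], axis=-1)
    px = first.pixel_mm
    affine = np.diag([px[0], px[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(mag.astype(np.float64), affine), path / MAGNITUDE_NAME)
    nib.save(nib.Nifti1Image(phase.astype(np.float64), affine), path / PHASE_NAME)
    sidecar = {
        "te_s": first.te_s,
        "b0_T": first.b0_T,
        "fov_mm": list(first.fov_mm),
        "timestamps_s": [f.timestamp_s for f in frames],
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return path


def read_frame_series(path: str | Path) -> list[ComplexFrame]:
    """Read a frame series back, sorted by timestamp."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    mag = np.asarray(nib.load(path / MAGNITUDE_NAME).dataobj, dtype=np.float64)
    phase = np.asarray(nib.load(path / PHASE_NAME).dataobj, dtype=np.float64)
    if mag.shape != phase.shape:
        raise ValueError("magnitude and phase stacks have different shapes")
    timestamps = sidecar["timestamps_s"]
    if mag.shape[-1] != len(timestamps):
        raise ValueError("sidecar timestamp count does not match the stacks")
    frames = [
        ComplexFrame(
            data=mag[..., i] * np.exp(1j * phase[..., i]),
            te_s=sidecar["te_s"],
            timestamp_s=timestamps[i],
            b0_T=sidecar["b0_T"],
            fov_mm=tuple(sidecar["fov_mm"]),
        )
        for i in range(len(timestamps))
    ]
    frames.sort(key=lambda f: f.timestamp_s)
    return frames


def write_sonication_log(log: SonicationLog, path: str | Path) -> Path:
    """Write the per-frame treatment record as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    log.to_dataframe().to_csv(path, index=False)
    return path


def read_sonication_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SonicationLog.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"log is missing columns: {sorted(missing)}")
    return df


def write_temperature_stack(
    tmaps: list[TemperatureMap],
    path: str | Path,
    focal_means_C: list[float] | None = None,
    drift_ref_means_C: list[float] | None = None,
) -> Path:
    """Write temperature maps as a NIfTI stack plus a CSV time series."""
    if not tmaps:
        raise ValueError("no temperature maps to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stack = np.stack([m.delta_T_C for m in tmaps], axis=-1)
    masks = np.stack([m.mask for m in tmaps], axis=-1)
    nib.save(nib.Nifti1Image(stack.astype(np.float64), np.eye(4)), path / "delta_T.nii.gz")
    nib.save(nib.Nifti1Image(masks.astype(np.uint8), np.eye(4)), path / "mask.nii.gz")
    table = {"timestamp_s": [m.timestamp_s for m in tmaps]}
    if focal_means_C is not None:
        table["focal_mean_C"] = focal_means_C
    if drift_ref_means_C is not None:
        table["drift_ref_mean_C"] = drift_ref_means_C
    pd.DataFrame(table).to_csv(path / "timeseries.csv", index=False)
    return path


def write_provenance(path: str | Path, config_echo: dict, seed: int) -> Path:
    """Machine-readable run record: config echo, seed, package version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record = {"package": "mrgfus", "version": _version, "seed": seed, "config": config_echo}
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
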