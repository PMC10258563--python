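"""NIfTI-1 volume I/O with CSV sidecar metadata.

Volumes are stored as NIfTI (3D for one trial, 4D for a trial stack) with
an identity affine in voxel units; the brain mask travels in a companion
``<stem>_mask.nii`` file and the trial metadata (trial_id, subject_id,
run_id, label) in a ``<stem>.csv`` sidecar, one row per trial in stack
order.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import TrialVolume

__all__ = ["write_volume", "read_volume", "write_trials", "read_trials"]


def _stem(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path.with_suffix("")


def _mask_path(path: Path) -> Path:
    return _stem(path).with_name(_stem(path).name + "_mask.nii")


def _sidecar_path(path: Path) -> Path:
    return _stem(path).with_suffix(".csv")


def write_trials(trials: list[TrialVolume], path) -> None:
    """Write a trial stack as 4D NIfTI + mask + CSV sidecar."""
    path = Path(path)
    data = np.stack([t.values for t in trials], axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    mask = trials[0].mask.astype(np.uint8)
    nib.save(nib.Nifti1Image(mask, np.eye(4)), str(_mask_path(path)))
    pd.DataFrame([{"trial_id": t.trial_id, "subject_id": t.subject_id,
                   "run_id": t.run_id, "label": t.label} for t in trials]
                 ).to_csv(_sidecar_path(path), index=False)


def write_volume(vol: TrialVolume, path) -> None:
    """Write a single trial volume (3D NIfTI + mask + sidecar row)."""
    write_trials([vol], path)


def _load_nifti(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        return np.asarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ValueError(f"could not parse NIfTI file {path}: {exc}") from exc


def read_trials(path) -> list[TrialVolume]:
    """Read a 3D/4D NIfTI (+ mask + sidecar) back into TrialVolumes."""
    path = Path(path)
    data = np.asarray(_load_nifti(path), dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"expected 3D or 4D volume, got shape {data.shape}")
    mask_file = _mask_path(path)
    if mask_file.exists():
        mask = _load_nifti(mask_file).astype(bool)
    else:
        mask = np.any(data != 0, axis=-1)
    if mask.shape != data.shape[:3]:
        raise ValueError(f"mask grid {mask.shape} does not match volume grid {data.shape[:3]}")
    n = data.shape[-1]
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = pd.read_csv(sidecar, dtype=str)
        if len(meta) != n:
            raise ValueError(f"sidecar has {len(meta)} rows for {n} volumes")
    else:
        meta = pd.DataFrame({"trial_id": [f"trial{i:05d}" for i in range(n)],
                             "subject_id": ["sub01"] * n,
                             "run_id": ["run01"] * n,
                             "label": ["unknown"] * n})
    out = []
    for i in range(n):
        values = data[..., i]
        values = np.where(mask, values, 0.0)
        row = meta.iloc[i]
        out.append(TrialVolume(values=values, mask=mask, label=row["label"],
                               subject_id=row["subject_id"], run_id=row["run_id"],
                               trial_id=row["trial_id"]))
    return out


def read_volume(path) -> TrialVolume:
    """Read a single trial volume; errors if the file holds several."""
    trials = read_trials(path)
    if len(trials) != 1:
        raise ValueError(f"{path} holds {len(trials)} volumes; use read_trials")
    return trials[0]


def write_map(volume: np.ndarray, path) -> None:
    """Write a bare statistic/relevance volume as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)), str(path))


def read_map(path) -> np.ndarray:
    return np.asarray(_load_nifti(Path(path)), dtype=np.float64)
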