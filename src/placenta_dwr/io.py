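"""NIfTI and table I/O shared by the pipeline stages.

Volumes travel as NIfTI-1 with their affine preserved; parameter maps
are written float32.  Cohort tables are TSV with one row per subject
(columns: subject_id, group, ga_onset, ga_mri, ga_delivery,
latency_days, then one column per ROI-mean parameter).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import SubjectRecord

__all__ = [
    "read_nifti_4d",
    "read_nifti_3d",
    "write_nifti_map",
    "write_cohort_table",
    "read_cohort_table",
    "write_manifest",
]

_META_COLUMNS = ["subject_id", "group", "ga_onset", "ga_mri", "ga_delivery", "latency_days"]


def read_nifti_4d(path, n_volumes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D NIfTI volume; returns (data, affine).

    ``n_volumes`` cross-checks the 4th dimension against the sidecar
    length before any fitting happens.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    if n_volumes is not None and data.shape[3] != n_volumes:
        raise ValueError(
            f"{path}: 4th dimension is {data.shape[3]} but the scheme has {n_volumes} measurements"
        )
    return data, img.affine


def read_nifti_3d(path, as_bool: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume (e.g. a parenchyma mask)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if as_bool:
        data = data > 0.5
    return data, img.affine


def write_nifti_map(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a parameter map (or 4D stack) as float32 NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def write_cohort_table(records, path) -> pd.DataFrame:
    """Write subject records (with ROI means) to TSV; returns the frame."""
    from .cohort import cohort_frame

    df = cohort_frame(records)
    ordered = _META_COLUMNS + [c for c in df.columns if c not in _META_COLUMNS]
    df = df[[c for c in ordered if c in df.columns]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return df


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read a TSV cohort table back into subject records."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", "group", "ga_mri", "ga_delivery") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        params = {
            c: float(row[c])
            for c in df.columns
            if c not in _META_COLUMNS and pd.notna(row[c])
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                ga_mri=float(row["ga_mri"]),
                ga_delivery=float(row["ga_delivery"]),
                ga_onset=float(row["ga_onset"]) if pd.notna(row.get("ga_onset")) else None,
                latency_days=float(row["latency_days"]) if pd.notna(row.get("latency_days")) else None,
                roi_means=params,
            )
        )
    return records


def write_manifest(path, **entries) -> None:
    """Write a JSON manifest (config, seeds, versions) for reproducibility."""
    import placenta_dwr

    payload = {"package_version": placenta_dwr.__version__}
    payload.update(entries)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
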