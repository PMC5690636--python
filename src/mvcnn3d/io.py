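"""Reading nodule stacks from disk and persisting prepared sample archives.

The on-disk input is a per-slice manifest CSV with columns

    patient_id, nodule_id, center_row, center_col, nodule_diag, patient_diag

plus either ``slice_path`` (one 2D image per row: DICOM ``.dcm`` via
pydicom, NIfTI ``.nii``/``.nii.gz`` via nibabel, or ``.npy``) or
``volume_path`` + ``slice_index`` (a 3D NIfTI per nodule, 0-based slice
index along the last axis).  Coordinates are 0-based; slices are ordered by
ascending ``slice_index`` (ascending axial position).

Prepared samples are stored as a compressed ``.npz`` tensor container next
to a ``samples.csv`` listing sample id, patient, label and rotation angle.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .dataprep import NoduleStack, VolumeSample

__all__ = [
    "load_manifest",
    "load_stacks",
    "write_cohort",
    "save_samples",
    "load_samples",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "nodule_id",
    "center_row",
    "center_col",
    "nodule_diag",
    "patient_diag",
]


def load_manifest(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str, "nodule_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    if "slice_path" not in df.columns and not {
        "volume_path",
        "slice_index",
    }.issubset(df.columns):
        raise ValueError("manifest needs slice_path or volume_path+slice_index")
    return df


def _read_slice(path: str) -> np.ndarray:
    ext = path.lower()
    if ext.endswith(".dcm"):
        import pydicom

        return pydicom.dcmread(path).pixel_array.astype(np.float32)
    if ext.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(path).dataobj).astype(np.float32)
        return np.squeeze(arr)
    if ext.endswith(".npy"):
        return np.load(path).astype(np.float32)
    raise ValueError(f"unsupported slice format: {path}")


def load_stacks(manifest, base_dir: str | None = None) -> list[NoduleStack]:
    """NoduleStack list from a manifest DataFrame or CSV path."""
    if not isinstance(manifest, pd.DataFrame):
        base_dir = base_dir or os.path.dirname(os.path.abspath(manifest))
        manifest = load_manifest(manifest)
    base_dir = base_dir or "."
    volumes: dict[str, np.ndarray] = {}
    stacks = []
    for nodule_id, grp in manifest.groupby("nodule_id", sort=True):
        if "slice_index" in grp.columns:
            grp = grp.sort_values("slice_index")
        first = grp.iloc[0]
        slices = []
        for _, row in grp.iterrows():
            if "slice_path" in grp.columns and isinstance(row.get("slice_path"), str):
                slices.append(_read_slice(os.path.join(base_dir, row["slice_path"])))
            else:
                vp = os.path.join(base_dir, str(row["volume_path"]))
                if vp not in volumes:
                    import nibabel as nib

                    volumes[vp] = np.asanyarray(nib.load(vp).dataobj).astype(np.float32)
                slices.append(volumes[vp][..., int(row["slice_index"])])
        stacks.append(
            NoduleStack(
                patient_id=str(first["patient_id"]),
                nodule_id=str(nodule_id),
                slices=slices,
                center=(int(first["center_row"]), int(first["center_col"])),
                nodule_diag=int(first["nodule_diag"]),
                patient_diag=int(first["patient_diag"]),
            )
        )
    return stacks


def write_cohort(stacks, out_dir) -> str:
    """Write stacks as per-nodule 3D NIfTI volumes plus ``manifest.csv``.

    Returns the manifest path; the layout round-trips through
    ``load_stacks``.
    """
    import nibabel as nib

    from .synthetic import cohort_manifest

    os.makedirs(out_dir, exist_ok=True)
    vol_dir = os.path.join(out_dir, "volumes")
    os.makedirs(vol_dir, exist_ok=True)
    paths = {}
    for stack in stacks:
        vol = np.stack(stack.slices, axis=-1)  # (M, N, Z): slice axis last
        rel = os.path.join("volumes", f"{stack.nodule_id}.nii.gz")
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), os.path.join(out_dir, rel))
        paths[stack.nodule_id] = rel
    manifest = cohort_manifest(stacks, volume_paths=paths)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def save_samples(samples, path) -> str:
    """Compressed archive of prepared samples plus a sibling samples.csv."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    data = np.stack([s.data for s in samples]).astype(np.float32)
    np.savez_compressed(
        path,
        data=data,
        label=np.array([s.label for s in samples], dtype=np.int64),
        patient_id=np.array([s.patient_id for s in samples]),
        nodule_id=np.array([s.nodule_id for s in samples]),
        rotation_deg=np.array([s.rotation_deg for s in samples], dtype=np.float64),
    )
    table = pd.DataFrame(
        {
            "sample_id": np.arange(len(samples)),
            "patient_id": [s.patient_id for s in samples],
            "nodule_id": [s.nodule_id for s in samples],
            "label": [s.label for s in samples],
            "rotation_deg": [s.rotation_deg for s in samples],
        }
    )
    table.to_csv(os.path.splitext(path)[0] + ".csv", index=False)
    return path


def load_samples(path) -> list[VolumeSample]:
    with np.load(path, allow_pickle=False) as z:
        return [
            VolumeSample(
                data=z["data"][i],
                label=int(z["label"][i]),
                patient_id=str(z["patient_id"][i]),
                nodule_id=str(z["nodule_id"][i]),
                rotation_deg=float(z["rotation_deg"][i]),
            )
            for i in range(z["data"].shape[0])
        ]
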