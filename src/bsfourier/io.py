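"""File formats: vector fields (MetaImage / NIfTI), manifests, landmark CSV.

Conventions: in-memory arrays are indexed ``(i, j, k)`` along the physical
x, y, z axes with geometry given by per-axis spacing and origin (mm);
world coordinates are ``origin + index * spacing``.  Only axis-aligned
geometries are supported.  Pair labels ``(t_from, t_to)``, weights and
roles travel in a JSON manifest next to the field files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .evaluation import LandmarkTracks
from .fields import DisplacementField, RegistrationSet

__all__ = [
    "read_field",
    "write_field",
    "read_registration_set",
    "write_registration_set",
    "read_landmarks",
    "write_tracks",
    "read_mask",
    "write_mask",
]


def write_field(field: DisplacementField, path) -> None:
    """Write a displacement field as a 3-component vector image
    (.mhd/.raw MetaImage or .nii/.nii.gz NIfTI, by extension)."""
    path = str(path)
    if path.endswith(".mhd"):
        import SimpleITK as sitk

        # SimpleITK arrays are (z, y, x, c)
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(field.vectors.transpose(2, 1, 0, 3)),
            isVector=True,
        )
        img.SetSpacing(tuple(field.spacing))
        img.SetOrigin(tuple(field.origin))
        sitk.WriteImage(img, path)
    elif path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(field.spacing)
        affine[:3, 3] = field.origin
        nib.save(nib.Nifti1Image(field.vectors, affine), path)
    else:
        raise FormatError(f"unsupported vector-image extension: {path}")


def _read_vectors(path):
    path = str(path)
    if path.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        if img.GetNumberOfComponentsPerPixel() != 3:
            raise FormatError(
                f"{path}: expected 3 vector components, "
                f"got {img.GetNumberOfComponentsPerPixel()}"
            )
        vectors = sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3)
        return vectors, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin())
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        vectors = np.asarray(img.dataobj)
        if vectors.ndim != 4 or vectors.shape[3] != 3:
            raise FormatError(f"{path}: expected an (nx, ny, nz, 3) vector image")
        aff = img.affine
        if np.any(np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))) > 1e-9):
            raise FormatError(f"{path}: only axis-aligned affines are supported")
        return vectors, np.diag(aff[:3, :3]).copy(), aff[:3, 3].copy()
    raise FormatError(f"unsupported vector-image extension: {path}")


def read_field(path, t_from: int, t_to: int, weight: float = 1.0,
               role=None) -> DisplacementField:
    vectors, spacing, origin = _read_vectors(path)
    return DisplacementField(vectors, t_from=t_from, t_to=t_to, weight=weight,
                             spacing=spacing, origin=origin, role=role)


def write_registration_set(reg: RegistrationSet, out_dir,
                           fmt: str = "mhd") -> Path:
    """Write every field plus the JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for f in reg:
        name = f"field_{f.t_from:03d}_{f.t_to:03d}"
        if f.role:
            name += f"_{f.role}"
        ext = ".mhd" if fmt == "mhd" else ".nii.gz"
        write_field(f, out_dir / (name + ext))
        entries.append({
            "path": name + ext,
            "t_from": int(f.t_from),
            "t_to": int(f.t_to),
            "weight": float(f.weight),
            "role": f.role,
        })
    manifest = {"period": int(reg.period), "fields": entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_registration_set(manifest_path) -> RegistrationSet:
    manifest_path = Path(manifest_path)
    try:
        manifest = json.loads(manifest_path.read_text())
    except FileNotFoundError as e:
        raise FormatError(f"manifest not found: {manifest_path}") from e
    if "period" not in manifest or "fields" not in manifest:
        raise FormatError(f"{manifest_path}: manifest needs 'period' and 'fields'")
    fields = []
    for entry in manifest["fields"]:
        for key in ("path", "t_from", "t_to"):
            if key not in entry:
                raise FormatError(
                    f"{manifest_path}: manifest entry missing {key!r}: {entry}"
                )
        fields.append(read_field(
            manifest_path.parent / entry["path"],
            t_from=entry["t_from"], t_to=entry["t_to"],
            weight=entry.get("weight", 1.0), role=entry.get("role"),
        ))
    return RegistrationSet(fields, manifest["period"])


def write_tracks(tracks, path) -> None:
    """Landmark tracks as tidy CSV: id, frame, x, y, z."""
    pos = tracks.positions if isinstance(tracks, LandmarkTracks) else np.asarray(tracks)
    n, P, _ = pos.shape
    df = pd.DataFrame({
        "id": np.repeat(np.arange(n), P),
        "frame": np.tile(np.arange(P), n),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
        "z": pos[:, :, 2].ravel(),
    })
    df.to_csv(path, index=False)


def read_landmarks(path) -> np.ndarray:
    """Read a tracks CSV back into an (n, frames, 3) array.

    A CSV with a single frame per id yields (n, 1, 3) (seed landmarks).
    """
    df = pd.read_csv(path)
    for col in ("id", "frame", "x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: landmarks CSV needs column {col!r}")
    df = df.sort_values(["id", "frame"])
    ids = df["id"].unique()
    P = df["frame"].nunique()
    if len(df) != len(ids) * P:
        raise FormatError(f"{path}: landmark frames are not aligned across ids")
    return df[["x", "y", "z"]].to_numpy().reshape(len(ids), P, 3)


def write_mask(mask, path, spacing=(1, 1, 1), origin=(0, 0, 0)) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj) > 0
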