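"""Reading and writing label volumes and tabular artifacts.

Coordinate contract used throughout the package:

* voxel indices are 0-based and address voxel *centers*;
* the world coordinate (mm) of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing``;
* axis 0 is left-right, axis 1 anterior-posterior and axis 2 points
  superior (toward the glenoid fossa) unless a volume declares otherwise
  via ``axes_superior``.

Label volumes hold exactly three integer values: 0 background, 1 condyle,
2 fossa.  One volume describes one temporomandibular joint (a condyle/fossa
pair already localised by an upstream segmentation step).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BACKGROUND = 0
CONDYLE = 1
FOSSA = 2
_VALID_LABELS = frozenset({BACKGROUND, CONDYLE, FOSSA})

NIFTI_SUFFIXES = (".nii", ".nii.gz")
SITK_SUFFIXES = (".nrrd", ".mha", ".mhd")


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a supported label-volume format."""


class LabelValidationError(ValueError):
    """Raised when voxel values fall outside the {0, 1, 2} label alphabet."""


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical spacing and origin (mm)."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes_superior: int = 2

    def __post_init__(self) -> None:
        self.voxels = np.ascontiguousarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D voxel array, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise LabelValidationError(
                f"voxel dtype must be integer, got {self.voxels.dtype}"
            )
        bad = np.setdiff1d(np.unique(self.voxels), sorted(_VALID_LABELS))
        if bad.size:
            raise LabelValidationError(
                f"voxel value {int(bad[0])} outside the label alphabet {{0, 1, 2}}"
            )
        self.voxels = self.voxels.astype(np.uint8, copy=False)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if self.axes_superior not in (0, 1, 2):
            raise ValueError("axes_superior must be 0, 1 or 2")
        self._centroid_cache: Optional[np.ndarray] = None

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def world_from_index(self, index: Sequence[float]) -> np.ndarray:
        """World (mm) coordinate of a (possibly fractional) voxel index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index_from_world(self, point: Sequence[float]) -> np.ndarray:
        """Continuous voxel index of a world point (inverse of world_from_index)."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def contains_world(self, point: Sequence[float]) -> bool:
        """True if the world point falls inside the voxel grid extent."""
        idx = self.index_from_world(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))


@dataclass
class JointRecord:
    """Bookkeeping for one joint in a dataset manifest."""

    joint_id: str
    side: str  # "left" | "right"
    volume_path: str = ""
    label: Optional[str] = None  # "correct" | "incorrect"
    provenance: str = "clinical"  # "clinical" | "synthetic" | "mirrored"
    source_joint_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.label not in (None, "correct", "incorrect"):
            raise ValueError(f"invalid label {self.label!r}")
        if self.provenance == "mirrored" and not self.source_joint_id:
            raise ValueError("mirrored records must reference their source joint_id")


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a NIfTI / NRRD / MetaImage file into a :class:`LabelVolume`.

    Spacing and origin come from the file header.  The volume must be
    axis-aligned (no oblique direction matrix); voxel values are validated
    against the {0, 1, 2} label alphabet.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = path.lower()
    if lower.endswith(NIFTI_SUFFIXES):
        return _read_nifti(path)
    if lower.endswith(SITK_SUFFIXES):
        return _read_sitk(path)
    raise VolumeFormatError(
        f"unsupported volume format for {path!r}; expected one of "
        f"{NIFTI_SUFFIXES + SITK_SUFFIXES}"
    )


def write_label_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write a :class:`LabelVolume` to NIfTI / NRRD / MetaImage by extension."""
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith(NIFTI_SUFFIXES):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(volume.spacing)
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
        img.header.set_zooms(tuple(volume.spacing))
        nib.save(img, path)
    elif lower.endswith(SITK_SUFFIXES):
        import SimpleITK as sitk

        # SimpleITK arrays are indexed [k, j, i]
        img = sitk.GetImageFromArray(volume.voxels.astype(np.uint8).transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        img.SetOrigin(tuple(float(o) for o in volume.origin))
        sitk.WriteImage(img, path)
    else:
        raise VolumeFormatError(f"unsupported volume format for {path!r}")


def _read_nifti(path: str) -> LabelVolume:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error surface varies
        raise VolumeFormatError(f"cannot read {path!r} as NIfTI: {exc}") from exc
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise VolumeFormatError(
            f"{path!r} has an oblique affine; only axis-aligned volumes are supported"
        )
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise LabelValidationError(f"{path!r} holds non-integer voxel values")
        data = np.round(data).astype(np.int64)
    spacing = np.abs(np.diag(rot))
    return LabelVolume(voxels=data, spacing=spacing, origin=affine[:3, 3].copy())


def _read_sitk(path: str) -> LabelVolume:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(path)
    except Exception as exc:
        raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            f"{path!r} has a non-identity direction matrix; only axis-aligned "
            "volumes are supported"
        )
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if not np.issubdtype(data.dtype, np.integer):
        raise LabelValidationError(f"{path!r} holds non-integer voxel values")
    return LabelVolume(
        voxels=data,
        spacing=np.array(img.GetSpacing(), dtype=float),
        origin=np.array(img.GetOrigin(), dtype=float),
    )


# ---------------------------------------------------------------------------
# Feature tables


def write_features(features, path: str | os.PathLike) -> None:
    """Write ray-feature vectors to CSV.

    Columns: ``joint_id, label, ray_000..ray_{N-1}, imputed_000..imputed_{N-1}``.
    All vectors must share the same length N.
    """
    features = list(features)
    if not features:
        raise ValueError("no feature vectors to write")
    n = len(features[0].distances)
    for fv in features:
        if len(fv.distances) != n:
            raise ValueError(
                f"ragged feature lengths: {len(fv.distances)} != {n} "
                f"(joint {fv.joint_id})"
            )
    rows = []
    for fv in features:
        row = {"joint_id": fv.joint_id, "label": getattr(fv, "label", None)}
        row.update({f"ray_{i:03d}": fv.distances[i] for i in range(n)})
        row.update({f"imputed_{i:03d}": int(fv.imputed[i]) for i in range(n)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | os.PathLike):
    """Read a feature CSV back to ``(joint_ids, labels, X, imputed)`` arrays."""
    df = pd.read_csv(path)
    ray_cols = sorted(c for c in df.columns if c.startswith("ray_"))
    imp_cols = sorted(c for c in df.columns if c.startswith("imputed_"))
    joint_ids = df["joint_id"].astype(str).to_list()
    labels = [None if pd.isna(v) else str(v) for v in df["label"]]
    return joint_ids, labels, df[ray_cols].to_numpy(float), df[imp_cols].to_numpy(bool)


# ---------------------------------------------------------------------------
# Dataset manifests

MANIFEST_COLUMNS = ["joint_id", "side", "volume_path", "label", "provenance"]


def write_manifest(records: Sequence[JointRecord], path: str | os.PathLike) -> None:
    rows = [
        {k: getattr(r, k) for k in MANIFEST_COLUMNS} | {"source_joint_id": r.source_joint_id}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str | os.PathLike) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            JointRecord(
                joint_id=str(row["joint_id"]),
                side=str(row["side"]),
                volume_path="" if pd.isna(row["volume_path"]) else str(row["volume_path"]),
                label=None if pd.isna(row["label"]) else str(row["label"]),
                provenance=str(row["provenance"]),
                source_joint_id=None
                if "source_joint_id" not in df.columns or pd.isna(row.get("source_joint_id"))
                else str(row["source_joint_id"]),
            )
        )
    ids = [r.joint_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate joint_id in manifest")
    return records
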