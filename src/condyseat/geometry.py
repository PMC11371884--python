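"""Hemisphere direction sets, condyle centroids and rigid perturbations.

The ray directions emulate the vertices of a reference hemi-icosphere of
radius 1 mm placed at the condyle centroid: N quasi-uniform unit vectors on
the superior hemisphere (the fossa lies superior to the condyle, so rays are
cast upward into the joint space).  The default construction is a spherical
Fibonacci lattice restricted to the hemisphere, which realises any vertex
count exactly — the count fixes the classifier input width, so it must be
hit exactly.  A clipped subdivided-icosahedron alternative is available for
fidelity experiments but only realises particular counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import CONDYLE, LabelVolume

DEFAULT_N_DIRECTIONS = 198
GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))  # 2*pi / phi**2

SUPERIOR_AXIS = 2
LATERAL_AXIS = 0


@dataclass(frozen=True)
class DirectionSet:
    """N unit vectors on the superior hemisphere."""

    directions: np.ndarray  # (n, 3), unit rows
    reference_radius_mm: float = 1.0  # scale-only; rays depend on direction alone
    construction: str = "fibonacci_hemisphere"

    @property
    def n(self) -> int:
        return self.directions.shape[0]

    def mirrored(self, lateral_axis: int = LATERAL_AXIS) -> "DirectionSet":
        """The left-right mirrored direction set (lateral components negated)."""
        d = self.directions.copy()
        d[:, lateral_axis] = -d[:, lateral_axis]
        return DirectionSet(d, self.reference_radius_mm, self.construction)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.directions, delimiter=",", fmt="%.17g")


@dataclass(frozen=True)
class RigidPerturbation:
    """A small rigid motion of the ray origin and directions.

    ``translation`` in mm, ``rotation_deg`` as extrinsic Euler angles about
    the x, y and z world axes, applied in the order X then Y then Z.
    """

    translation: tuple = (0.0, 0.0, 0.0)
    rotation_deg: tuple = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @property
    def is_identity(self) -> bool:
        return not (any(self.translation) or any(self.rotation_deg))

    def inverse(self) -> "RigidPerturbation":
        rot = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        inv = rot.inv().as_euler("xyz", degrees=True)
        # Inverse of (rotate, translate) as an independent pair; exact when
        # composed back because directions and origin transform independently.
        return RigidPerturbation(
            translation=tuple(-t for t in self.translation),
            rotation_deg=tuple(inv),
        )


IMPLEMENTED_CONSTRUCTIONS = ("fibonacci_hemisphere", "clipped_icosphere")


def build_direction_set(
    n: int = DEFAULT_N_DIRECTIONS,
    construction: str = "fibonacci_hemisphere",
    reference_radius_mm: float = 1.0,
) -> DirectionSet:
    """Build ``n`` quasi-uniform unit directions on the superior hemisphere.

    Deterministic for fixed ``(n, construction)``.  ``fibonacci_hemisphere``
    realises any n >= 1 (n = 1 degenerates to the superior axis);
    ``clipped_icosphere`` only realises the vertex counts of clipped
    subdivided icosahedra and raises otherwise, naming achievable counts.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if construction == "fibonacci_hemisphere":
        dirs = _fibonacci_hemisphere(n)
    elif construction == "clipped_icosphere":
        dirs = _clipped_icosphere(n)
    else:
        raise ValueError(
            f"unknown construction {construction!r}; choose from {IMPLEMENTED_CONSTRUCTIONS}"
        )
    return DirectionSet(dirs, reference_radius_mm, construction)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    z = 1.0 - i / n  # in (0, 1]; i = 0 is the exact superior pole
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = i * GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs.flags.writeable = False
    return dirs


def _clipped_icosphere(n: int) -> np.ndarray:
    import trimesh

    achievable = {}
    for subdiv in range(7):
        verts = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0).vertices
        kept = verts[verts[:, SUPERIOR_AXIS] >= -1e-9]
        achievable[len(kept)] = kept
    if n not in achievable:
        raise ValueError(
            f"clipped_icosphere cannot realise n={n}; achievable counts: "
            f"{sorted(achievable)}"
        )
    dirs = np.asarray(achievable[n], dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # stable deterministic order: superior component desc, then x, then y
    order = np.lexsort((dirs[:, 1], dirs[:, 0], -dirs[:, 2]))
    dirs = np.ascontiguousarray(dirs[order])
    dirs.flags.writeable = False
    return dirs


def condyle_centroid(volume: LabelVolume) -> np.ndarray:
    """World-coordinate (mm) centroid of the condyle-labelled voxel centers."""
    cached = getattr(volume, "_centroid_cache", None)
    if cached is not None:
        return cached
    idx = np.argwhere(volume.voxels == CONDYLE)
    if idx.size == 0:
        raise ValueError("no condyle voxels")
    centroid = volume.origin + idx.mean(axis=0) * volume.spacing
    volume._centroid_cache = centroid
    return centroid


def perturb(
    ds: DirectionSet, origin: np.ndarray, p: RigidPerturbation
) -> tuple[DirectionSet, np.ndarray]:
    """Apply a rigid perturbation: rotate the directions, translate the origin."""
    origin = np.asarray(origin, dtype=float)
    if p.is_identity:
        return ds, origin
    R = p.rotation_matrix()
    dirs = ds.directions @ R.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return (
        DirectionSet(dirs, ds.reference_radius_mm, ds.construction),
        origin + np.asarray(p.translation, dtype=float),
    )
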