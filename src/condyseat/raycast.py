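"""Ray-casting joint-gap measurement on condyle/fossa label volumes.

From the condyle centroid, one ray is cast per hemisphere direction.  Each
ray walks the voxel grid with incremental face-crossing traversal
(Amanatides–Woo); labels are categorical so no interpolation is applied.
The condyle exit is the first condyle -> non-condyle transition, the fossa
entry the first subsequent transition into fossa label, both located at the
shared voxel face (sub-voxel along the ray).  The gap is the Euclidean
distance between the two crossing points, which for a unit direction equals
the difference of the ray parameters — the condyle–fossa joint-space width
in millimeters along that direction.

Rays that never reach the fossa (they leave the grid first, or the fossa is
absent in that direction) carry no gap; they are imputed with a value
bounded by the minimum and maximum of the measured gaps of the same casting
so the classifier input stays dense without over-weighting missing rays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .geometry import DirectionSet, RigidPerturbation, condyle_centroid, perturb
from .io import CONDYLE, FOSSA, LabelVolume

STATUS_OK = 0
STATUS_NO_FOSSA = 1
STATUS_NO_CONDYLE_EXIT = 2
STATUS_OUT_OF_VOLUME = 3

STATUS_NAMES = {
    STATUS_OK: "ok",
    STATUS_NO_FOSSA: "no_fossa",
    STATUS_NO_CONDYLE_EXIT: "no_condyle_exit",
    STATUS_OUT_OF_VOLUME: "out_of_volume",
}

IMPUTATION_POLICIES = ("midpoint", "uniform")


@dataclass(frozen=True)
class RayHit:
    """Outcome of casting a single ray."""

    status: str
    condyle_exit: Optional[np.ndarray] = None
    fossa_entry: Optional[np.ndarray] = None
    gap_mm: Optional[float] = None


@dataclass
class RayFeatureVector:
    """Per-joint vector of N condyle–fossa gap distances plus imputation mask."""

    joint_id: str
    distances: np.ndarray
    imputed: np.ndarray
    label: Optional[str] = None

    @property
    def n_imputed(self) -> int:
        return int(np.count_nonzero(self.imputed))


@njit(cache=True)
def _traverse(labels, spacing, vol_origin, ray_origin, dirs, t_exit, t_fossa, status):
    """March every ray through the grid; record crossing parameters (mm).

    For each ray: t_exit = parameter of the first condyle->non-condyle face
    crossing, t_fossa = parameter of the first subsequent crossing into
    fossa.  Directions are unit vectors so parameters are millimeters.
    """
    nx, ny, nz = labels.shape
    nrays = dirs.shape[0]
    for r in range(nrays):
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        # continuous index coords; voxel i spans [i-0.5, i+0.5]
        gx = (ray_origin[0] - vol_origin[0]) / spacing[0]
        gy = (ray_origin[1] - vol_origin[1]) / spacing[1]
        gz = (ray_origin[2] - vol_origin[2]) / spacing[2]
        ix = int(np.floor(gx + 0.5))
        iy = int(np.floor(gy + 0.5))
        iz = int(np.floor(gz + 0.5))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            status[r] = STATUS_OUT_OF_VOLUME
            t_exit[r] = np.nan
            t_fossa[r] = np.nan
            continue
        stepx = 1 if dx > 0 else (-1 if dx < 0 else 0)
        stepy = 1 if dy > 0 else (-1 if dy < 0 else 0)
        stepz = 1 if dz > 0 else (-1 if dz < 0 else 0)
        big = 1e30
        # parameter to the next face along each axis, in mm
        if stepx != 0:
            bx = vol_origin[0] + (ix + 0.5 * stepx) * spacing[0]
            tmaxx = (bx - ray_origin[0]) / dx
            tdx = spacing[0] / abs(dx)
        else:
            tmaxx, tdx = big, big
        if stepy != 0:
            by = vol_origin[1] + (iy + 0.5 * stepy) * spacing[1]
            tmaxy = (by - ray_origin[1]) / dy
            tdy = spacing[1] / abs(dy)
        else:
            tmaxy, tdy = big, big
        if stepz != 0:
            bz = vol_origin[2] + (iz + 0.5 * stepz) * spacing[2]
            tmaxz = (bz - ray_origin[2]) / dz
            tdz = spacing[2] / abs(dz)
        else:
            tmaxz, tdz = big, big

        prev = labels[ix, iy, iz]
        te = np.nan
        tf = np.nan
        st = STATUS_NO_CONDYLE_EXIT
        seen_condyle = prev == 1
        exited = False
        while True:
            if tmaxx <= tmaxy and tmaxx <= tmaxz:
                t = tmaxx
                tmaxx += tdx
                ix += stepx
                inside = 0 <= ix < nx
            elif tmaxy <= tmaxz:
                t = tmaxy
                tmaxy += tdy
                iy += stepy
                inside = 0 <= iy < ny
            else:
                t = tmaxz
                tmaxz += tdz
                iz += stepz
                inside = 0 <= iz < nz
            if not inside:
                if exited:
                    st = STATUS_NO_FOSSA
                elif seen_condyle:
                    st = STATUS_OUT_OF_VOLUME  # left grid while still in condyle
                else:
                    st = STATUS_NO_CONDYLE_EXIT
                break
            cur = labels[ix, iy, iz]
            if cur == 1:
                seen_condyle = True
            if not exited and prev == 1 and cur != 1:
                te = t
                exited = True
            if exited and cur == 2:
                tf = t
                st = STATUS_OK
                break
            prev = cur
        t_exit[r] = te
        t_fossa[r] = tf
        status[r] = st


def cast_rays(
    volume: LabelVolume, origin: np.ndarray, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised traversal: returns (t_exit, t_fossa, status) arrays in mm."""
    origin = np.asarray(origin, dtype=float)
    if not volume.contains_world(origin):
        raise ValueError(f"ray origin {origin} lies outside the volume grid")
    directions = np.ascontiguousarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length ray direction")
    if not np.allclose(norms, 1.0, atol=1e-9):
        raise ValueError("ray directions must be unit vectors")
    n = directions.shape[0]
    t_exit = np.empty(n)
    t_fossa = np.empty(n)
    status = np.empty(n, dtype=np.int64)
    _traverse(
        volume.voxels,
        volume.spacing,
        volume.origin,
        origin,
        directions,
        t_exit,
        t_fossa,
        status,
    )
    return t_exit, t_fossa, status


def cast_ray(volume: LabelVolume, origin: np.ndarray, direction: np.ndarray) -> RayHit:
    """Cast one ray and report the crossing points and gap."""
    direction = np.asarray(direction, dtype=float)
    t_exit, t_fossa, status = cast_rays(volume, origin, direction.reshape(1, 3))
    st = int(status[0])
    origin = np.asarray(origin, dtype=float)
    if st == STATUS_OK:
        pe = origin + t_exit[0] * direction
        pf = origin + t_fossa[0] * direction
        return RayHit(
            status="ok",
            condyle_exit=pe,
            fossa_entry=pf,
            gap_mm=float(t_fossa[0] - t_exit[0]),
        )
    exit_pt = None if np.isnan(t_exit[0]) else origin + t_exit[0] * direction
    return RayHit(status=STATUS_NAMES[st], condyle_exit=exit_pt)


def impute(
    distances: np.ndarray,
    ok_mask: np.ndarray,
    policy: str = "midpoint",
    rng_seed: int = 0,
) -> np.ndarray:
    """Fill missing ray distances with values in [min, max] of the measured ones.

    ``midpoint`` assigns (min+max)/2 deterministically; ``uniform`` draws
    seeded uniform values in [min, max] (stochastic regularisation during
    training).  Measured entries are returned unchanged.
    """
    distances = np.asarray(distances, dtype=float)
    ok_mask = np.asarray(ok_mask, dtype=bool)
    if policy not in IMPUTATION_POLICIES:
        raise ValueError(f"unknown imputation policy {policy!r}")
    if not ok_mask.any():
        raise ValueError("cannot impute: zero measured ray distances")
    out = distances.copy()
    n_missing = int(np.count_nonzero(~ok_mask))
    if n_missing == 0:
        return out
    lo = float(distances[ok_mask].min())
    hi = float(distances[ok_mask].max())
    if policy == "midpoint":
        out[~ok_mask] = 0.5 * (lo + hi)
    else:
        rng = np.random.default_rng(rng_seed)
        out[~ok_mask] = rng.uniform(lo, hi, size=n_missing)
    return out


def extract_features(
    volume: LabelVolume,
    ds: DirectionSet,
    perturbation: Optional[RigidPerturbation] = None,
    imputation: str = "midpoint",
    rng_seed: int = 0,
    joint_id: str = "",
    label: Optional[str] = None,
) -> RayFeatureVector:
    """Cast one ray per direction from the condyle centroid; impute misses.

    The hemisphere center is the condyle centroid; an optional rigid
    perturbation rotates the directions and translates the origin (training
    augmentation).  The imputation min/max are computed from this casting's
    own measured gaps, after the perturbation.
    """
    centroid = condyle_centroid(volume)
    cidx = np.round(volume.index_from_world(centroid)).astype(int)
    if volume.voxels[tuple(cidx)] != CONDYLE:
        raise ValueError(f"centroid not inside condyle (joint {joint_id!r})")
    if perturbation is not None:
        ds, origin = perturb(ds, centroid, perturbation)
    else:
        origin = centroid
    t_exit, t_fossa, status = cast_rays(volume, origin, ds.directions)
    ok = status == STATUS_OK
    if not ok.any():
        raise ValueError(f"no fossa coverage (joint {joint_id!r})")
    gaps = np.where(ok, t_fossa - t_exit, 0.0)
    gaps = impute(gaps, ok, policy=imputation, rng_seed=rng_seed)
    return RayFeatureVector(
        joint_id=joint_id, distances=gaps, imputed=~ok, label=label
    )


def brute_force_gap(
    volume: LabelVolume,
    origin: np.ndarray,
    direction: np.ndarray,
    step_fraction: float = 0.1,
) -> Optional[float]:
    """Dense-sampling gap oracle: walk the ray at step = min(spacing)*fraction.

    Independent of the incremental traversal; used to cross-check it.
    Returns the gap in mm, or None if no condyle exit / fossa entry exists.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    step = float(volume.spacing.min()) * step_fraction
    extent = float(np.linalg.norm(volume.spacing * np.array(volume.shape)))
    ts = np.arange(0.0, extent * 2, step)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    idx = np.round((pts - volume.origin) / volume.spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    labels = np.zeros(len(ts), dtype=np.uint8)
    labels[inside] = volume.voxels[
        idx[inside, 0], idx[inside, 1], idx[inside, 2]
    ]
    in_condyle = labels == CONDYLE
    if not in_condyle.any():
        return None
    first_c = int(np.argmax(in_condyle))
    after = np.nonzero(~in_condyle[first_c:])[0]
    if after.size == 0:
        return None
    exit_i = first_c + int(after[0])
    fossa_after = np.nonzero(labels[exit_i:] == FOSSA)[0]
    if fossa_after.size == 0:
        return None
    entry_i = exit_i + int(fossa_after[0])
    return float(ts[entry_i] - ts[exit_i])
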