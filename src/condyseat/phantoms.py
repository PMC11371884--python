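"""Synthetic condyle/fossa phantoms with analytically known joint gaps.

A phantom is a condyle sphere articulating with a spherical-shell cap (the
fossa).  The condyle center is offset from the fossa center by a
displacement vector; its magnitude controls the seating quality and defines
the ground-truth label, mirroring the clinical notion that a condyle not
centered in the fossa is incorrectly seated.  Spheres beat anatomical
realism here because every ray gap has a closed-form line–sphere solution,
giving an exact oracle for the voxel ray-caster.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .io import CONDYLE, FOSSA, JointRecord, LabelVolume

DEFAULT_CORRECT_DISP_MM = (0.0, 0.5)
DEFAULT_INCORRECT_DISP_MM = (1.5, 3.5)


@dataclass(frozen=True)
class PhantomSpec:
    condyle_radius_mm: float = 5.0
    fossa_inner_radius_mm: float = 7.0
    fossa_thickness_mm: float = 2.0
    fossa_coverage_deg: float = 80.0  # polar half-angle of the fossa cap
    displacement_mm: tuple = (0.0, 0.0, 0.0)  # condyle center - fossa center
    spacing_mm: float = 0.4

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")
        if not 0 < self.fossa_coverage_deg <= 180:
            raise ValueError("fossa_coverage_deg must lie in (0, 180]")
        d = np.linalg.norm(self.displacement_mm)
        if d >= self.fossa_inner_radius_mm:
            raise ValueError(
                "condyle center must stay inside the fossa inner sphere"
            )

    @property
    def displacement(self) -> np.ndarray:
        return np.asarray(self.displacement_mm, dtype=float)


def _in_fossa(spec: PhantomSpec, p: np.ndarray) -> bool:
    r = float(np.linalg.norm(p))
    ri, ro = spec.fossa_inner_radius_mm, spec.fossa_inner_radius_mm + spec.fossa_thickness_mm
    if not ri <= r <= ro:
        return False
    return p[2] >= r * np.cos(np.deg2rad(spec.fossa_coverage_deg))


def analytic_gap(spec: PhantomSpec, direction: Sequence[float]) -> Optional[float]:
    """Closed-form ray gap from the condyle center along a unit direction.

    Distance to the condyle surface is the condyle radius.  The fossa-entry
    distance is the smallest positive root over the solid's boundary
    surfaces — the inner and outer spheres (quadratic in t) and, when the
    cap is partial, the bounding cone (quadratic in t) — at which the ray
    enters the shell cap.  Returns the gap in mm, or None when the
    direction misses the fossa entirely (``no_fossa``).
    """
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    o = spec.displacement  # ray origin relative to the fossa center
    ri = spec.fossa_inner_radius_mm
    ro = ri + spec.fossa_thickness_mm
    ou = float(o @ u)
    oo = float(o @ o)
    candidates = []
    for radius in (ri, ro):
        disc = ou * ou - oo + radius * radius
        if disc >= 0:
            root = np.sqrt(disc)
            candidates += [-ou - root, -ou + root]
    cov = spec.fossa_coverage_deg
    if cov == 90.0:
        # cap boundary degenerates to the plane z = 0
        if abs(u[2]) > 1e-15:
            candidates.append(-o[2] / u[2])
    elif cov < 180.0:
        # cone z^2 = c^2 |p|^2 (membership test selects the correct nappe)
        c2 = np.cos(np.deg2rad(cov)) ** 2
        A = u[2] * u[2] - c2
        B = 2.0 * (o[2] * u[2] - c2 * ou)
        C = o[2] * o[2] - c2 * oo
        if abs(A) > 1e-15:
            disc = B * B - 4 * A * C
            if disc >= 0:
                root = np.sqrt(disc)
                candidates += [(-B - root) / (2 * A), (-B + root) / (2 * A)]
        elif abs(B) > 1e-15:
            candidates.append(-C / B)
    eps = 1e-9
    for t in sorted(c for c in candidates if c > eps):
        if _in_fossa(spec, o + (t + eps) * u):
            return float(t - spec.condyle_radius_mm)
    return None


def solids_overlap(spec: PhantomSpec, n_polar: int = 50, n_azim: int = 90) -> bool:
    """True if the condyle sphere intersects the fossa shell cap.

    Checks, over a dense grid of in-cap radial directions from the fossa
    center, whether the condyle's radial extent reaches the inner radius.
    """
    d = spec.displacement
    rc = spec.condyle_radius_mm
    ri = spec.fossa_inner_radius_mm
    theta = np.linspace(0.0, np.deg2rad(spec.fossa_coverage_deg), n_polar)
    phi = np.linspace(0.0, 2 * np.pi, n_azim, endpoint=False)
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    u = np.stack(
        [
            (st * np.cos(phi)[None, :]).ravel(),
            (st * np.sin(phi)[None, :]).ravel(),
            np.broadcast_to(ct, (n_polar, n_azim)).ravel(),
        ],
        axis=1,
    )
    du = u @ d
    h2 = float(d @ d) - du * du  # squared distance from condyle center to the line
    hits = h2 <= rc * rc
    t_max = du[hits] + np.sqrt(rc * rc - h2[hits])
    return bool(t_max.size and np.any(t_max >= ri))


def rasterize_phantom(spec: PhantomSpec, margin_mm: float = 1.2) -> LabelVolume:
    """Voxelise the phantom: voxel centers inside each solid get its label.

    The fossa center sits at world (0, 0, 0); the grid is symmetric about
    it with the configured isotropic spacing.  Raises if the solids overlap.
    """
    s = spec.spacing_mm
    d = spec.displacement
    reach = max(
        spec.fossa_inner_radius_mm + spec.fossa_thickness_mm,
        float(np.linalg.norm(d)) + spec.condyle_radius_mm,
    ) + margin_mm
    half = int(np.ceil(reach / s))
    n = 2 * half + 1
    coords = (np.arange(n) - half) * s
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    condyle = (x - d[0]) ** 2 + (y - d[1]) ** 2 + (z - d[2]) ** 2 <= (
        spec.condyle_radius_mm**2
    )
    r2 = x**2 + y**2 + z**2
    ri, ro = spec.fossa_inner_radius_mm, spec.fossa_inner_radius_mm + spec.fossa_thickness_mm
    with np.errstate(invalid="ignore"):
        in_cap = z >= np.sqrt(r2) * np.cos(np.deg2rad(spec.fossa_coverage_deg))
    fossa = (r2 >= ri * ri) & (r2 <= ro * ro) & in_cap
    if np.any(condyle & fossa):
        raise ValueError("condyle and fossa solids overlap")
    voxels = np.zeros((n, n, n), dtype=np.uint8)
    voxels[condyle] = CONDYLE
    voxels[fossa] = FOSSA
    return LabelVolume(
        voxels=voxels,
        spacing=np.full(3, s),
        origin=np.full(3, -half * s),
    )


@dataclass
class SyntheticDataset:
    """A reproducible collection of phantom joints with known labels."""

    records: list  # of (JointRecord, PhantomSpec)
    seed: int

    @property
    def labels(self) -> Dict[str, str]:
        return {rec.joint_id: rec.label for rec, _ in self.records}

    @property
    def n_correct(self) -> int:
        return sum(rec.label == "correct" for rec, _ in self.records)

    @property
    def n_incorrect(self) -> int:
        return sum(rec.label == "incorrect" for rec, _ in self.records)

    def rasterize_all(self) -> Dict[str, LabelVolume]:
        return {rec.joint_id: rasterize_phantom(spec) for rec, spec in self.records}


def _random_displacement(
    rng: np.random.Generator, magnitude: float, inferior_bias: bool
) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    if inferior_bias:
        v[2] = -abs(v[2])  # displace away from the fossa cap
    return v * magnitude


def make_dataset(
    n_correct: int,
    n_incorrect: int,
    correct_disp_mm: tuple = DEFAULT_CORRECT_DISP_MM,
    incorrect_disp_mm: tuple = DEFAULT_INCORRECT_DISP_MM,
    seed: int = 0,
    spacing_mm: float = 0.4,
    radius_jitter: float = 0.10,
    inferior_bias: bool = True,
    fossa_coverage_deg: float = 80.0,
) -> SyntheticDataset:
    """Draw a labelled phantom dataset with class-separated displacements.

    Correct joints get displacement magnitudes from ``correct_disp_mm``,
    incorrect ones from ``incorrect_disp_mm``; the ranges must be disjoint
    so the ground truth is unambiguous.  Condyle and fossa radii are
    jittered by +/-``radius_jitter`` (fractional).  Large displacements are
    biased toward the inferior hemisphere and rejection-sampled so the
    solids never overlap.  Fully reproducible from ``seed``.
    """
    if n_correct < 0 or n_incorrect < 0:
        raise ValueError("class counts must be >= 0")
    lo_c, hi_c = correct_disp_mm
    lo_i, hi_i = incorrect_disp_mm
    if max(lo_c, lo_i) < min(hi_c, hi_i):
        raise ValueError(
            "displacement ranges overlap; ground-truth labels would be ambiguous"
        )
    rng = np.random.default_rng(seed)
    records = []
    plan = [("correct", (lo_c, hi_c))] * n_correct + [
        ("incorrect", (lo_i, hi_i))
    ] * n_incorrect
    for i, (label, (lo, hi)) in enumerate(plan):
        rc = 5.0 * rng.uniform(1 - radius_jitter, 1 + radius_jitter)
        ri = 7.0 * rng.uniform(1 - radius_jitter, 1 + radius_jitter)
        mag = rng.uniform(lo, hi)
        spec = None
        for _ in range(200):
            disp = _random_displacement(rng, mag, inferior_bias)
            candidate = PhantomSpec(
                condyle_radius_mm=rc,
                fossa_inner_radius_mm=ri,
                fossa_coverage_deg=fossa_coverage_deg,
                displacement_mm=tuple(disp),
                spacing_mm=spacing_mm,
            )
            if not solids_overlap(candidate):
                spec = candidate
                break
        if spec is None:  # pragma: no cover - bounds keep this unreachable
            raise RuntimeError(f"could not place joint {i} without overlap")
        rec = JointRecord(
            joint_id=f"syn{i:03d}",
            side="left" if i % 2 == 0 else "right",
            label=label,
            provenance="synthetic",
        )
        records.append((rec, spec))
    return SyntheticDataset(records=records, seed=seed)
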