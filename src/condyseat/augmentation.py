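"""Training-time data augmentation.

Two strategies are used during training only:

* contralateral mirroring — each training condyle/fossa volume is flipped
  left-right once per fold, doubling the training sample count and
  simulating the opposite-side joint;
* rigid jitter of the ray hemisphere — per epoch, per joint, the hemisphere
  origin is translated uniformly within +/-2 mm per axis and the directions
  rotated uniformly within +/-10 degrees per Euler axis, decoupling the
  classifier from the exact centroid position and from head tilt at scan
  time.

Validation features are always extracted with zero perturbation and
deterministic (midpoint) imputation.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np

from .geometry import LATERAL_AXIS, RigidPerturbation
from .io import JointRecord, LabelVolume


@dataclass(frozen=True)
class AugmentationConfig:
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 10.0
    mirror: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_translation_mm < 0 or self.max_rotation_deg < 0:
            raise ValueError("augmentation bounds must be >= 0")


def mirror_pair(volume: LabelVolume, lateral_axis: int = LATERAL_AXIS) -> LabelVolume:
    """Reflect a volume through its own mid-sagittal plane.

    Voxels are flipped along the left-right axis with origin and spacing
    unchanged, which in world coordinates is the reflection through the
    plane halving the volume extent on that axis.  Labels are preserved and
    the operation is an involution.
    """
    flipped = np.flip(volume.voxels, axis=lateral_axis).copy()
    return LabelVolume(
        voxels=flipped,
        spacing=volume.spacing.copy(),
        origin=volume.origin.copy(),
        axes_superior=volume.axes_superior,
    )


def mirror_record(record: JointRecord) -> JointRecord:
    """Manifest entry for the mirrored counterpart of a joint."""
    return dataclasses.replace(
        record,
        joint_id=record.joint_id + "_mirror",
        side="right" if record.side == "left" else "left",
        provenance="mirrored",
        source_joint_id=record.joint_id,
    )


def _stream_seed(rng_seed: int, epoch: int, joint_id: str) -> list:
    return [rng_seed, epoch, zlib.crc32(joint_id.encode("utf-8"))]


def sample_perturbation(
    cfg: AugmentationConfig, epoch: int, joint_id: str
) -> RigidPerturbation:
    """Draw the rigid jitter for (epoch, joint): uniform within the bounds.

    The stream is seeded deterministically by (rng_seed, epoch, joint_id),
    so the same triple always yields the same perturbation while different
    epochs or joints get independent draws.
    """
    rng = np.random.default_rng(_stream_seed(cfg.rng_seed, epoch, joint_id))
    t = rng.uniform(-cfg.max_translation_mm, cfg.max_translation_mm, size=3)
    r = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg, size=3)
    return RigidPerturbation(translation=tuple(t), rotation_deg=tuple(r))


def imputation_seed(rng_seed: int, epoch: int, joint_id: str) -> int:
    """Seed for the per-joint uniform-imputation stream during training."""
    return zlib.crc32(f"{rng_seed}:{epoch}:{joint_id}:impute".encode("utf-8"))
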