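"""Suprathreshold voxel extraction and the Volume intensity score.

For each arm, the voxels whose Z score exceeds the threshold (2.5 SD by
default, strict ``>``) are extracted; their physical volume in mL, the
mean Z over that volume, and the composite Volume intensity score
(VIS = suprathreshold volume x mean Z, units mL·SD) summarise the focal
radioligand uptake. Because volume x mean Z equals voxel volume x
summed Z algebraically, the score satisfies both the "mean" and the
"summed" reading of the composite up to the constant voxel volume; the
implementation reports both the mean and the sum. An empty
suprathreshold set yields volume = mean Z = VIS = 0 rather than an
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvariantError
from .volume import VoxelVolume
from .zscore import ZMap

#: Default extraction threshold in SD units.
DEFAULT_THRESHOLD_SD = 2.5


@dataclass(frozen=True)
class ArmMetrics:
    """Per-arm derived quantities; one row of the per-arm results table.

    ``supra_sum_z`` is ``None`` for rows read from a published table
    where only volume and mean Z are printed.
    """

    affected: bool
    n_voxels_examined: int
    mean_bq: float
    sd_bq: float
    supra_volume_ml: float
    supra_mean_z: float
    vis: float
    supra_sum_z: float | None = None
    side: str | None = None
    pain_vas: float | None = None

    def __post_init__(self) -> None:
        if self.supra_volume_ml < 0 or self.vis < 0:
            raise InvariantError("suprathreshold volume and VIS must be >= 0")
        if self.pain_vas is not None and not (0 <= self.pain_vas <= 100):
            raise InvariantError(f"pain VAS must be in [0, 100], got {self.pain_vas}")
        if self.supra_volume_ml == 0:
            if self.supra_mean_z != 0 or self.vis != 0:
                raise InvariantError(
                    "empty suprathreshold set must report volume = meanZ = VIS = 0"
                )


@dataclass(frozen=True)
class SubjectRecord:
    """One examination: affected and unaffected arm metrics plus metadata."""

    subject_id: str
    timepoint: str  # "before" | "after"
    affected: ArmMetrics
    unaffected: ArmMetrics

    def __post_init__(self) -> None:
        if self.timepoint not in ("before", "after"):
            raise InvariantError(f"timepoint must be before/after, got {self.timepoint!r}")
        if not self.affected.affected or self.unaffected.affected:
            raise InvariantError("affected/unaffected arm flags inconsistent")

    def arm(self, which: str) -> ArmMetrics:
        if which == "affected":
            return self.affected
        if which == "unaffected":
            return self.unaffected
        raise ValueError(f"which must be 'affected' or 'unaffected', got {which!r}")


def suprathreshold_mask(
    zmap: ZMap,
    arm_mask: np.ndarray,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
) -> np.ndarray:
    """Voxels within the arm whose Z score is strictly above the threshold."""
    if not threshold_sd > 0:
        raise InvariantError(f"threshold must be > 0 SD, got {threshold_sd}")
    arm_mask = np.asarray(arm_mask, dtype=bool)
    if arm_mask.shape != zmap.volume.shape:
        raise InvariantError("arm mask and Z map dimensions differ")
    return (zmap.volume.data > threshold_sd) & arm_mask


def compute_metrics(
    emission: VoxelVolume,
    zmap: ZMap,
    arm_mask: np.ndarray,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    affected: bool = False,
    side: str | None = None,
    pain_vas: float | None = None,
) -> ArmMetrics:
    """Fill every per-arm metric from an emission volume and its Z map.

    ``supra_volume_ml`` is the suprathreshold voxel count times the
    physical voxel volume; VIS = supra_volume_ml x supra_mean_z, which
    equals voxel_volume_ml x supra_sum_z identically.
    """
    arm_mask = np.asarray(arm_mask, dtype=bool)
    if arm_mask.shape != emission.shape:
        raise InvariantError("arm mask and emission dimensions differ")
    if not arm_mask.any():
        raise InvariantError("empty arm mask")
    from .segmentation import arm_voxel_stats

    n, mean_bq, sd_bq = arm_voxel_stats(emission, arm_mask)
    supra = suprathreshold_mask(zmap, arm_mask, threshold_sd)
    n_supra = int(supra.sum())
    if n_supra == 0:
        vol_ml = mean_z = sum_z = vis = 0.0
    else:
        zvals = zmap.volume.data[supra]
        vol_ml = n_supra * emission.voxel_volume_ml
        mean_z = float(zvals.mean())
        sum_z = float(zvals.sum())
        vis = vol_ml * mean_z
    return ArmMetrics(
        affected=affected,
        n_voxels_examined=n,
        mean_bq=mean_bq,
        sd_bq=sd_bq,
        supra_volume_ml=vol_ml,
        supra_mean_z=mean_z,
        supra_sum_z=sum_z,
        vis=vis,
        side=side,
        pain_vas=pain_vas,
    )
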