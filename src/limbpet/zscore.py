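"""Z-score parametric images referenced to the unaffected arm.

The unaffected (contralateral) arm serves as the within-subject
reference region: its voxel mean and SD define the Z transform
``z = (v - mean) / sd`` applied to the whole emission volume. Using one
common reference for both arms is what makes inter-arm comparison of Z
values meaningful; a per-arm-SD variant exists behind a flag in the
pipeline for sensitivity analysis. Each examination uses its own
same-day reference — injected dose varies between sessions, so
references are never pooled across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateReferenceError
from .segmentation import arm_voxel_stats
from .volume import VoxelVolume


@dataclass(frozen=True)
class ReferenceStats:
    """Normalisation constants taken from the reference (unaffected) arm."""

    mean_bq: float
    sd_bq: float
    n_voxels: int
    source: str = "unaffected"

    def __post_init__(self) -> None:
        if self.n_voxels < 2:
            raise DegenerateReferenceError(
                f"reference needs >= 2 voxels, got {self.n_voxels}"
            )
        if not (self.sd_bq > 0):
            raise DegenerateReferenceError(
                f"reference SD must be > 0 (got {self.sd_bq}); Z units undefined"
            )


@dataclass(frozen=True)
class ZMap:
    """An emission volume re-expressed in SD units above the reference mean."""

    volume: VoxelVolume
    reference: ReferenceStats


def reference_stats(
    emission: VoxelVolume, unaffected_mask: np.ndarray, source: str = "unaffected"
) -> ReferenceStats:
    """Mean, SD and voxel count of the reference arm's emission signal.

    Same estimator as :func:`limbpet.segmentation.arm_voxel_stats`
    (sample SD, denominator n-1).

    Raises
    ------
    DegenerateReferenceError
        Fewer than two voxels, or zero SD (constant region).
    """
    mask = np.asarray(unaffected_mask, dtype=bool)
    if mask.sum() < 2:
        raise DegenerateReferenceError(
            f"reference mask holds {int(mask.sum())} voxel(s); need >= 2"
        )
    n, mean, sd = arm_voxel_stats(emission, mask)
    return ReferenceStats(mean_bq=mean, sd_bq=sd, n_voxels=n, source=source)


def zscore_map(emission: VoxelVolume, ref: ReferenceStats) -> ZMap:
    """Transform every voxel value v to (v - ref.mean) / ref.sd.

    Dimensions and spacing are preserved; the result carries the
    ``zscore`` units tag. Applied to the reference arm itself, the Z
    values have mean 0 and SD 1 by construction.
    """
    z = (emission.data - ref.mean_bq) / ref.sd_bq
    vol = emission.with_data(
        z, units="zscore", description=f"Z vs {ref.source} arm"
    )
    return ZMap(volume=vol, reference=ref)
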