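"""Segment the two arms from the transmission (density) volume.

The study posture places both arms, stretched overhead, in the field of
view; the transmission scan gives a density map in which the arms are
the only large bodies above air density. Segmentation thresholds the
density map (2-class Otsu by default), labels connected components with
26-connectivity, and keeps the two largest limb-sized components — or,
in semi-automatic mode, the components containing caller-supplied seed
voxels. Side labels are assigned deterministically by centroid order
along axis 0 (smaller coordinate = left); the *affected* side is never
inferred here, it is metadata supplied to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import InvariantError, SegmentationError
from .volume import VoxelVolume

#: 26-neighbourhood structuring element for 3D component labelling.
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ArmSegmentation:
    """Two disjoint arm masks labelled by anatomical side."""

    left_mask: np.ndarray
    right_mask: np.ndarray
    left_centroid: tuple[float, float, float]
    right_centroid: tuple[float, float, float]
    left_size: int
    right_size: int
    density_threshold: float

    def __post_init__(self) -> None:
        if self.left_size == 0 or self.right_size == 0:
            raise InvariantError("arm masks must be non-empty")
        if np.logical_and(self.left_mask, self.right_mask).any():
            raise InvariantError("arm masks must be disjoint")

    def mask(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.left_mask if side == "left" else self.right_mask

    @property
    def component_sizes(self) -> dict[str, int]:
        return {"left": self.left_size, "right": self.right_size}


def segment_arms(
    transmission: VoxelVolume,
    density_threshold: float | None = None,
    seeds: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
    min_component_voxels: int = 100,
) -> ArmSegmentation:
    """Locate and segment the two arms from a density volume.

    Parameters
    ----------
    transmission : VoxelVolume
        Density map (units tag ``density``).
    density_threshold : float, optional
        Voxels strictly above this density are candidate tissue. When
        omitted, a 2-class Otsu split of the density histogram is used —
        deterministic and parameter-free; the threshold must then fall
        strictly between air and tissue levels.
    seeds : pair of voxel index triples, optional
        Semi-automatic mode: the connected component containing each
        seed becomes one arm. Without seeds the two largest components
        are used.
    min_component_voxels : int
        Components smaller than this are not considered limbs.

    Raises
    ------
    SegmentationError
        Fewer than two limb-sized components, a constant (all-air)
        volume, or a seed falling in background.
    """
    if transmission.units != "density":
        raise InvariantError(
            f"segmentation expects a density volume, got units={transmission.units!r}"
        )
    data = transmission.data
    if density_threshold is None:
        try:
            density_threshold = float(threshold_otsu(data))
        except ValueError as exc:  # constant image
            raise SegmentationError(f"cannot derive density threshold: {exc}") from exc

    foreground = data > density_threshold
    labels, n_components = ndimage.label(foreground, structure=_CONNECTIVITY_26)
    if n_components < 2:
        raise SegmentationError(
            f"found {n_components} connected component(s) above threshold "
            f"{density_threshold:g}; need two arms"
        )
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background

    if seeds is not None:
        if len(seeds) != 2:
            raise SegmentationError("exactly two seeds required")
        picked = []
        for seed in seeds:
            lab = int(labels[tuple(int(i) for i in seed)])
            if lab == 0:
                raise SegmentationError(f"seed {tuple(seed)} falls in background")
            picked.append(lab)
        if picked[0] == picked[1]:
            raise SegmentationError("both seeds fall in the same component")
    else:
        order = np.argsort(sizes)[::-1]
        picked = [int(order[0]), int(order[1])]

    if any(sizes[lab] < min_component_voxels for lab in picked):
        raise SegmentationError(
            f"fewer than two components of >= {min_component_voxels} voxels "
            f"(largest candidate sizes: {[int(sizes[lab]) for lab in picked]})"
        )

    masks = [labels == lab for lab in picked]
    centroids = [tuple(map(float, ndimage.center_of_mass(m))) for m in masks]
    # deterministic side assignment: smaller axis-0 centroid = left
    if centroids[0][0] > centroids[1][0]:
        masks.reverse()
        centroids.reverse()
        picked.reverse()
    return ArmSegmentation(
        left_mask=masks[0],
        right_mask=masks[1],
        left_centroid=centroids[0],
        right_centroid=centroids[1],
        left_size=int(masks[0].sum()),
        right_size=int(masks[1].sum()),
        density_threshold=float(density_threshold),
    )


def arm_voxel_stats(
    emission: VoxelVolume, mask: np.ndarray
) -> tuple[int, float, float]:
    """Count, mean and sample SD (denominator n-1) of emission under a mask.

    These populate the examined-voxel count and mean intensity (Bq)
    columns of the per-arm results table.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != emission.shape:
        raise InvariantError(
            f"mask shape {mask.shape} does not match volume shape {emission.shape}"
        )
    values = emission.data[mask]
    n = int(values.size)
    if n == 0:
        raise InvariantError("empty mask: no voxels to summarise")
    if n == 1:
        raise InvariantError("single-voxel mask: sample SD undefined")
    return n, float(values.mean()), float(values.std(ddof=1))
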