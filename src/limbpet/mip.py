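"""Maximum intensity projection (MIP) rendering.

The study presents parametric images as coronal maximum intensity
projections: each output pixel is the maximum voxel value along the
projection ray. With the package's axis convention (axis 0 left-right,
axis 1 anterior-posterior for the prone posture, axis 2 axial), the
coronal projection collapses axis 1.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .errors import InvariantError
from .volume import VoxelVolume

#: Anatomical names for projection axes under the package convention.
AXIS_NAMES = {"sagittal": 0, "coronal": 1, "axial": 2}


def render_mip(volume: VoxelVolume, axis: int | str = "coronal") -> np.ndarray:
    """Per-pixel maximum of the volume along one axis.

    Parameters
    ----------
    volume : VoxelVolume
    axis : int or {"sagittal", "coronal", "axial"}

    Returns
    -------
    ndarray (2D)
        The projected maxima, in the volume's units; deterministic.
    """
    if isinstance(axis, str):
        if axis not in AXIS_NAMES:
            raise InvariantError(f"unknown axis name {axis!r}; use {sorted(AXIS_NAMES)}")
        axis = AXIS_NAMES[axis]
    if axis not in (0, 1, 2):
        raise InvariantError(f"axis must be 0, 1 or 2, got {axis}")
    return np.max(volume.data, axis=axis)


def mip_to_image(
    mip: np.ndarray, window: tuple[float, float] | None = None
) -> Image.Image:
    """Render a projection as an 8-bit linear-grayscale image.

    ``window`` gives the (low, high) values mapped to black and white;
    by default the data range is used. Values outside the window clip.
    """
    mip = np.asarray(mip, dtype=float)
    if mip.ndim != 2:
        raise InvariantError("expected a 2D projection")
    lo, hi = window if window is not None else (float(mip.min()), float(mip.max()))
    if hi <= lo:
        scaled = np.zeros_like(mip)
    else:
        scaled = np.clip((mip - lo) / (hi - lo), 0.0, 1.0)
    # transpose so axis 0 (left-right) runs along image width
    return Image.fromarray(np.round(255 * scaled).astype(np.uint8).T, mode="L")
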