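"""The in-memory carrier for 3D scalar volumes.

A :class:`VoxelVolume` holds the voxel grid together with its physical
spacing and a units tag; the same type carries emission (radioactivity
concentration, Bq), transmission/density, and Z-score parametric images.
All processing happens in floating point regardless of the on-disk
element type, because Z maps require signed fractional values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvariantError

#: Recognised units tags.
UNITS = ("Bq", "density", "zscore")


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; converted to float64 on construction.
    spacing_mm : tuple of float
        Edge lengths of one voxel along each axis, in millimetres.
    units : {"Bq", "density", "zscore"}
        What the voxel values measure.
    description : str
        Free text carried through I/O (truncated to 80 bytes on disk).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = "Bq"
    description: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise InvariantError(f"volume must be 3D, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise InvariantError(f"all dimensions must be >= 1, got {data.shape}")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise InvariantError(f"spacings must be positive and finite, got {self.spacing_mm}")
        if self.units not in UNITS:
            raise InvariantError(f"units must be one of {UNITS}, got {self.units!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def with_data(self, data: np.ndarray, units: str | None = None,
                  description: str | None = None) -> "VoxelVolume":
        """Return a copy with new voxel values (and optionally new tags)."""
        return replace(
            self,
            data=data,
            units=self.units if units is None else units,
            description=self.description if description is None else description,
        )

    def validate_finite(self) -> None:
        if np.isnan(self.data).any():
            raise InvariantError("volume contains NaN values")
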