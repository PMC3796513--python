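"""Synthetic emission/transmission phantoms with exact ground truth.

The phantom emulates the acquisition geometry of the bilateral-arm PET
study — a 128x128x63 grid at 2.46 mm plane spacing with two disjoint
dense arms surrounded by air — so that every downstream stage
(segmentation, Z mapping, suprathreshold metrics) can be validated
against known truth. Arms are straight circular cylinders along axis 1:
segmentation only needs two disjoint dense bodies, so anatomy is
deliberately simplified. The optional hotspot is a hard sphere of
uniform amplitude, expressed in SD units above the arm background, and
is clipped to the affected arm's mask so the ground-truth volume stays
exact.

No scanner physics is simulated (no point-spread, attenuation, scatter
or decay); Gaussian voxel noise is the default, matching the tail
analysis behind the 2.5 SD extraction rule. ``poisson_scaled`` draws
scaled Poisson counts whose variance is proportional to the local mean,
calibrated so the arm background reproduces the requested SD.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvariantError
from .metrics import ArmMetrics, SubjectRecord
from .volume import VoxelVolume


@dataclass(frozen=True)
class Hotspot:
    """A spherical region of elevated uptake inside one arm.

    ``amplitude_sd`` is the added emission expressed in multiples of the
    background emission SD, i.e. an amplitude of 6 plants voxels whose
    expected Z score against the other arm is ~6.
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float
    amplitude_sd: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise InvariantError("hotspot radius must be > 0")
        if self.amplitude_sd < 0:
            raise InvariantError("hotspot amplitude must be >= 0 SD")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic emission/transmission pair.

    Defaults reproduce the study grid (128x128x63, 2.46 mm planes) with
    two 20 mm-radius arms 120 mm apart — roughly the per-arm voxel
    counts of real examinations — and an arm emission background of
    2000 +/- 500 Bq.
    """

    dims: tuple[int, int, int] = (128, 128, 63)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.46)
    arm_radius_mm: float = 20.0
    arm_separation_mm: float = 120.0
    tissue_density: float = 1.0
    air_density: float = 0.0
    emission_mean_bq: float = 2000.0
    emission_sd_bq: float = 500.0
    background_bq: float = 0.0
    hotspot: Hotspot | None = None
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise InvariantError(f"dims must be three positive integers, got {self.dims}")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvariantError("spacings must be positive")
        if self.arm_separation_mm <= 2 * self.arm_radius_mm:
            raise InvariantError(
                "arms overlap: separation must exceed twice the radius "
                f"({self.arm_separation_mm} <= 2 x {self.arm_radius_mm})"
            )
        if not (0 <= self.air_density < self.tissue_density):
            raise InvariantError("need 0 <= air_density < tissue_density")
        if self.emission_mean_bq <= 0 or self.emission_sd_bq <= 0:
            raise InvariantError("emission mean and SD must be > 0")
        if self.noise_model not in ("gaussian", "poisson_scaled"):
            raise InvariantError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth masks and volumes for a generated phantom."""

    left_mask: np.ndarray
    right_mask: np.ndarray
    hotspot_mask: np.ndarray
    hotspot_volume_ml: float
    affected_side: str  # "left" | "right" | "none"

    def __post_init__(self) -> None:
        if np.logical_and(self.left_mask, self.right_mask).any():
            raise InvariantError("arm masks must be disjoint")
        if self.affected_side not in ("left", "right", "none"):
            raise InvariantError(f"bad affected_side {self.affected_side!r}")
        if self.hotspot_mask.any():
            arm = self.left_mask if self.affected_side == "left" else self.right_mask
            if not (self.hotspot_mask <= arm).all():
                raise InvariantError("hotspot mask must lie inside the affected arm")

    def arm_mask(self, side: str) -> np.ndarray:
        return self.left_mask if side == "left" else self.right_mask


def _voxel_grids_mm(spec: PhantomSpec):
    nx, ny, nz = spec.dims
    sx, sy, sz = spec.spacing_mm
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    return x, y, z


def _arm_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Two cylinders along axis 1, cross-sections in the (axis0, axis2) plane."""
    x, _, z = _voxel_grids_mm(spec)
    cx_mid = x[-1] / 2.0
    cz = z[-1] / 2.0
    r = spec.arm_radius_mm
    masks = []
    for cx in (cx_mid - spec.arm_separation_mm / 2, cx_mid + spec.arm_separation_mm / 2):
        if cx - r < 0 or cx + r > x[-1] or cz - r < 0 or cz + r > z[-1]:
            raise InvariantError(
                "arm cylinder extends outside the grid; shrink radius/separation "
                "or enlarge dims"
            )
        in_circle = (x[:, None] - cx) ** 2 + (z[None, :] - cz) ** 2 <= r**2
        masks.append(np.repeat(in_circle[:, None, :], spec.dims[1], axis=1))
    return masks[0], masks[1]


def _hotspot_mask(spec: PhantomSpec) -> np.ndarray:
    x, y, z = _voxel_grids_mm(spec)
    ci, cj, ck = spec.hotspot.center_voxel
    cx, cy, cz = x[int(ci)], y[int(cj)], z[int(ck)]
    d2 = (
        (x[:, None, None] - cx) ** 2
        + (y[None, :, None] - cy) ** 2
        + (z[None, None, :] - cz) ** 2
    )
    return d2 <= spec.hotspot.radius_mm**2


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelVolume, VoxelVolume, PhantomTruth]:
    """Generate an (emission, transmission, truth) triple from a spec.

    Transmission equals ``tissue_density`` inside the two arm cylinders
    and ``air_density`` outside. Emission is ``emission_mean_bq`` plus
    noise inside the arms and ``background_bq`` plus noise outside;
    hotspot voxels are raised by ``amplitude_sd x emission_sd_bq``
    before noise. Identical seeds yield voxelwise-identical volumes.
    """
    left, right = _arm_masks(spec)
    arms = left | right

    trans = np.where(arms, spec.tissue_density, spec.air_density).astype(np.float64)

    mean_field = np.where(arms, spec.emission_mean_bq, spec.background_bq).astype(
        np.float64
    )
    if spec.hotspot is not None and spec.hotspot.amplitude_sd > 0:
        sphere = _hotspot_mask(spec)
        ci = spec.hotspot.center_voxel
        if left[tuple(int(i) for i in ci)]:
            affected = "left"
        elif right[tuple(int(i) for i in ci)]:
            affected = "right"
        else:
            raise InvariantError("hotspot centre must lie inside an arm")
        hotspot = sphere & (left if affected == "left" else right)
        mean_field[hotspot] += spec.hotspot.amplitude_sd * spec.emission_sd_bq
    else:
        hotspot = np.zeros(spec.dims, dtype=bool)
        affected = "none"

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian":
        emission = rng.normal(mean_field, spec.emission_sd_bq)
    else:  # poisson_scaled: variance proportional to local mean
        scale = spec.emission_sd_bq**2 / spec.emission_mean_bq
        emission = scale * rng.poisson(np.maximum(mean_field, 0.0) / scale)

    spacing = spec.spacing_mm
    voxel_ml = float(np.prod(spacing)) / 1000.0
    emission_vol = VoxelVolume(
        emission, spacing, units="Bq", description="synthetic emission phantom"
    )
    trans_vol = VoxelVolume(
        trans, spacing, units="density", description="synthetic transmission phantom"
    )
    truth = PhantomTruth(
        left_mask=left,
        right_mask=right,
        hotspot_mask=hotspot,
        hotspot_volume_ml=float(hotspot.sum()) * voxel_ml,
        affected_side=affected,
    )
    return emission_vol, trans_vol, truth


# ---------------------------------------------------------------------------
# Published per-arm results table (fixture)
# ---------------------------------------------------------------------------

_TABLE2_RESOURCE = "table2.tsv"


def table2_frame() -> pd.DataFrame:
    """The published per-arm results table as a DataFrame, values verbatim.

    36 rows: 10 subjects x 2 arms before treatment, 8 x 2 after (two
    subjects discontinued and have no after-treatment examination).
    Columns: subject, timepoint, arm, pain_vas, examined_voxels,
    mean_bq, sd_bq, volume_ml, mean_z, vis, note. Two rows carry notes
    flagging apparent transcription inconsistencies in the source table:
    the subject-2 after-treatment arms print identical mean intensities,
    and the subject-7 after-treatment score does not equal its printed
    volume x mean Z under any rounding of the printed inputs. Values are
    shipped exactly as printed.
    """
    ref = importlib.resources.files("limbpet").joinpath("data", _TABLE2_RESOURCE)
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"subject": str, "note": str})
    df["note"] = df["note"].fillna("")
    return df


def table2_fixture() -> list[SubjectRecord]:
    """The fixture table as typed :class:`SubjectRecord` objects (18 exams)."""
    df = table2_frame()
    records = []
    for (subject, timepoint), grp in df.groupby(["subject", "timepoint"], sort=False):
        arms = {}
        for _, row in grp.iterrows():
            arms[row["arm"]] = ArmMetrics(
                affected=row["arm"] == "affected",
                n_voxels_examined=int(row["examined_voxels"]),
                mean_bq=float(row["mean_bq"]),
                sd_bq=float(row["sd_bq"]),
                supra_volume_ml=float(row["volume_ml"]),
                supra_mean_z=float(row["mean_z"]),
                vis=float(row["vis"]),
                pain_vas=float(row["pain_vas"]),
            )
        records.append(
            SubjectRecord(
                subject_id=str(subject),
                timepoint=str(timepoint),
                affected=arms["affected"],
                unaffected=arms["unaffected"],
            )
        )
    return records
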