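"""Model/Results objects orchestrating the per-examination pipeline and
the group-level analysis.

:class:`BilateralExamModel` is built from one examination's emission and
transmission volumes plus the operator-supplied affected side; ``fit()``
runs segmentation -> reference statistics -> Z mapping -> suprathreshold
metrics and returns an :class:`ExamResults` carrying both arms' metrics,
the intermediate statistics, and a structured log — the audit trail an
observer-independent analysis implies.

:class:`GroupComparison` is built from a collection of examination
records (or the packaged published table); ``fit()`` computes the group
means, the arm contrasts (t-tests in all three modes and the equivalent
unbalanced ANOVA) and the pain-score rank correlations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as group_stats
from .analyze_io import read_analyze_pair
from .errors import InvariantError, PipelineError
from .metrics import (
    DEFAULT_THRESHOLD_SD,
    ArmMetrics,
    SubjectRecord,
    compute_metrics,
)
from .mip import render_mip
from .segmentation import ArmSegmentation, arm_voxel_stats, segment_arms
from .volume import VoxelVolume
from .zscore import ReferenceStats, ZMap, reference_stats, zscore_map


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one unattended per-examination run.

    ``affected_side`` is operator-supplied metadata — the pipeline never
    infers handedness from the signal, which would be circular.
    """

    emission_header: str | PathLike
    emission_image: str | PathLike
    transmission_header: str | PathLike
    transmission_image: str | PathLike
    affected_side: str  # "left" | "right"
    subject_id: str = "subject"
    timepoint: str = "before"
    pain_vas_affected: float | None = None
    pain_vas_unaffected: float | None = None
    threshold_sd: float = DEFAULT_THRESHOLD_SD
    density_threshold: float | None = None
    segmentation_seeds: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None
    per_arm_sd: bool = False

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise InvariantError(
                f"affected_side must be 'left' or 'right', got {self.affected_side!r}"
            )


class BilateralExamModel:
    """One PET examination of both arms, ready to fit.

    Parameters
    ----------
    emission : VoxelVolume
        Radioactivity concentration volume (Bq).
    transmission : VoxelVolume
        Density volume used for segmentation.
    affected_side : {"left", "right"}
        Which arm is symptomatic; the other arm is the reference.
    threshold_sd : float
        Z threshold for suprathreshold extraction (strict ``>``).
    density_threshold : float, optional
        Override for the Otsu segmentation threshold.
    segmentation_seeds : pair of voxel triples, optional
        Semi-automatic segmentation seeds.
    per_arm_sd : bool
        Sensitivity-analysis variant: keep the unaffected-arm mean as
        the Z origin but scale each arm by its own SD. Default False —
        one common reference makes inter-arm Z values comparable.
    """

    def __init__(
        self,
        emission: VoxelVolume,
        transmission: VoxelVolume,
        affected_side: str,
        threshold_sd: float = DEFAULT_THRESHOLD_SD,
        density_threshold: float | None = None,
        segmentation_seeds=None,
        per_arm_sd: bool = False,
        min_component_voxels: int = 100,
    ):
        if affected_side not in ("left", "right"):
            raise InvariantError(
                f"affected_side must be 'left' or 'right', got {affected_side!r}"
            )
        if emission.shape != transmission.shape:
            raise InvariantError("emission and transmission dimensions differ")
        self.emission = emission
        self.transmission = transmission
        self.affected_side = affected_side
        self.unaffected_side = "right" if affected_side == "left" else "left"
        self.threshold_sd = float(threshold_sd)
        self.density_threshold = density_threshold
        self.segmentation_seeds = segmentation_seeds
        self.per_arm_sd = per_arm_sd
        self.min_component_voxels = min_component_voxels

    @classmethod
    def from_analyze(
        cls,
        emission_header,
        emission_image,
        transmission_header,
        transmission_image,
        affected_side: str,
        **kwargs,
    ) -> "BilateralExamModel":
        """Build the model from two Analyze 7.5 pairs on disk."""
        emission = read_analyze_pair(emission_header, emission_image, units="Bq")
        transmission = read_analyze_pair(
            transmission_header, transmission_image, units="density"
        )
        return cls(emission, transmission, affected_side, **kwargs)

    @classmethod
    def from_config(cls, config: RunConfig) -> "BilateralExamModel":
        return cls.from_analyze(
            config.emission_header,
            config.emission_image,
            config.transmission_header,
            config.transmission_image,
            config.affected_side,
            threshold_sd=config.threshold_sd,
            density_threshold=config.density_threshold,
            segmentation_seeds=config.segmentation_seeds,
            per_arm_sd=config.per_arm_sd,
        )

    def fit(self) -> "ExamResults":
        """Run the full per-examination pipeline and return the results."""
        try:
            segmentation = segment_arms(
                self.transmission,
                density_threshold=self.density_threshold,
                seeds=self.segmentation_seeds,
                min_component_voxels=self.min_component_voxels,
            )
        except Exception as exc:
            raise PipelineError("segmentation", exc) from exc

        unaffected_mask = segmentation.mask(self.unaffected_side)
        affected_mask = segmentation.mask(self.affected_side)
        try:
            reference = reference_stats(
                self.emission, unaffected_mask, source=self.unaffected_side
            )
            zmaps = {
                "affected": zscore_map(self.emission, reference),
                "unaffected": zscore_map(self.emission, reference),
            }
            if self.per_arm_sd:
                _, _, sd_aff = arm_voxel_stats(self.emission, affected_mask)
                per_arm_ref = ReferenceStats(
                    mean_bq=reference.mean_bq,
                    sd_bq=sd_aff,
                    n_voxels=reference.n_voxels,
                    source=f"{self.unaffected_side} mean / affected SD",
                )
                zmaps["affected"] = zscore_map(self.emission, per_arm_ref)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("zscore_mapping", exc) from exc

        try:
            metrics = {
                "affected": compute_metrics(
                    self.emission,
                    zmaps["affected"],
                    affected_mask,
                    self.threshold_sd,
                    affected=True,
                    side=self.affected_side,
                ),
                "unaffected": compute_metrics(
                    self.emission,
                    zmaps["unaffected"],
                    unaffected_mask,
                    self.threshold_sd,
                    affected=False,
                    side=self.unaffected_side,
                ),
            }
        except Exception as exc:
            raise PipelineError("suprathreshold_metrics", exc) from exc

        log = {
            "density_threshold": segmentation.density_threshold,
            "component_sizes": segmentation.component_sizes,
            "affected_side": self.affected_side,
            "reference_mean_bq": reference.mean_bq,
            "reference_sd_bq": reference.sd_bq,
            "reference_n_voxels": reference.n_voxels,
            "threshold_sd": self.threshold_sd,
            "per_arm_sd": self.per_arm_sd,
        }
        return ExamResults(
            model=self,
            segmentation=segmentation,
            reference=reference,
            zmaps=zmaps,
            metrics=metrics,
            log=log,
        )


@dataclass(frozen=True)
class ExamResults:
    """Fitted per-examination results: both arms' metrics plus audit log."""

    model: BilateralExamModel
    segmentation: ArmSegmentation
    reference: ReferenceStats
    zmaps: Mapping[str, ZMap]
    metrics: Mapping[str, ArmMetrics]
    log: Mapping[str, object]

    def to_record(
        self,
        subject_id: str = "subject",
        timepoint: str = "before",
        pain_vas_affected: float | None = None,
        pain_vas_unaffected: float | None = None,
    ) -> SubjectRecord:
        """Package the fitted metrics as one examination record."""
        import dataclasses

        aff = dataclasses.replace(self.metrics["affected"], pain_vas=pain_vas_affected)
        unaff = dataclasses.replace(
            self.metrics["unaffected"], pain_vas=pain_vas_unaffected
        )
        return SubjectRecord(
            subject_id=subject_id, timepoint=timepoint, affected=aff, unaffected=unaff
        )

    def render_mip(self, which: str = "zscore", axis="coronal") -> np.ndarray:
        """MIP of the Z map (``zscore``) or the emission volume (``emission``)."""
        vol = self.zmaps["affected"].volume if which == "zscore" else self.model.emission
        return render_mip(vol, axis=axis)

    def summary(self) -> str:
        """Human-readable per-examination report."""
        buf = io.StringIO()
        ref = self.reference
        buf.write("Bilateral-limb PET examination\n")
        buf.write("==============================\n")
        buf.write(
            f"Affected side: {self.model.affected_side}   "
            f"Z threshold: >{self.model.threshold_sd} SD\n"
        )
        buf.write(
            f"Density threshold: {self.log['density_threshold']:.4g}   "
            f"components: {self.log['component_sizes']}\n"
        )
        buf.write(
            f"Reference ({ref.source} arm): mean {ref.mean_bq:.1f} Bq, "
            f"SD {ref.sd_bq:.1f} Bq, n={ref.n_voxels}\n\n"
        )
        buf.write(
            f"{'arm':<12}{'voxels':>8}{'mean Bq':>10}{'SD':>9}"
            f"{'vol mL':>9}{'mean Z':>8}{'VIS':>10}\n"
        )
        for name in ("unaffected", "affected"):
            m = self.metrics[name]
            buf.write(
                f"{name:<12}{m.n_voxels_examined:>8}{m.mean_bq:>10.1f}"
                f"{m.sd_bq:>9.1f}{m.supra_volume_ml:>9.2f}"
                f"{m.supra_mean_z:>8.2f}{m.vis:>10.2f}\n"
            )
        return buf.getvalue()


def run_subject(config: RunConfig) -> SubjectRecord:
    """End-to-end: Analyze pairs on disk -> one examination record."""
    model = BilateralExamModel.from_config(config)
    results = model.fit()
    return results.to_record(
        subject_id=config.subject_id,
        timepoint=config.timepoint,
        pain_vas_affected=config.pain_vas_affected,
        pain_vas_unaffected=config.pain_vas_unaffected,
    )


class GroupComparison:
    """Group-level analysis over a collection of examination records.

    Accepts :class:`SubjectRecord` objects or a flat per-arm DataFrame
    with columns subject, timepoint, arm, pain_vas, examined_voxels,
    mean_bq, sd_bq, volume_ml, mean_z, vis.
    """

    def __init__(self, records: Iterable[SubjectRecord] | pd.DataFrame):
        if isinstance(records, pd.DataFrame):
            self.frame = records.copy()
        else:
            self.frame = group_stats.records_to_frame(list(records))
        if self.frame.empty:
            raise InvariantError("no records supplied")

    @classmethod
    def from_published_table(cls) -> "GroupComparison":
        """Built from the packaged published per-arm results table."""
        from .phantom import table2_frame

        return cls(table2_frame())

    def _paired_columns(self, timepoint: str, column: str):
        df = self.frame[self.frame["timepoint"] == timepoint]
        wide = df.pivot(index="subject", columns="arm", values=column).dropna()
        return wide["affected"].to_numpy(float), wide["unaffected"].to_numpy(float)

    def fit(self) -> "GroupComparisonResults":
        summaries = group_stats.summarize_groups(self.frame)
        contrasts: dict[str, dict[str, group_stats.TestResult]] = {}
        for timepoint in ("before", "after"):
            aff, unaff = self._paired_columns(timepoint, "volume_ml")
            if len(aff) < 2:
                continue
            contrasts[timepoint] = {
                "paired": group_stats.t_test(aff, unaff, "paired"),
                "pooled": group_stats.t_test(aff, unaff, "pooled"),
                "welch": group_stats.t_test(aff, unaff, "welch"),
                "anova": group_stats.oneway_anova_unbalanced([aff, unaff]),
            }
        pain = self.frame["pain_vas"].to_numpy(float)
        vis = self.frame["vis"].to_numpy(float)
        corr_all = group_stats.spearman(pain, vis)
        affected = self.frame[self.frame["arm"] == "affected"]
        corr_affected = group_stats.spearman(
            affected["pain_vas"].to_numpy(float), affected["vis"].to_numpy(float)
        )
        return GroupComparisonResults(
            frame=self.frame,
            group_summaries=summaries,
            volume_contrasts=contrasts,
            spearman_all=corr_all,
            spearman_affected=corr_affected,
        )


@dataclass(frozen=True)
class GroupComparisonResults:
    """Fitted group statistics: means, contrasts and correlations."""

    frame: pd.DataFrame
    group_summaries: list
    volume_contrasts: Mapping[str, Mapping[str, group_stats.TestResult]]
    spearman_all: float
    spearman_affected: float

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.group_summaries:
            rows.append({"group": s.label, "n": s.n, **s.means})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Group summary (column means)\n")
        buf.write("============================\n")
        buf.write(self.summary_frame().to_string(index=False, float_format="%.4g"))
        buf.write("\n\nSuprathreshold-volume contrast (affected vs unaffected)\n")
        buf.write("-------------------------------------------------------\n")
        for timepoint, tests in self.volume_contrasts.items():
            for mode, res in tests.items():
                stat_name = "F" if mode == "anova" else "t"
                buf.write(
                    f"{timepoint:<8}{mode:<8}{stat_name} = {res.statistic:8.3f}  "
                    f"df = {res.degrees_of_freedom:6.2f}  "
                    f"p(two-tailed) = {res.p_two_tailed:.2e}\n"
                )
        buf.write("\nSpearman rank correlation, pain VAS vs Volume intensity score\n")
        buf.write("-------------------------------------------------------------\n")
        buf.write(f"all arms            R = {self.spearman_all:.2f}\n")
        buf.write(f"affected arms only  R = {self.spearman_affected:.2f}\n")
        return buf.getvalue()
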