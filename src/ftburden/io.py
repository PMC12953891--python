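"""NIfTI / CSV input-output and the validated pipeline configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .acquisition import AcquisitionParams
from .synthetic import CohortSpec, PatientPhantom

__all__ = [
    "save_volume",
    "load_volume",
    "write_patient_dir",
    "read_patient_dir",
    "PipelineConfig",
]

DSC_FILE = "dsc_4d.nii.gz"
T1_PRE_FILE = "t1_pre.nii.gz"
T1_POST_FILE = "t1_post.nii.gz"
TRUTH_VOI_FILE = "truth_voi.nii.gz"
TRUTH_RCBV_FILE = "truth_rcbv.nii.gz"
TRUTH_K2_FILE = "truth_k2.nii.gz"


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    """Write an array as NIfTI-1, preserving the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), path)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_patient_dir(patient: PatientPhantom, out_dir: str | Path) -> Path:
    """Write one phantom patient's volumes (and truth maps) to a directory."""
    out = Path(out_dir) / patient.patient_id
    aff = patient.acq.affine
    save_volume(out / DSC_FILE, patient.dsc.astype(np.float32), aff)
    save_volume(out / T1_PRE_FILE, patient.t1_pre.astype(np.float32), aff)
    save_volume(out / T1_POST_FILE, patient.t1_post.astype(np.float32), aff)
    save_volume(out / TRUTH_VOI_FILE, patient.truth.voi_true.astype(np.uint8), aff)
    save_volume(out / TRUTH_RCBV_FILE, patient.truth.rcbv_true.astype(np.float32), aff)
    save_volume(out / TRUTH_K2_FILE, patient.truth.k2_true.astype(np.float32), aff)
    return out


def read_patient_dir(patient_dir: str | Path) -> dict[str, np.ndarray]:
    """Load the acquired volumes of one patient directory.

    Raises a stage-named error if a required volume is missing or the
    grids are inconsistent.
    """
    patient_dir = Path(patient_dir)
    vols = {}
    for key, fname in (("dsc", DSC_FILE), ("t1_pre", T1_PRE_FILE), ("t1_post", T1_POST_FILE)):
        path = patient_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"DSC reader stage: missing input volume {path}")
        try:
            vols[key], vols[f"{key}_affine"] = load_volume(path)
        except Exception as exc:  # corrupted file
            raise ValueError(f"DSC reader stage: cannot read {path}: {exc}") from exc
    if vols["dsc"].ndim != 4:
        raise ValueError("DSC reader stage: dsc_4d must be a 4D volume")
    if vols["dsc"].shape[:3] != vols["t1_pre"].shape or vols["t1_pre"].shape != vols[
        "t1_post"
    ].shape:
        raise ValueError("DSC reader stage: inconsistent volume grids")
    voi_path = patient_dir / TRUTH_VOI_FILE
    if voi_path.exists():
        vols["truth_voi"], _ = load_volume(voi_path)
    return vols


# ---------------------------------------------------------------------------
# configuration


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionBlock(_Block):
    tr_s: float = 1.35
    te_s: float = 0.043
    n_frames: int = 75
    n_baseline: int = 8
    voxel_mm: tuple[float, float, float] = (1.8, 1.8, 5.0)
    grid: tuple[int, int, int] = (32, 32, 15)

    def to_params(self) -> AcquisitionParams:
        return AcquisitionParams(**self.model_dump())


class CohortBlock(_Block):
    n_tp: int = 35
    n_tra: int = 24
    mean_fracs_tp: tuple[float, float, float] = (0.44, 0.19, 0.37)
    mean_fracs_tra: tuple[float, float, float] = (0.60, 0.19, 0.21)
    frac_dispersion: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0

    def to_spec(self) -> CohortSpec:
        return CohortSpec(**self.model_dump())


class LeakageBlock(_Block):
    onset_threshold: float = 0.1


class ScalingBlock(_Block):
    path: Literal["ratio", "standardized"] = "ratio"


class SegmentationBlock(_Block):
    threshold: float | Literal["otsu"] = "otsu"
    min_component_vox: int = 10
    closing_radius: int = 1


class ThresholdBlock(_Block):
    thr_low: float = 1.0
    thr_high: float = 1.6


class StatisticsBlock(_Block):
    n_boot: int = 2000
    n_boot_compare: int = 10000
    seed: int = 0
    level: float = 0.95
    fixed_cutoff_high: float = 24.0
    fixed_cutoff_low: float = 59.0


class PipelineConfig(_Block):
    """Versioned, schema-validated configuration of the whole pipeline.

    Unknown keys are rejected; every stochastic step carries an explicit
    seed (cohort generation under ``cohort.seed``, bootstrap statistics
    under ``statistics.seed``).
    """

    version: int = 1
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    leakage: LeakageBlock = Field(default_factory=LeakageBlock)
    scaling: ScalingBlock = Field(default_factory=ScalingBlock)
    segmentation: SegmentationBlock = Field(default_factory=SegmentationBlock)
    thresholds: ThresholdBlock = Field(default_factory=ThresholdBlock)
    statistics: StatisticsBlock = Field(default_factory=StatisticsBlock)

    @model_validator(mode="after")
    def _check_version(self):
        if self.version != 1:
            raise ValueError(f"unsupported config schema version {self.version}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path


def write_truth_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort truth/summary table as RFC-4180 CSV (UTF-8, header)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\r\n")
    return path
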