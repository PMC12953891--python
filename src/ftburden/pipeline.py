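"""End-to-end FTB quantification for a single patient.

Chains the processing stages: DSC signal → ΔR2* → reference curve →
voxelwise leakage fit → corrected CBV → ratio (or standardized) rCBV,
in parallel ΔT1 → enhancing-lesion VOI, and finally voxel classification
into FTB classes with a per-patient summary. Each stage is logged with
its parameters and timing.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager

import numpy as np

from .acquisition import AcquisitionParams
from .dsc import corrected_cbv, fit_leakage, signal_to_delta_r2star, whole_brain_reference_curve
from .ftb import FtbMap, FtbSummary, FtbThresholds, classify_voxels, summarize_ftb
from .scaling import LandmarkModel, RcbvMap, normalize_to_ratio, standardize_landmarks
from .segmentation import VoiMask, compute_delta_t1, qc_voi, segment_voi

logger = logging.getLogger("ftburden")

__all__ = ["quantify_patient", "PatientResult"]


@contextmanager
def _stage(name: str, **params):
    t0 = time.perf_counter()
    logger.info("stage %s: start %s", name, params or "")
    try:
        yield
    except Exception as exc:
        logger.error("stage %s: failed (%s)", name, exc)
        raise
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


class PatientResult:
    """Container for the per-patient pipeline outputs."""

    def __init__(
        self,
        rcbv: RcbvMap,
        rcbv_uncorrected: RcbvMap,
        voi: VoiMask,
        ftb: FtbMap,
        summary: FtbSummary,
        qc_flags: set[str],
    ):
        self.rcbv = rcbv
        self.rcbv_uncorrected = rcbv_uncorrected
        self.voi = voi
        self.ftb = ftb
        self.summary = summary
        self.qc_flags = qc_flags


def quantify_patient(
    dsc: np.ndarray,
    t1_pre: np.ndarray,
    t1_post: np.ndarray,
    acq: AcquisitionParams,
    thresholds: FtbThresholds | None = None,
    scale_path: str = "ratio",
    landmark_model: LandmarkModel | None = None,
    segmentation_threshold: float | str = "otsu",
    min_component_vox: int = 10,
    closing_radius: int = 1,
    voi_override: np.ndarray | None = None,
    context_masks: dict[str, np.ndarray] | None = None,
    patient_id: str = "",
    label: str = "unknown",
) -> PatientResult:
    """Run the full quantification chain on one patient's volumes.

    ``voi_override`` bypasses ΔT1 segmentation with a user-supplied lesion
    mask (used verbatim). ``scale_path`` selects plain ratio scaling or an
    additional landmark standardization (identity model unless one is
    given). Returns maps, the VOI, the FTB label map and the summary row.
    """
    if thresholds is None:
        thresholds = FtbThresholds()
    if scale_path not in ("ratio", "standardized"):
        raise ValueError("scale_path must be 'ratio' or 'standardized'")

    with _stage("delta_r2star", te_s=acq.te_s, n_baseline=acq.n_baseline):
        dr2 = signal_to_delta_r2star(dsc, acq)
    brain = dr2.valid_mask

    with _stage("delta_t1"):
        dt1 = compute_delta_t1(t1_pre, t1_post, brain)

    if voi_override is not None:
        voi = VoiMask(
            mask=np.asarray(voi_override, dtype=bool),
            volume_ml=float(np.count_nonzero(voi_override)) * acq.voxel_volume_ml,
            threshold=np.nan,
        )
    else:
        with _stage(
            "segment_voi",
            threshold=segmentation_threshold,
            min_component_vox=min_component_vox,
        ):
            voi = segment_voi(
                dt1,
                brain,
                acq.voxel_volume_ml,
                threshold=segmentation_threshold,
                min_component_vox=min_component_vox,
                closing_radius=closing_radius,
            )

    with _stage("reference_curve"):
        reference = whole_brain_reference_curve(dr2, brain, enhancing_mask=voi.mask)

    with _stage("leakage_fit"):
        fit = fit_leakage(dr2, reference)

    with _stage("cbv_integration"):
        cbv = corrected_cbv(dr2, fit, corrected=True)
        cbv_unc = corrected_cbv(dr2, fit, corrected=False)

    with _stage("rcbv_scaling", path=scale_path):
        reference_mask = brain & ~voi.mask
        rcbv = normalize_to_ratio(cbv, reference_mask)
        rcbv_unc = normalize_to_ratio(cbv_unc, reference_mask)
        if scale_path == "standardized":
            model = landmark_model or LandmarkModel.identity(rcbv.values[brain])
            rcbv = standardize_landmarks(rcbv, model)

    with _stage("qc_voi"):
        if not np.isnan(voi.threshold):
            qc_flags = qc_voi(
                voi,
                dt1,
                brain,
                context_masks=context_masks,
                invalid_mask=~dr2.valid_mask,
            )
        else:
            qc_flags = set()

    with _stage("ftb_classification", thr_low=thresholds.thr_low, thr_high=thresholds.thr_high):
        ftb = classify_voxels(rcbv, voi, thresholds)
        summary = summarize_ftb(ftb, acq.voxel_volume_ml, patient_id, label)

    return PatientResult(rcbv, rcbv_unc, voi, ftb, summary, qc_flags)
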