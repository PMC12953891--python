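"""Enhancement mapping and lesion VOI extraction from T1-weighted volumes.

The contrast-enhancing lesion is delineated on the ΔT1 map — the
gain-aligned difference of post- and pre-contrast T1 volumes — by
thresholding (Otsu by default), 26-connected component filtering and a
light morphological closing. Quality rules that a human reader would
apply (artefact-affected signal, overlap with non-pathological
structures, incomplete lesion coverage) are implemented as advisory QC
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball, closing

__all__ = [
    "DeltaT1Map",
    "VoiMask",
    "compute_delta_t1",
    "segment_voi",
    "qc_voi",
    "rigid_align_translation",
]

QC_SIGNAL_ARTIFACT = "signal_artifact"
QC_NON_PATHOLOGICAL = "non_pathological_overlap"
QC_INCOMPLETE_COVERAGE = "incomplete_coverage"


@dataclass
class DeltaT1Map:
    """Post-minus-pre contrast T1 difference after gain alignment."""

    values: np.ndarray
    alignment: str
    gain: float


@dataclass
class VoiMask:
    """Binary lesion volume of interest with QC metadata."""

    mask: np.ndarray
    volume_ml: float
    threshold: float
    qc_flags: set[str] = field(default_factory=set)


def compute_delta_t1(
    t1_pre: np.ndarray,
    t1_post: np.ndarray,
    brain_mask: np.ndarray,
    alignment: str = "identity",
) -> DeltaT1Map:
    """Subtract aligned T1 volumes to expose contrast enhancement.

    A global multiplicative gain — the ratio of within-brain median
    intensities — is applied to the post-contrast volume first, so the
    map is invariant to overall receiver-gain differences between the two
    acquisitions. The median is robust to the (small) enhancing lesion.
    Only identity alignment is supported here; rigidly align volumes with
    :func:`rigid_align_translation` beforehand if needed.
    """
    if alignment not in ("identity", "rigid"):
        raise ValueError("alignment must be 'identity' or 'rigid'")
    t1_pre = np.asarray(t1_pre, dtype=float)
    t1_post = np.asarray(t1_post, dtype=float)
    if t1_pre.shape != t1_post.shape or t1_pre.shape != brain_mask.shape:
        raise ValueError("T1 volumes and brain mask must share one grid")
    med_pre = np.median(t1_pre[brain_mask])
    med_post = np.median(t1_post[brain_mask])
    if med_post <= 0 or med_pre <= 0:
        raise ValueError("non-positive median brain intensity; cannot align gains")
    gain = med_pre / med_post
    return DeltaT1Map(values=gain * t1_post - t1_pre, alignment=alignment, gain=gain)


def segment_voi(
    dt1: DeltaT1Map,
    brain_mask: np.ndarray,
    voxel_volume_ml: float,
    threshold: float | str = "otsu",
    min_component_vox: int = 10,
    closing_radius: int = 1,
) -> VoiMask:
    """Threshold the ΔT1 map into the contrast-enhancing lesion VOI.

    Voxels above the threshold (Otsu within the brain by default, or a
    fixed value) are grouped into 26-connected components; components
    smaller than ``min_component_vox`` are dropped and a morphological
    closing with a 1-voxel-radius ball fills pinholes.
    """
    values = np.asarray(dt1.values, dtype=float)
    if not np.all(np.isfinite(values[brain_mask])):
        raise ValueError("ΔT1 map contains non-finite values inside the brain")
    inside = values[brain_mask]
    if threshold == "otsu":
        if np.ptp(inside) == 0:
            raise ValueError("no enhancing lesion found (flat ΔT1 map)")
        thr = float(threshold_otsu(inside))
    else:
        thr = float(threshold)
    raw = (values > thr) & brain_mask
    if not raw.any():
        raise ValueError("no enhancing lesion found")
    comps = cc_label(raw, connectivity=3)
    sizes = np.bincount(comps.ravel())
    keep = np.flatnonzero(sizes >= min_component_vox)
    keep = keep[keep != 0]
    if keep.size == 0:
        raise ValueError("no enhancing lesion found (all components below size filter)")
    mask = np.isin(comps, keep)
    if closing_radius > 0:
        mask = closing(mask, ball(closing_radius)) | mask
    mask &= brain_mask
    return VoiMask(
        mask=mask,
        volume_ml=float(mask.sum()) * voxel_volume_ml,
        threshold=thr,
    )


def qc_voi(
    voi: VoiMask,
    dt1: DeltaT1Map,
    brain_mask: np.ndarray,
    context_masks: dict[str, np.ndarray] | None = None,
    invalid_mask: np.ndarray | None = None,
    overlap_tol: float = 0.02,
    coverage_tol: float = 0.05,
) -> set[str]:
    """Run the automated segmentation quality rules; returns raised flags.

    * ``signal_artifact`` — any VOI voxel was flagged signal-invalid
      upstream (e.g. susceptibility dropout in the DSC series).
    * ``non_pathological_overlap`` — the VOI overlaps a supplied
      non-pathological structure mask (ventricles, vessels, meninges) by
      more than ``overlap_tol`` of its volume.
    * ``incomplete_coverage`` — more than ``coverage_tol`` of the
      supra-threshold ΔT1 voxels lie outside the VOI.

    Flags are advisory; they are also recorded on ``voi.qc_flags``.
    """
    flags: set[str] = set()
    n_voi = int(voi.mask.sum())
    if n_voi == 0:
        raise ValueError("cannot QC an empty VOI")
    if invalid_mask is not None and np.any(voi.mask & invalid_mask):
        flags.add(QC_SIGNAL_ARTIFACT)
    for mask in (context_masks or {}).values():
        if np.count_nonzero(voi.mask & mask) > overlap_tol * n_voi:
            flags.add(QC_NON_PATHOLOGICAL)
            break
    enhancing = (np.asarray(dt1.values) > voi.threshold) & brain_mask
    n_enh = int(enhancing.sum())
    if n_enh > 0 and np.count_nonzero(enhancing & ~voi.mask) > coverage_tol * n_enh:
        flags.add(QC_INCOMPLETE_COVERAGE)
    voi.qc_flags |= flags
    return flags


def rigid_align_translation(
    moving: np.ndarray, fixed: np.ndarray, max_shift: int = 3
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Integer-translation alignment by exhaustive SSD grid search.

    A deliberately thin utility: phantoms are generated co-registered, so
    identity is the default path and this covers small residual shifts
    only (no rotation, no subvoxel interpolation).
    """
    best = None
    rng = range(-max_shift, max_shift + 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                shifted = np.roll(moving, (dx, dy, dz), axis=(0, 1, 2))
                ssd = float(np.sum((shifted - fixed) ** 2))
                if best is None or ssd < best[0]:
                    best = (ssd, (dx, dy, dz), shifted)
    _, shift, shifted = best
    return shifted, shift
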