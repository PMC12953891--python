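"""Fractional tumor burden: voxel classification, summaries and rendering.

Within the enhancing-lesion VOI each voxel's rCBV ratio is assigned to one
of three burden classes:

* FTB_low  — rCBV ≤ 1.0 (includes negative post-correction values)
* FTB_mid  — 1.0 < rCBV < 1.6
* FTB_high — rCBV ≥ 1.6

Both boundary values are closed on the outer classes by definition. The
per-lesion FTB fractions (percent of VOI voxels per class) are the
diagnostic quantities carried into the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .scaling import RcbvMap
from .segmentation import VoiMask

__all__ = [
    "FtbThresholds",
    "FtbMap",
    "FtbSummary",
    "FtbVoxelClassifier",
    "classify_voxels",
    "summarize_ftb",
    "render_outputs",
    "CLASS_NAMES",
    "CLASS_COLORS",
]

CLASS_NAMES = ("low", "mid", "high")
#: rendering convention: red = high, yellow = mid, blue = low
CLASS_COLORS = {"low": (0, 0, 255), "mid": (255, 255, 0), "high": (255, 0, 0)}
OUTSIDE = -1


@dataclass(frozen=True)
class FtbThresholds:
    """The two rCBV ratio thresholds separating the burden classes."""

    thr_low: float = 1.0
    thr_high: float = 1.6

    def __post_init__(self) -> None:
        if not 0 < self.thr_low < self.thr_high:
            raise ValueError("thresholds must satisfy 0 < thr_low < thr_high")


class FtbVoxelClassifier(ClassifierMixin, BaseEstimator):
    """Threshold classifier mapping rCBV values to burden classes 0/1/2.

    Stateless by design — ``fit`` only records the class set — so it can
    sit at the end of an sklearn pipeline operating on rCBV features.
    Class indices follow :data:`CLASS_NAMES` (0 = low, 1 = mid, 2 = high).
    """

    def __init__(self, thr_low: float = 1.0, thr_high: float = 1.6):
        self.thr_low = thr_low
        self.thr_high = thr_high

    def fit(self, X, y=None):
        FtbThresholds(self.thr_low, self.thr_high)
        self.classes_ = np.array([0, 1, 2])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        labels = np.full(x.shape, 1, dtype=np.int8)
        labels[x <= self.thr_low] = 0
        labels[x >= self.thr_high] = 2
        return labels


@dataclass
class FtbMap:
    """Per-voxel class labels over the VOI (−1 outside)."""

    labels: np.ndarray
    voi: np.ndarray
    thresholds: FtbThresholds
    source_scale: str


@dataclass
class FtbSummary:
    """Per-patient FTB class counts, percentages and VOI volume."""

    n_low: int
    n_mid: int
    n_high: int
    pct_low: float
    pct_mid: float
    pct_high: float
    voi_volume_ml: float
    patient_id: str = ""
    label: str = "unknown"

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_low, self.n_mid, self.n_high])

    @property
    def percentages(self) -> np.ndarray:
        return np.array([self.pct_low, self.pct_mid, self.pct_high])

    def as_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "label": self.label,
            "pct_low": self.pct_low,
            "pct_mid": self.pct_mid,
            "pct_high": self.pct_high,
            "voi_volume_ml": self.voi_volume_ml,
        }


def classify_voxels(
    rcbv: RcbvMap, voi: VoiMask | np.ndarray, thr: FtbThresholds | None = None
) -> FtbMap:
    """Assign every VOI voxel to an FTB class by its rCBV ratio.

    Raw-scale maps are rejected: the thresholds are defined on the ratio
    (or standardized-ratio) scale only.
    """
    if thr is None:
        thr = FtbThresholds()
    if rcbv.scale == "raw":
        raise ValueError("cannot threshold a raw-scale CBV map; normalise it first")
    mask = voi.mask if isinstance(voi, VoiMask) else np.asarray(voi, dtype=bool)
    if mask.shape != rcbv.values.shape:
        raise ValueError("VOI and rCBV grids do not match")
    clf = FtbVoxelClassifier(thr.thr_low, thr.thr_high).fit(np.zeros((1, 1)))
    labels = np.full(mask.shape, OUTSIDE, dtype=np.int8)
    labels[mask] = clf.predict(rcbv.values[mask])
    return FtbMap(labels=labels, voi=mask, thresholds=thr, source_scale=rcbv.scale)


def summarize_ftb(
    ftb: FtbMap,
    voxel_volume_ml: float,
    patient_id: str = "",
    label: str = "unknown",
) -> FtbSummary:
    """Tally exact class counts and VOI percentages for one lesion."""
    n_total = int(ftb.voi.sum())
    if n_total == 0:
        raise ValueError("empty VOI")
    inside = ftb.labels[ftb.voi]
    counts = np.bincount(inside, minlength=3)
    pct = 100.0 * counts / n_total
    return FtbSummary(
        n_low=int(counts[0]),
        n_mid=int(counts[1]),
        n_high=int(counts[2]),
        pct_low=float(pct[0]),
        pct_mid=float(pct[1]),
        pct_high=float(pct[2]),
        voi_volume_ml=n_total * voxel_volume_ml,
        patient_id=patient_id,
        label=label,
    )


def render_outputs(
    ftb: FtbMap,
    t1_post: np.ndarray,
    affine: np.ndarray,
    out_dir: str | Path,
    basename: str = "ftb",
    slice_png: bool = True,
) -> dict[str, Path]:
    """Write the FTB label volume, class histogram and RGB overlay.

    Outputs: ``<basename>_labels.nii.gz`` (int8 labels, −1 outside the
    VOI), ``<basename>_histogram.csv`` (per-class voxel counts), a 4D
    uint8 RGB overlay NIfTI blending the grayscale post-contrast T1 with
    the class colours (red high / yellow mid / blue low), and optionally
    a mid-lesion axial slice PNG.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    labels_img = nib.Nifti1Image(ftb.labels.astype(np.int8), affine)
    paths["labels"] = out_dir / f"{basename}_labels.nii.gz"
    nib.save(labels_img, paths["labels"])

    inside = ftb.labels[ftb.voi]
    counts = np.bincount(inside, minlength=3)
    hist = pd.DataFrame(
        {"ftb_class": CLASS_NAMES, "n_voxels": counts, "pct_voi": 100 * counts / inside.size}
    )
    paths["histogram"] = out_dir / f"{basename}_histogram.csv"
    hist.to_csv(paths["histogram"], index=False)

    t1 = np.asarray(t1_post, dtype=float)
    lo, hi = np.percentile(t1, [1, 99])
    gray = np.clip((t1 - lo) / max(hi - lo, 1e-12), 0, 1) * 255
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    for idx, name in enumerate(CLASS_NAMES):
        rgb[ftb.labels == idx] = CLASS_COLORS[name]
    rgb = rgb.astype(np.uint8)
    overlay_img = nib.Nifti1Image(rgb, affine)
    paths["overlay"] = out_dir / f"{basename}_overlay.nii.gz"
    nib.save(overlay_img, paths["overlay"])

    if slice_png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        zs = np.flatnonzero(ftb.voi.any(axis=(0, 1)))
        z = int(zs[len(zs) // 2]) if zs.size else ftb.voi.shape[2] // 2
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(np.rot90(rgb[:, :, z]), interpolation="nearest")
        ax.set_axis_off()
        ax.set_title(f"FTB overlay, slice {z}")
        paths["slice_png"] = out_dir / f"{basename}_overlay_z{z}.png"
        fig.savefig(paths["slice_png"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths
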