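"""DSC signal conversion and leakage-corrected cerebral blood volume.

The processing chain is: signal → ΔR2* via the log-ratio relation, a
whole-brain reference curve from non-enhancing tissue, a per-voxel linear
fit of each ΔR2* curve on the reference curve and its running integral
(the two-parameter extravasation model), and finally CBV as the time
integral of the leakage-corrected curve.

The numerics live in two scikit-learn style estimators operating on
``(n_voxels, n_frames)`` arrays — :class:`DeltaR2Star` and
:class:`LeakageCorrector` — while the module-level functions wrap them for
whole 4D volumes with masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .acquisition import AcquisitionParams

__all__ = [
    "DeltaR2Star",
    "LeakageCorrector",
    "DeltaR2Series",
    "LeakageFit",
    "CbvMap",
    "signal_to_delta_r2star",
    "whole_brain_reference_curve",
    "fit_leakage",
    "corrected_cbv",
]


class DeltaR2Star(TransformerMixin, BaseEstimator):
    """Convert DSC signal curves to ΔR2* curves.

    Each row of ``X`` is one voxel's signal time course; the transform is
    ``ΔR2*(t) = -ln(S(t)/S0) / TE`` with S0 the mean over the baseline
    frames. Rows whose baseline mean or any sample is non-positive cannot
    be log-converted and are returned as all-zero; :meth:`valid_rows`
    identifies them.

    Parameters
    ----------
    te_s : float
        Echo time in seconds.
    baseline_frames : int
        Number of leading pre-bolus frames averaged into S0.
    """

    def __init__(self, te_s: float = 0.043, baseline_frames: int = 8):
        self.te_s = te_s
        self.baseline_frames = baseline_frames

    def fit(self, X, y=None):
        X = check_array(X)
        if not 0 < self.baseline_frames < X.shape[1]:
            raise ValueError("baseline_frames must lie strictly inside the series")
        self.n_features_in_ = X.shape[1]
        return self

    def valid_rows(self, X) -> np.ndarray:
        X = check_array(X)
        s0 = X[:, : self.baseline_frames].mean(axis=1)
        return (s0 > 0) & np.all(X > 0, axis=1)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X)
        valid = self.valid_rows(X)
        s0 = X[:, : self.baseline_frames].mean(axis=1)
        out = np.zeros_like(X, dtype=float)
        if np.any(valid):
            out[valid] = -np.log(X[valid] / s0[valid, None]) / self.te_s
        return out


class LeakageCorrector(BaseEstimator):
    """Two-parameter linear extravasation model for ΔR2* curves.

    Fitting learns the reference curve (frame-wise mean of the supplied
    non-enhancing voxel curves, unless a curve is passed explicitly), its
    running time integral, and the post-onset fit window — the frames from
    the first point where the reference exceeds ``onset_threshold`` of its
    peak. Each voxel curve is then regressed on
    ``[reference(t), -∫reference]`` giving a perfusion scale ``k1`` and a
    leakage coefficient ``k2``; the corrected curve adds the fitted
    leakage term back, and CBV is its trapezoidal time integral over the
    fit window.

    Parameters
    ----------
    tr_s : float
        Frame spacing in seconds.
    onset_threshold : float
        Fraction of the reference peak defining bolus onset.

    Attributes
    ----------
    reference_curve_ : ndarray of shape (n_frames,)
    leak_integral_ : ndarray of shape (n_frames,)
        Running trapezoidal integral of the reference curve.
    onset_frame_ : int
    reference_cbv_ : float
        Time integral of the reference curve over the fit window; the CBV
        a unit-rCBV voxel would have.
    """

    def __init__(self, tr_s: float = 1.35, onset_threshold: float = 0.1):
        self.tr_s = tr_s
        self.onset_threshold = onset_threshold

    def fit(self, X, y=None, reference: np.ndarray | None = None):
        if reference is None:
            X = check_array(X)
            reference = X.mean(axis=0)
        reference = np.asarray(reference, dtype=float).ravel()
        peak = reference.max()
        if peak <= 0:
            raise ValueError(
                "degenerate reference curve: voxelwise leakage fit is unidentifiable"
            )
        self.reference_curve_ = reference
        self.leak_integral_ = cumulative_trapezoid(reference, dx=self.tr_s, initial=0.0)
        self.onset_frame_ = int(np.argmax(reference > self.onset_threshold * peak))
        design = np.column_stack(
            [
                reference[self.onset_frame_ :],
                -self.leak_integral_[self.onset_frame_ :],
            ]
        )
        if np.linalg.matrix_rank(design) < 2:
            raise ValueError(
                "rank-deficient regressors: voxelwise leakage fit is unidentifiable"
            )
        self._design = design
        self._design_pinv = np.linalg.pinv(design)
        self.reference_cbv_ = float(
            np.trapezoid(reference[self.onset_frame_ :], dx=self.tr_s)
        )
        self.n_features_in_ = reference.size
        return self

    def coefficients(self, X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-voxel (k1, k2, residual RMS) of the linear leakage fit."""
        check_is_fitted(self)
        X = check_array(X)
        y = X[:, self.onset_frame_ :]
        beta = y @ self._design_pinv.T
        resid = y - beta @ self._design.T
        rms = np.sqrt(np.mean(resid**2, axis=1))
        return beta[:, 0], beta[:, 1], rms

    def cbv(self, X, corrected: bool = True) -> np.ndarray:
        """Per-voxel CBV (integral of the, optionally corrected, curve)."""
        check_is_fitted(self)
        X = check_array(X)
        curves = X[:, self.onset_frame_ :]
        if corrected:
            _, k2, _ = self.coefficients(X)
            curves = curves + k2[:, None] * self.leak_integral_[self.onset_frame_ :]
        return np.trapezoid(curves, dx=self.tr_s, axis=1)

    def transform(self, X) -> np.ndarray:
        """Corrected CBV as a single-column feature matrix."""
        return self.cbv(X, corrected=True)[:, None]


# ---------------------------------------------------------------------------
# volume-level wrappers


@dataclass
class DeltaR2Series:
    """4D ΔR2* array with the validity mask and provenance metadata."""

    values: np.ndarray
    valid_mask: np.ndarray
    baseline_window: tuple[int, int]
    acq: AcquisitionParams


@dataclass
class LeakageFit:
    """Voxel maps of the leakage model coefficients plus the reference."""

    k1: np.ndarray
    k2: np.ndarray
    reference_curve: np.ndarray
    residual_rms: np.ndarray
    onset_frame: int
    reference_cbv: float


@dataclass
class CbvMap:
    """3D CBV map in arbitrary units (integral of corrected ΔR2*)."""

    values: np.ndarray
    corrected: bool
    brain_mask: np.ndarray


def signal_to_delta_r2star(
    dsc: np.ndarray,
    acq: AcquisitionParams,
    baseline_window: tuple[int, int] | None = None,
) -> DeltaR2Series:
    """Convert a 4D DSC series to ΔR2*, flagging unconvertible voxels.

    ``baseline_window`` is a half-open frame range; it defaults to
    ``(0, acq.n_baseline)``. Voxels whose baseline mean or any sample is
    non-positive (air, signal dropout) are excluded from the valid mask
    and zero-filled.
    """
    dsc = np.asarray(dsc, dtype=float)
    if dsc.ndim != 4:
        raise ValueError("dsc must be a 4D (x, y, z, t) array")
    if baseline_window is None:
        baseline_window = (0, acq.n_baseline)
    lo, hi = baseline_window
    if not (0 <= lo < hi <= dsc.shape[-1]):
        raise ValueError("baseline window empty or out of range")
    if lo != 0:
        raise ValueError("baseline window must start at frame 0")
    grid = dsc.shape[:3]
    flat = dsc.reshape(-1, dsc.shape[-1])
    est = DeltaR2Star(te_s=acq.te_s, baseline_frames=hi).fit(flat)
    values = est.transform(flat).reshape(dsc.shape)
    valid = est.valid_rows(flat).reshape(grid)
    return DeltaR2Series(values, valid, baseline_window, acq)


def whole_brain_reference_curve(
    dr2: DeltaR2Series,
    brain_mask: np.ndarray | None = None,
    enhancing_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Frame-wise mean ΔR2* over non-enhancing brain voxels.

    This is the reference tissue curve the leakage fit regresses against;
    enhancing voxels are excluded so extravasation does not contaminate
    the reference.
    """
    mask = dr2.valid_mask if brain_mask is None else brain_mask & dr2.valid_mask
    if enhancing_mask is not None:
        mask = mask & ~enhancing_mask
    if not np.any(mask):
        raise ValueError("no voxels available to average a reference curve from")
    return dr2.values[mask].mean(axis=0)


def fit_leakage(dr2: DeltaR2Series, reference: np.ndarray) -> LeakageFit:
    """Fit the two-parameter leakage model at every valid voxel."""
    est = LeakageCorrector(tr_s=dr2.acq.tr_s).fit(None, reference=reference)
    grid = dr2.values.shape[:3]
    flat = dr2.values.reshape(-1, dr2.values.shape[-1])
    k1, k2, rms = est.coefficients(flat)
    invalid = ~dr2.valid_mask.ravel()
    for arr in (k1, k2, rms):
        arr[invalid] = 0.0
    return LeakageFit(
        k1=k1.reshape(grid),
        k2=k2.reshape(grid),
        reference_curve=est.reference_curve_,
        residual_rms=rms.reshape(grid),
        onset_frame=est.onset_frame_,
        reference_cbv=est.reference_cbv_,
    )


def corrected_cbv(
    dr2: DeltaR2Series, fit: LeakageFit, corrected: bool = True
) -> CbvMap:
    """Integrate (corrected) ΔR2* into a CBV map, zero outside the brain.

    With ``corrected=False`` the leakage term is omitted, reproducing the
    uncorrected CBV that is biased low wherever contrast extravasates.
    Negative values are retained; they are handled at the scaling stage.
    """
    if fit.k2.shape != dr2.values.shape[:3]:
        raise ValueError("leakage fit grid does not match the ΔR2* series")
    est = LeakageCorrector(tr_s=dr2.acq.tr_s).fit(None, reference=fit.reference_curve)
    flat = dr2.values.reshape(-1, dr2.values.shape[-1])
    if corrected:
        curves = flat[:, est.onset_frame_ :] + fit.k2.reshape(-1, 1) * est.leak_integral_[
            est.onset_frame_ :
        ]
    else:
        curves = flat[:, est.onset_frame_ :]
    values = np.trapezoid(curves, dx=dr2.acq.tr_s, axis=1).reshape(dr2.values.shape[:3])
    values[~dr2.valid_mask] = 0.0
    return CbvMap(values=values, corrected=corrected, brain_mask=dr2.valid_mask.copy())
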