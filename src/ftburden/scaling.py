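"""Put CBV on the ratio scale where the FTB thresholds are meaningful.

Two steps are offered: reference-region ratio normalisation (divide by the
mean CBV of non-enhancing brain, making reference tissue 1.0 by
construction) and an optional histogram-landmark intensity
standardisation, a piecewise-linear monotone remapping through matched
percentile landmarks. The default pipeline thresholds ratio-scaled maps;
the standardisation path exists for cross-scanner harmonisation and
defaults to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .dsc import CbvMap

__all__ = [
    "RcbvMap",
    "LandmarkModel",
    "RatioNormalizer",
    "LandmarkStandardizer",
    "normalize_to_ratio",
    "standardize_landmarks",
]

DECILES = tuple(range(0, 101, 10))


@dataclass
class RcbvMap:
    """3D relative CBV map with a mandatory scale tag.

    ``scale`` is one of ``raw`` (integrator output, arbitrary units),
    ``ratio`` (reference tissue ≡ 1) or ``standardized`` (landmark-mapped
    ratio scale). ``reference_value`` is the mean raw CBV of the reference
    region used for ratio scaling.
    """

    values: np.ndarray
    scale: str
    reference_value: float
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "ratio", "standardized"):
            raise ValueError(f"unknown rCBV scale tag {self.scale!r}")


def _piecewise_monotone_map(
    x: np.ndarray, source: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Piecewise-linear map through (source, target) landmarks.

    Values beyond the outer landmarks are extrapolated with the slope of
    the adjacent segment, keeping the transform strictly monotone.
    """
    out = np.interp(x, source, target)
    lo_slope = (target[1] - target[0]) / (source[1] - source[0])
    hi_slope = (target[-1] - target[-2]) / (source[-1] - source[-2])
    below = x < source[0]
    above = x > source[-1]
    out[below] = target[0] + (x[below] - source[0]) * lo_slope
    out[above] = target[-1] + (x[above] - source[-1]) * hi_slope
    return out


@dataclass(frozen=True)
class LandmarkModel:
    """Matched percentile landmarks: source scale → standard scale."""

    source_values: tuple[float, ...]
    standard_values: tuple[float, ...]
    percentiles: tuple[float, ...] = DECILES

    def __post_init__(self) -> None:
        s = np.asarray(self.source_values, dtype=float)
        t = np.asarray(self.standard_values, dtype=float)
        if s.size != t.size or s.size < 2:
            raise ValueError("landmark model needs matched pairs (at least two)")
        if np.any(np.diff(s) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("landmark model must be strictly monotone")

    @classmethod
    def identity(cls, values: np.ndarray, percentiles=DECILES) -> "LandmarkModel":
        """Model whose landmarks map a distribution onto itself."""
        marks = np.percentile(values, percentiles)
        # collapse duplicate landmarks so the model stays strictly monotone
        marks = np.unique(marks)
        if marks.size < 2:
            marks = np.array([marks[0], marks[0] + 1.0])
        return cls(tuple(marks), tuple(marks), tuple(percentiles))

    @classmethod
    def from_samples(
        cls, source: np.ndarray, standard: np.ndarray, percentiles=DECILES
    ) -> "LandmarkModel":
        """Match the percentiles of a source sample to a standard sample."""
        s = np.percentile(source, percentiles)
        t = np.percentile(standard, percentiles)
        keep = np.concatenate([[True], (np.diff(s) > 0) & (np.diff(t) > 0)])
        return cls(tuple(s[keep]), tuple(t[keep]), tuple(np.asarray(percentiles)[keep]))

    def apply(self, values: np.ndarray) -> np.ndarray:
        return _piecewise_monotone_map(
            np.asarray(values, dtype=float),
            np.asarray(self.source_values),
            np.asarray(self.standard_values),
        )


class RatioNormalizer(TransformerMixin, BaseEstimator):
    """Scale CBV so the learned reference mean becomes 1.

    ``fit`` records the mean of the supplied reference-region values;
    ``transform`` divides by it. Ratio scaling is idempotent: a map whose
    reference mean is already 1 is returned unchanged.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False)
        ref = float(np.mean(X))
        if ref <= 0:
            raise ValueError("degenerate reference region: non-positive mean CBV")
        self.reference_value_ = ref
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        check_is_fitted(self)
        return np.asarray(X, dtype=float) / self.reference_value_


class LandmarkStandardizer(TransformerMixin, BaseEstimator):
    """Histogram-landmark intensity standardisation.

    ``fit`` learns the percentile landmarks of the training intensities
    and pairs them with ``standard_values`` (defaults to the learned
    landmarks themselves, i.e. the identity model); ``transform`` applies
    the piecewise-linear monotone map. Analogous to percentile-matching
    normalisation used to harmonise MR intensities across scanners.

    Parameters
    ----------
    percentiles : sequence of float
        Landmark percentiles (default deciles, 0–100).
    standard_values : sequence of float or None
        Target landmark intensities on the standard scale.
    """

    def __init__(self, percentiles=DECILES, standard_values=None):
        self.percentiles = percentiles
        self.standard_values = standard_values

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False)
        if self.standard_values is None:
            self.model_ = LandmarkModel.identity(X.ravel(), self.percentiles)
        else:
            source = np.percentile(X.ravel(), self.percentiles)
            keep = np.concatenate([[True], np.diff(source) > 0])
            std = np.asarray(self.standard_values, dtype=float)[keep]
            self.model_ = LandmarkModel(
                tuple(source[keep]), tuple(std), tuple(np.asarray(self.percentiles)[keep])
            )
        self.n_features_in_ = X.shape[-1] if X.ndim > 1 else 1
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return self.model_.apply(X)


def normalize_to_ratio(cbv: CbvMap | RcbvMap, reference_mask: np.ndarray) -> RcbvMap:
    """Normalise a CBV map by the mean over a reference region.

    Negative CBV values (possible after leakage correction) map to
    negative ratios and are classified as FTB_low downstream.
    """
    values = np.asarray(cbv.values, dtype=float)
    if not np.any(reference_mask):
        raise ValueError("reference mask is empty")
    norm = RatioNormalizer().fit(values[reference_mask])
    brain = getattr(cbv, "brain_mask", None)
    return RcbvMap(
        values=norm.transform(values),
        scale="ratio",
        reference_value=norm.reference_value_,
        brain_mask=brain,
    )


def standardize_landmarks(rcbv: RcbvMap, model: LandmarkModel) -> RcbvMap:
    """Map an rCBV map through a matched-percentile landmark model."""
    return RcbvMap(
        values=model.apply(rcbv.values),
        scale="standardized",
        reference_value=rcbv.reference_value,
        brain_mask=rcbv.brain_mask,
    )
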