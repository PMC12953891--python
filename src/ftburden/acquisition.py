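"""Acquisition geometry and timing for the dynamic susceptibility contrast series.

The defaults reproduce a 1.5-T gradient-echo EPI perfusion protocol:
TR 1.35 s, TE 43 ms, 75 dynamic frames, 1.8 x 1.8 x 5.0 mm voxels.
The in-plane matrix defaults to a desk-scale 32 x 32 x 15 grid so that a
whole synthetic cohort can be processed in seconds; real acquisitions use
larger matrices but the processing is resolution-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionParams"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and geometry of a DSC acquisition.

    Parameters
    ----------
    tr_s : float
        Repetition time (frame spacing) in seconds.
    te_s : float
        Echo time in seconds; converts signal ratios to ΔR2* via
        ``-ln(S/S0)/TE``.
    n_frames : int
        Number of dynamic frames.
    n_baseline : int
        Number of pre-bolus frames used to estimate the baseline signal S0.
    voxel_mm : tuple of float
        Voxel edge lengths (x, y, z) in millimetres.
    grid : tuple of int
        Volume dimensions in voxels.
    """

    tr_s: float = 1.35
    te_s: float = 0.043
    n_frames: int = 75
    n_baseline: int = 8
    voxel_mm: tuple[float, float, float] = (1.8, 1.8, 5.0)
    grid: tuple[int, int, int] = (32, 32, 15)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.te_s <= 0:
            raise ValueError("te_s must be positive")
        if self.n_baseline < 3:
            raise ValueError("n_baseline must be at least 3")
        if self.n_baseline >= self.n_frames:
            raise ValueError("n_baseline must be smaller than n_frames")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be three positive lengths")
        if len(self.grid) != 3 or any(g <= 0 for g in self.grid):
            raise ValueError("grid must be three positive dimensions")

    @property
    def frame_times_s(self) -> np.ndarray:
        """Mid-frame acquisition times, frame 0 at t = 0."""
        return np.arange(self.n_frames) * self.tr_s

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres."""
        return float(np.prod(self.voxel_mm)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """RAS affine mapping voxel indices to mm, origin at the corner."""
        aff = np.diag([*self.voxel_mm, 1.0])
        return aff
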