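"""Frame selection: FSC-average plateau detection and best-quality pick.

As the adaptive force grows, map agreement keeps inching upward while
stereochemistry degrades, so the refined model is not the last frame but the
one with the best (lowest) quality score among frames whose FSC-average sits
on the plateau — within a relative tolerance epsilon of the trajectory
maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from densfit.fitting_engine import FitTrajectory

__all__ = ["SelectionResult", "detect_plateau", "select_best_frame"]

DEFAULT_EPSILON = 0.01


@dataclass
class SelectionResult:
    """Outcome of plateau-constrained frame selection."""

    frame_index: int
    plateau_indices: list
    fsc_avg_max: float
    quality_at_selection: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.frame_index not in self.plateau_indices:
            raise ValueError("selected frame must lie on the plateau")

    def summary(self) -> dict:
        return {
            "frame_index": int(self.frame_index),
            "plateau_first": int(min(self.plateau_indices)),
            "plateau_last": int(max(self.plateau_indices)),
            "plateau_size": len(self.plateau_indices),
            "fsc_avg_max": float(self.fsc_avg_max),
            "quality_at_selection": float(self.quality_at_selection),
            "epsilon": float(self.epsilon),
        }


def _fsc_series(traj: FitTrajectory) -> np.ndarray:
    return np.array([f.fsc_avg for f in traj.frames])


def detect_plateau(traj: FitTrajectory, epsilon: float = DEFAULT_EPSILON) -> list:
    """Indices of frames whose FSC-average is within epsilon of the maximum.

    The plateau is the superlevel set ``fsc_avg >= (1 - epsilon) * max``;
    it is not required to be contiguous in time.
    """
    if traj.n_frames < 3:
        raise ValueError("plateau detection needs at least 3 frames")
    fsc = _fsc_series(traj)
    top = fsc.max()
    plateau = np.flatnonzero(fsc >= (1.0 - epsilon) * top)
    if len(plateau) == traj.n_frames and np.ptp(fsc) == 0:
        warnings.warn("all frames share the same FSC-average; "
                      "degenerate plateau spans the whole trajectory",
                      stacklevel=2)
    return [int(i) for i in plateau]


def select_best_frame(traj: FitTrajectory,
                      epsilon: float = DEFAULT_EPSILON) -> SelectionResult:
    """Best-quality (lowest-score) frame within the FSC-average plateau.

    Ties are broken by earliest time.
    """
    plateau = detect_plateau(traj, epsilon)
    qualities = np.array([traj.frames[i].quality for i in plateau])
    best = plateau[int(np.argmin(qualities))]  # argmin returns first minimum
    fsc = _fsc_series(traj)
    return SelectionResult(
        frame_index=best,
        plateau_indices=plateau,
        fsc_avg_max=float(fsc.max()),
        quality_at_selection=float(traj.frames[best].quality),
        epsilon=epsilon,
    )
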