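"""Automatic temporal (AT) subtraction calibration.

The raw transmission coefficients of a frame are dominated by clutter — the
specular return from the colon wall, which depends on the unknown and slowly
varying antenna-to-wall distance, folds and angulations.  A polyp perturbs the
measured field far more between neighbouring frames than the clutter does, so
the scattered field of a frame is estimated by subtracting, from the pool of
all previously acquired frames, the one whose S-parameters are most similar.

Similarity between two frames is measured on their 24 transmission
coefficients viewed as point sets in the complex plane, using the modified
Hausdorff distance (mean-of-nearest-neighbour distances, combined by max).  A
Chebyshev alternative — the maximum per-pair magnitude difference — is kept as
a configurable metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .frames_io import MeasurementPlan, SParamFrame, Trajectory

__all__ = [
    "CalibratedFrame",
    "NoReferenceError",
    "modified_hausdorff_distance",
    "frame_points",
    "frame_distance",
    "select_reference",
    "calibrate",
    "calibrate_trajectory",
]


class NoReferenceError(LookupError):
    """No previous frame is available to calibrate against."""


@dataclass
class CalibratedFrame:
    """Scattered-field estimate of one frame after reference subtraction.

    ``reference_index`` is ``None`` only for the sentinel first frame, which
    is never calibrated (its values are identically zero and it is never
    scored by the detector).
    """

    frame_index: int
    reference_index: int | None
    values: dict[tuple[int, int], complex]

    def __post_init__(self) -> None:
        if self.reference_index is not None and not (
            self.reference_index < self.frame_index
        ):
            raise ValueError("reference_index must precede frame_index")

    def values_array(self, plan: MeasurementPlan) -> np.ndarray:
        return np.array([self.values[p] for p in plan.pairs], dtype=complex)

    def energy(self) -> float:
        """Total scattered-field energy sum(|Es|^2) over the plan."""
        v = np.array(list(self.values.values()))
        return float(np.sum(np.abs(v) ** 2))


def modified_hausdorff_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Modified Hausdorff distance between two planar point sets.

    ``MHD(A, B) = max(d(A, B), d(B, A))`` with ``d(A, B)`` the mean over
    points of A of the Euclidean distance to their nearest neighbour in B.
    Symmetric and zero iff every point is matched at distance zero in both
    directions; the triangle inequality does *not* hold in general.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("modified Hausdorff distance requires non-empty sets")
    a = a.reshape(len(a), -1)
    b = b.reshape(len(b), -1)
    d = cdist(a, b)
    return float(max(d.min(axis=1).mean(), d.min(axis=0).mean()))


def frame_points(frame: SParamFrame, plan: MeasurementPlan) -> np.ndarray:
    """Represent a frame as 24 (Re, Im) points in the complex plane."""
    v = frame.values_array(plan)
    return np.column_stack([v.real, v.imag])


def frame_distance(
    f: SParamFrame,
    g: SParamFrame,
    plan: MeasurementPlan,
    metric: str = "mhd",
) -> float:
    """Distance between two frames of the same plan.

    ``metric="mhd"`` treats each frame's coefficients as an unlabelled point
    set in the complex plane; ``metric="chebyshev"`` is the maximum per-pair
    magnitude difference (the max-norm reading of the reference-selection
    rule).  Both are symmetric, non-negative and zero on identical frames.
    """
    if set(f.values) != set(g.values):
        raise ValueError("frames have mismatched measurement plans")
    if f.frequency_hz != g.frequency_hz:
        raise ValueError("frames have mismatched frequencies")
    if metric == "mhd":
        return modified_hausdorff_distance(
            frame_points(f, plan), frame_points(g, plan)
        )
    if metric == "chebyshev":
        diff = f.values_array(plan) - g.values_array(plan)
        return float(np.max(np.abs(diff)))
    raise ValueError(f"unknown metric {metric!r}")


def select_reference(
    current: SParamFrame,
    pool: list[SParamFrame],
    plan: MeasurementPlan,
    metric: str = "mhd",
) -> SParamFrame:
    """Pick the pool frame most similar to ``current``.

    Ties are broken in favour of the most recent frame (largest frame index).
    Raises :class:`NoReferenceError` on an empty pool; the caller must then
    skip calibration and detection for this frame.
    """
    if not pool:
        raise NoReferenceError(
            f"no reference available for frame {current.frame_index}"
        )
    best = None
    best_d = None
    for cand in pool:
        if cand.frame_index >= current.frame_index:
            raise ValueError("pool must contain only earlier frames")
        d = frame_distance(current, cand, plan, metric=metric)
        if (
            best is None
            or d < best_d
            or (d == best_d and cand.frame_index > best.frame_index)
        ):
            best, best_d = cand, d
    return best


def calibrate(current: SParamFrame, reference: SParamFrame) -> CalibratedFrame:
    """Subtract the reference frame pairwise: Es = S(current) - S(reference)."""
    if set(current.values) != set(reference.values):
        raise ValueError("frames have mismatched measurement plans")
    if current.frequency_hz != reference.frequency_hz:
        raise ValueError("frames have mismatched frequencies")
    values = {
        pair: current.values[pair] - reference.values[pair]
        for pair in current.values
    }
    return CalibratedFrame(
        frame_index=current.frame_index,
        reference_index=reference.frame_index,
        values=values,
    )


def calibrate_trajectory(
    traj: Trajectory,
    metric: str = "mhd",
    pool_window: int | None = None,
) -> list[CalibratedFrame]:
    """AT-calibrate every frame of a trajectory.

    Frame ``n`` is calibrated against the most similar frame among frames
    ``0 .. n-1`` (or the last ``pool_window`` of them).  Frame 0 has no
    predecessors and is emitted as a zero-field sentinel with
    ``reference_index=None``.
    """
    plan = traj.plan
    out: list[CalibratedFrame] = []
    for n, frame in enumerate(traj.frames):
        if n == 0:
            out.append(
                CalibratedFrame(
                    frame_index=0,
                    reference_index=None,
                    values={p: 0j for p in plan.pairs},
                )
            )
            continue
        lo = 0 if pool_window is None else max(0, n - pool_window)
        ref = select_reference(frame, traj.frames[lo:n], plan, metric=metric)
        out.append(calibrate(frame, ref))
    return out
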