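"""Ground-truth labelling and sensitivity/specificity evaluation.

Frames are labelled from the registered lesion extents: frame ``n`` covers the
axial interval ``[z_n, z_n + step)`` and is a lesion frame iff that interval
overlaps any lesion extent dilated by ``tolerance_frames`` steps on each side
(the dilation absorbs the manual registration of the lesion position).  Frame
0 and the detector warm-up frames are never counted.

Counting units are hybrid by default, matching how per-trajectory results are
reported clinically: each lesion is one positive unit (detected iff at least
one alarm frame overlaps its dilated extent), while every scored healthy frame
is one negative unit.  Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), in
percent; a zero denominator yields ``None`` (undefined), never a silent 0 or
100.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detector import DetectionResult
from .frames_io import Trajectory

__all__ = [
    "ConfusionCounts",
    "TrajectoryEvaluation",
    "EvaluationReport",
    "label_frames",
    "lesion_frame_sets",
    "confusion",
    "sensitivity_specificity",
    "evaluate_trajectory",
    "evaluate_ensemble",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


def _lesion_frames(
    traj: Trajectory, lesion, tolerance_frames: int
) -> set[int]:
    """Frames whose [z_n, z_n+step) interval overlaps the dilated extent."""
    tol = tolerance_frames * traj.step_mm
    lo = lesion.z_start_mm - tol
    hi = lesion.z_end_mm + tol
    out = set()
    for frame in traj.frames:
        if frame.z_mm < hi and frame.z_mm + traj.step_mm > lo:
            out.add(frame.frame_index)
    return out


def lesion_frame_sets(
    traj: Trajectory, tolerance_frames: int = 1
) -> list[set[int]]:
    """Per-lesion sets of frame indices covered by the dilated extent."""
    z_max = traj.frames[-1].z_mm + traj.step_mm
    for lesion in traj.lesions:
        if lesion.z_end_mm < traj.frames[0].z_mm or lesion.z_start_mm > z_max:
            raise ValueError(
                f"lesion [{lesion.z_start_mm}, {lesion.z_end_mm}] mm lies "
                "outside the trajectory"
            )
    return [_lesion_frames(traj, l, tolerance_frames) for l in traj.lesions]


def label_frames(
    traj: Trajectory,
    tolerance_frames: int = 1,
    warmup_frames: int = 3,
) -> dict[int, str]:
    """Label every scored frame 'lesion' or 'healthy'.

    Frame 0 and the first ``warmup_frames`` frames are excluded (not scored
    by the detector, hence never counted).
    """
    lesion_frames: set[int] = set()
    for s in lesion_frame_sets(traj, tolerance_frames):
        lesion_frames |= s
    labels = {}
    for frame in traj.frames:
        n = frame.frame_index
        if n == 0 or n <= warmup_frames:
            continue
        labels[n] = "lesion" if n in lesion_frames else "healthy"
    return labels


def confusion(
    labels: dict[int, str],
    result: DetectionResult,
    lesion_sets: list[set[int]] | None = None,
    positive_unit: str = "lesion",
) -> ConfusionCounts:
    """Count TP/FP/TN/FN from frame labels and detector output.

    With ``positive_unit='lesion'`` each ground-truth lesion counts once: TP
    iff at least one alarm frame falls in its (dilated) frame set, else FN.
    With ``positive_unit='frame'`` every lesion-labelled frame is a positive
    unit.  Healthy units are always scored frames: FP if the frame alarmed,
    TN otherwise.
    """
    if positive_unit not in ("lesion", "frame"):
        raise ValueError("positive_unit must be 'lesion' or 'frame'")
    scored = result.scored_frames
    if set(labels) != scored:
        raise ValueError(
            "labelled frames do not match the detector's scored frames"
        )
    alarms = result.alarm_frames
    counts = ConfusionCounts()
    for n, lab in labels.items():
        if lab == "healthy":
            if n in alarms:
                counts.fp += 1
            else:
                counts.tn += 1
        elif positive_unit == "frame":
            if n in alarms:
                counts.tp += 1
            else:
                counts.fn += 1
    if positive_unit == "lesion":
        if lesion_sets is None:
            raise ValueError("lesion-level counting requires lesion_sets")
        for frames in lesion_sets:
            if frames & alarms:
                counts.tp += 1
            else:
                counts.fn += 1
    return counts


def sensitivity_specificity(
    c: ConfusionCounts,
) -> tuple[float | None, float | None]:
    """(sensitivity %, specificity %); ``None`` marks an undefined ratio."""
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return sens, spec


@dataclass
class TrajectoryEvaluation:
    label: str
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    n_frames: int
    lesion_sizes_mm: list[float]
    histology: list[str]


@dataclass
class EvaluationReport:
    """Per-trajectory and pooled detection performance."""

    per_trajectory: list[TrajectoryEvaluation]
    pooled: ConfusionCounts
    pooled_sensitivity: float | None
    pooled_specificity: float | None
    macro_sensitivity: float | None
    macro_specificity: float | None

    def to_rows(self) -> list[dict]:
        rows = []
        for ev in self.per_trajectory:
            rows.append(
                {
                    "label": ev.label,
                    "histology": ";".join(ev.histology),
                    "lesion_size_mm": ";".join(f"{s:g}" for s in ev.lesion_sizes_mm),
                    "n_frames": ev.n_frames,
                    "sensitivity_pct": _fmt(ev.sensitivity),
                    "specificity_pct": _fmt(ev.specificity),
                    "tp": ev.counts.tp,
                    "fp": ev.counts.fp,
                    "tn": ev.counts.tn,
                    "fn": ev.counts.fn,
                }
            )
        rows.append(
            {
                "label": "OVERALL (pooled)",
                "histology": "",
                "lesion_size_mm": "",
                "n_frames": sum(ev.n_frames for ev in self.per_trajectory),
                "sensitivity_pct": _fmt(self.pooled_sensitivity),
                "specificity_pct": _fmt(self.pooled_specificity),
                "tp": self.pooled.tp,
                "fp": self.pooled.fp,
                "tn": self.pooled.tn,
                "fn": self.pooled.fn,
            }
        )
        return rows


def _fmt(v: float | None) -> str:
    return "undefined" if v is None else f"{v:.2f}"


def evaluate_trajectory(
    traj: Trajectory,
    result: DetectionResult,
    tolerance_frames: int = 1,
    positive_unit: str = "lesion",
) -> TrajectoryEvaluation:
    labels = label_frames(
        traj,
        tolerance_frames=tolerance_frames,
        warmup_frames=result.config.warmup_frames,
    )
    sets = lesion_frame_sets(traj, tolerance_frames)
    counts = confusion(labels, result, lesion_sets=sets, positive_unit=positive_unit)
    sens, spec = sensitivity_specificity(counts)
    return TrajectoryEvaluation(
        label=traj.label,
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        n_frames=len(traj),
        lesion_sizes_mm=[l.size_mm for l in traj.lesions],
        histology=[l.histology_label for l in traj.lesions],
    )


def evaluate_ensemble(
    trajectories: list[Trajectory],
    results: list[DetectionResult],
    tolerance_frames: int = 1,
    positive_unit: str = "lesion",
) -> EvaluationReport:
    """Evaluate each trajectory and pool the counts (micro-average).

    The macro-averaged percentages (mean of the per-trajectory values that
    are defined) are reported alongside the pooled ones.
    """
    if len(trajectories) != len(results):
        raise ValueError("one detection result per trajectory required")
    evals = [
        evaluate_trajectory(t, r, tolerance_frames, positive_unit)
        for t, r in zip(trajectories, results)
    ]
    pooled = ConfusionCounts()
    for ev in evals:
        pooled = pooled + ev.counts
    sens, spec = sensitivity_specificity(pooled)
    sens_vals = [ev.sensitivity for ev in evals if ev.sensitivity is not None]
    spec_vals = [ev.specificity for ev in evals if ev.specificity is not None]
    return EvaluationReport(
        per_trajectory=evals,
        pooled=pooled,
        pooled_sensitivity=sens,
        pooled_specificity=spec,
        macro_sensitivity=sum(sens_vals) / len(sens_vals) if sens_vals else None,
        macro_specificity=sum(spec_vals) / len(spec_vals) if spec_vals else None,
    )
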