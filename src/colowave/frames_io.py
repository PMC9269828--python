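"""Acquisition data model and on-disk formats for ring-array microwave colonoscopy.

A colonoscope-tip accessory carries a ring of ``N_a`` transmitting antennas
(paired with a coplanar receiving ring) of 20 mm outer diameter.  At each 4 mm
step along the colon axis one *frame* of complex transmission S-parameters is
acquired: every transmitter illuminates the lumen in turn and the three
receivers closest to it (the one directly opposite plus its two neighbours on
either side, modulo the ring) record the transmission coefficient, giving
``3 * N_a`` = 24 pairs for the standard 8-antenna ring.

This module defines the in-memory containers — :class:`ArrayGeometry`,
:class:`MeasurementPlan`, :class:`SParamFrame`, :class:`Trajectory`,
:class:`LesionTruth`, :class:`DielectricProps` — and the plain-text CSV +
JSON-sidecar format used to persist trajectories.  Complex values are stored
as separate real/imaginary columns and floats are serialised with ``repr`` so
that ``read_trajectory(write_trajectory(t)) == t`` bit-exactly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = [
    "ArrayGeometry",
    "MeasurementPlan",
    "SParamFrame",
    "Trajectory",
    "LesionTruth",
    "DielectricProps",
    "TrajectoryFormatError",
    "build_measurement_plan",
    "read_trajectory",
    "write_trajectory",
    "sidecar_path",
]

HISTOLOGY_LABELS = ("adenoma_hgd", "adenocarcinoma", "other")
TISSUE_LABELS = ("healthy_mucosa", "neoplasm")

#: Default acquisition frequency in Hz (centre frequency of the narrowband
#: cavity-backed slot antennas).
DEFAULT_FREQUENCY_HZ = 7.6e9


class TrajectoryFormatError(ValueError):
    """Raised when an on-disk trajectory violates the frame/plan contract."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Ring antenna array geometry.

    Antenna ``i`` sits at angle ``2*pi*i / n_antennas_per_ring`` (antenna 0 at
    angle 0, indices counter-clockwise) on a circle of ``ring_radius_mm``.
    The transmitting and receiving rings are treated as coplanar; the physical
    axial offset between them is retained as ``tx_rx_ring_offset_z_mm`` for
    completeness but defaults to zero for 2D cross-sectional imaging.
    """

    n_antennas_per_ring: int = 8
    ring_radius_mm: float = 10.0
    tx_rx_ring_offset_z_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.n_antennas_per_ring < 3:
            raise ValueError("need at least 3 antennas per ring")
        if not self.ring_radius_mm > 0:
            raise ValueError("ring_radius_mm must be positive")

    @property
    def angular_positions(self) -> np.ndarray:
        """Angles of the antennas in radians, strictly increasing in [0, 2*pi)."""
        n = self.n_antennas_per_ring
        return 2.0 * np.pi * np.arange(n) / n

    def antenna_xy_mm(self) -> np.ndarray:
        """(n, 2) array of antenna centre coordinates in the slice plane, mm."""
        ang = self.angular_positions
        return self.ring_radius_mm * np.column_stack([np.cos(ang), np.sin(ang)])


@dataclass(frozen=True)
class MeasurementPlan:
    """Ordered list of (tx, rx) index pairs acquired per frame."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate (tx, rx) pairs in measurement plan")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)


def build_measurement_plan(geometry: ArrayGeometry) -> MeasurementPlan:
    """Enumerate the three-closest-receivers acquisition scheme.

    For each transmitter ``i`` the receivers are ``(i-1) mod N_a``, ``i`` and
    ``(i+1) mod N_a``, in that order; transmitters are visited in index order.
    For the 8-antenna ring this yields the 24-pair plan (e.g. transmitter 0
    pairs with receivers 7, 0, 1 and transmitter 7 with receivers 6, 7, 0).
    """
    n = geometry.n_antennas_per_ring
    pairs = []
    for i in range(n):
        for j in ((i - 1) % n, i, (i + 1) % n):
            pairs.append((i, j))
    return MeasurementPlan(tuple(pairs))


@dataclass
class SParamFrame:
    """One acquisition step: complex transmission coefficients keyed by (tx, rx)."""

    frame_index: int
    z_mm: float
    values: dict[tuple[int, int], complex]
    frequency_hz: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be positive")
        for pair, v in self.values.items():
            if not (math.isfinite(v.real) and math.isfinite(v.imag)):
                raise ValueError(f"non-finite S-parameter at pair {pair}")

    def values_array(self, plan: MeasurementPlan) -> np.ndarray:
        """Complex values ordered by the plan's pair order."""
        try:
            return np.array([self.values[p] for p in plan.pairs], dtype=complex)
        except KeyError as exc:  # pragma: no cover - guarded by validation
            raise TrajectoryFormatError(
                f"frame {self.frame_index} missing pair {exc.args[0]}"
            ) from exc

    def validate_against(self, plan: MeasurementPlan) -> None:
        missing = plan.pair_set - set(self.values)
        if missing:
            pair = min(missing)
            raise TrajectoryFormatError(
                f"frame {self.frame_index} missing pair {pair}"
            )
        extra = set(self.values) - plan.pair_set
        if extra:
            raise TrajectoryFormatError(
                f"frame {self.frame_index} has pair {min(extra)} outside the plan"
            )


@dataclass
class LesionTruth:
    """Ground-truth axial extent of one lesion along the trajectory."""

    z_start_mm: float
    z_end_mm: float
    histology_label: str = "adenocarcinoma"
    size_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_start_mm < self.z_end_mm:
            raise ValueError("z_start_mm must be < z_end_mm")
        if not self.size_mm > 0:
            raise ValueError("size_mm must be positive")
        if self.histology_label not in HISTOLOGY_LABELS:
            raise ValueError(f"unknown histology label {self.histology_label!r}")


@dataclass(frozen=True)
class DielectricProps:
    """Relative permittivity and conductivity (S/m) of one tissue."""

    relative_permittivity: float
    conductivity_s_per_m: float
    tissue: str = "healthy_mucosa"

    def __post_init__(self) -> None:
        if not self.relative_permittivity >= 1:
            raise ValueError("relative_permittivity must be >= 1")
        if self.conductivity_s_per_m < 0:
            raise ValueError("conductivity must be non-negative")
        if self.tissue not in TISSUE_LABELS:
            raise ValueError(f"unknown tissue label {self.tissue!r}")


@dataclass
class Trajectory:
    """Ordered frame sequence with uniform axial step and optional ground truth."""

    frames: list[SParamFrame]
    step_mm: float = 4.0
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    lesions: list[LesionTruth] = field(default_factory=list)
    label: str = ""
    provenance: dict | None = None

    def __post_init__(self) -> None:
        if not self.step_mm > 0:
            raise ValueError("step_mm must be positive")
        plan = build_measurement_plan(self.geometry)
        if not self.frames:
            raise TrajectoryFormatError("no frames")
        z0 = self.frames[0].z_mm
        f0 = self.frames[0].frequency_hz
        for n, frame in enumerate(self.frames):
            if frame.frame_index != n:
                raise TrajectoryFormatError(
                    f"frame indices must be consecutive from 0; "
                    f"got {frame.frame_index} at position {n}"
                )
            if abs(frame.z_mm - (z0 + n * self.step_mm)) > 1e-9:
                raise TrajectoryFormatError(
                    f"frame {n} z={frame.z_mm} mm off the uniform grid "
                    f"(expected {z0 + n * self.step_mm} mm)"
                )
            if frame.frequency_hz != f0:
                raise TrajectoryFormatError(
                    f"frame {n} frequency {frame.frequency_hz} Hz differs from "
                    f"frame 0 ({f0} Hz)"
                )
            frame.validate_against(plan)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def plan(self) -> MeasurementPlan:
        return build_measurement_plan(self.geometry)

    @property
    def frequency_hz(self) -> float:
        return self.frames[0].frequency_hz

    def z_positions(self) -> np.ndarray:
        return np.array([f.z_mm for f in self.frames])


# ---------------------------------------------------------------------------
# On-disk format: frame CSV + JSON metadata sidecar
# ---------------------------------------------------------------------------

_CSV_HEADER = ["frame_index", "z_mm", "tx", "rx", "frequency_hz", "re", "im"]


def sidecar_path(path: Path | str) -> Path:
    """Metadata sidecar lives next to the CSV with a .json suffix."""
    return Path(path).with_suffix(".json")


def write_trajectory(traj: Trajectory, path: Path | str) -> None:
    """Write ``traj`` as a frame CSV plus JSON sidecar.

    Row order is deterministic (frame_index, then plan pair order) and floats
    use ``repr`` so repeated writes are byte-identical and values round-trip
    exactly.
    """
    path = Path(path)
    plan = traj.plan
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write(",".join(_CSV_HEADER) + "\n")
        for frame in traj.frames:
            for tx, rx in plan.pairs:
                v = frame.values[(tx, rx)]
                fh.write(
                    f"{frame.frame_index},{frame.z_mm!r},{tx},{rx},"
                    f"{frame.frequency_hz!r},{v.real!r},{v.imag!r}\n"
                )
    meta = {
        "geometry": {
            "n_antennas_per_ring": traj.geometry.n_antennas_per_ring,
            "ring_radius_mm": traj.geometry.ring_radius_mm,
            "tx_rx_ring_offset_z_mm": traj.geometry.tx_rx_ring_offset_z_mm,
        },
        "step_mm": traj.step_mm,
        "label": traj.label,
        "lesions": [
            {
                "z_start_mm": l.z_start_mm,
                "z_end_mm": l.z_end_mm,
                "histology_label": l.histology_label,
                "size_mm": l.size_mm,
            }
            for l in traj.lesions
        ],
        "provenance": traj.provenance,
    }
    with open(sidecar_path(path), "w", newline="\n", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_trajectory(path: Path | str) -> Trajectory:
    """Read a trajectory from a frame CSV and its JSON sidecar.

    Raises :class:`TrajectoryFormatError` naming the offending frame and pair
    when a frame is incomplete, when frame indices are not consecutive, or
    when frames disagree on the acquisition frequency.
    """
    path = Path(path)
    with open(sidecar_path(path), encoding="utf-8") as fh:
        meta = json.load(fh)
    geometry = ArrayGeometry(
        n_antennas_per_ring=meta["geometry"]["n_antennas_per_ring"],
        ring_radius_mm=meta["geometry"]["ring_radius_mm"],
        tx_rx_ring_offset_z_mm=meta["geometry"].get("tx_rx_ring_offset_z_mm", 0.0),
    )
    lesions = [
        LesionTruth(
            z_start_mm=l["z_start_mm"],
            z_end_mm=l["z_end_mm"],
            histology_label=l["histology_label"],
            size_mm=l["size_mm"],
        )
        for l in meta.get("lesions", [])
    ]

    by_frame: dict[int, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrajectoryFormatError("no frames")
        if list(reader.fieldnames) != _CSV_HEADER:
            raise TrajectoryFormatError(
                f"unexpected CSV header {reader.fieldnames}"
            )
        for row in reader:
            n = int(row["frame_index"])
            rec = by_frame.setdefault(
                n,
                {
                    "z_mm": float(row["z_mm"]),
                    "frequency_hz": float(row["frequency_hz"]),
                    "values": {},
                },
            )
            rec["values"][(int(row["tx"]), int(row["rx"]))] = complex(
                float(row["re"]), float(row["im"])
            )
    if not by_frame:
        raise TrajectoryFormatError("no frames")

    frames = []
    for n in sorted(by_frame):
        rec = by_frame[n]
        frames.append(
            SParamFrame(
                frame_index=n,
                z_mm=rec["z_mm"],
                values=rec["values"],
                frequency_hz=rec["frequency_hz"],
            )
        )
    return Trajectory(
        frames=frames,
        step_mm=meta["step_mm"],
        geometry=geometry,
        lesions=lesions,
        label=meta.get("label", ""),
        provenance=meta.get("provenance"),
    )
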