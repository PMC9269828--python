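"""Synthetic colon trajectory simulator.

Stands in for ex vivo S-parameter recordings, reproducing the statistical
structure the detection algorithm relies on rather than full antenna physics:

* **Wall clutter** — a deterministic specular-like return per pair whose phase
  is the round-trip to the wall at the pair's mid-bearing and whose amplitude
  decays with antenna-to-wall distance.  Folds (sinusoidal radius modulation)
  and angulations (lateral centre-line drift of the lumen relative to the
  probe) make the clutter drift smoothly from frame to frame.
* **Polyp scattering** — a Born single-scattering term per lesion: complex
  dielectric contrast ``tau`` times a two-leg 2D cylindrical-spread kernel
  ``g(d) = exp(-j k d)/sqrt(d)`` (transmitter→polyp, polyp→receiver), scaled
  by lesion volume and windowed axially by a raised-cosine over the lesion
  extent, so a lesion contributes nothing outside its own footprint.
* **Debris** — weak, axially broad scatterers emulating suboptimal colon
  cleaning; their response varies slowly along z, like clutter.
* **Noise** — i.i.d. circular complex Gaussian per pair and frame.

The contrast amplitude derives from the measured tissue properties: at
7.6 GHz a neoplasm exhibits roughly 30% higher relative permittivity and 90%
higher conductivity than healthy mucosa, entering through the complex
permittivity ratio ``tau = (eps*_lesion - eps*_bg) / eps*_bg``.

Simulation is a pure function of (scene spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import focuser
from .frames_io import (
    ArrayGeometry,
    DielectricProps,
    LesionTruth,
    MeasurementPlan,
    SParamFrame,
    Trajectory,
    build_measurement_plan,
)

__all__ = [
    "VACUUM_PERMITTIVITY",
    "HEALTHY_MUCOSA",
    "NEOPLASM",
    "Polyp",
    "Debris",
    "SceneSpec",
    "complex_permittivity",
    "scattering_amplitude",
    "simulate_frame",
    "simulate_trajectory",
]

VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Nominal healthy colon mucosa at 7.6 GHz.
HEALTHY_MUCOSA = DielectricProps(46.0, 8.0, tissue="healthy_mucosa")
#: Nominal neoplastic tissue: +30% relative permittivity, +90% conductivity.
NEOPLASM = DielectricProps(46.0 * 1.3, 8.0 * 1.9, tissue="neoplasm")


def complex_permittivity(props: DielectricProps, frequency_hz: float) -> complex:
    """eps* = eps_r - j * sigma / (2 pi f eps0)."""
    return props.relative_permittivity - 1j * props.conductivity_s_per_m / (
        2.0 * np.pi * frequency_hz * VACUUM_PERMITTIVITY
    )


def scattering_amplitude(
    props_lesion: DielectricProps,
    props_background: DielectricProps,
    frequency_hz: float = 7.6e9,
) -> complex:
    """Complex dielectric contrast tau = (eps*_lesion - eps*_bg) / eps*_bg.

    Zero for identical tissues; invariant under scaling both complex
    permittivities by a common factor; |tau| grows with the permittivity
    difference at fixed conductivity.
    """
    for p in (props_lesion, props_background):
        if not p.relative_permittivity > 0:
            raise ValueError("relative permittivity must be positive")
    eb = complex_permittivity(props_background, frequency_hz)
    el = complex_permittivity(props_lesion, frequency_hz)
    return (el - eb) / eb


@dataclass(frozen=True)
class Polyp:
    """One lesion: a point scatterer with an axial footprint of ``size_mm``."""

    z_center_mm: float
    radial_offset_mm: float
    angle_rad: float
    size_mm: float
    props: DielectricProps = NEOPLASM
    background: DielectricProps = HEALTHY_MUCOSA
    histology_label: str = "adenocarcinoma"


@dataclass(frozen=True)
class Debris:
    """A weak residual-content scatterer with a broad axial footprint."""

    z_center_mm: float
    radial_offset_mm: float
    angle_rad: float
    extent_mm: float = 40.0
    amplitude: float = 0.05


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and contents of one synthetic colon scene.

    ``lumen_radius_mm`` is the nominal radius (colon diameter 40–90 mm,
    default 50 mm → radius 25); folds modulate it sinusoidally along z;
    ``curvature_mm`` is the peak lateral offset of the lumen centre-line
    relative to the probe axis (half-sine over the scene length), emulating
    an angulation.  ``noise_sigma`` is the total standard deviation of the
    additive circular complex noise per S-parameter.
    """

    length_mm: float = 200.0
    lumen_radius_mm: float = 25.0
    fold_amplitude_mm: float = 0.0
    fold_period_mm: float = 40.0
    curvature_mm: float = 0.0
    curvature_angle_rad: float = 0.0
    debris: tuple[Debris, ...] = ()
    polyps: tuple[Polyp, ...] = ()
    clutter_amplitude: float = 1.0
    noise_sigma: float = 0.02
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError("length_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for p in self.polyps:
            if not 0 <= p.z_center_mm <= self.length_mm:
                raise ValueError(
                    f"polyp z_center {p.z_center_mm} mm outside scene "
                    f"[0, {self.length_mm}] mm"
                )

    def wall_radius_mm(self, z_mm: float) -> float:
        return self.lumen_radius_mm + self.fold_amplitude_mm * math.sin(
            2.0 * math.pi * z_mm / self.fold_period_mm
        )

    def center_offset_mm(self, z_mm: float) -> tuple[float, float]:
        """Lumen centre-line offset relative to the probe axis at ``z``."""
        a = self.curvature_mm * math.sin(math.pi * z_mm / self.length_mm)
        return (
            a * math.cos(self.curvature_angle_rad),
            a * math.sin(self.curvature_angle_rad),
        )


def _axial_window(dz_mm: float, extent_mm: float) -> float:
    """Raised-cosine footprint: 1 at the centre, 0 beyond +-extent/2."""
    if abs(dz_mm) >= extent_mm / 2.0:
        return 0.0
    return math.cos(math.pi * dz_mm / extent_mm) ** 2


def _spread(d_mm: float, k_rad_m: float) -> complex:
    """2D cylindrical-spread kernel g(d) = exp(-j k d) / sqrt(d), d in metres."""
    d_m = d_mm * 1e-3
    return complex(np.exp(-1j * k_rad_m * d_m) / math.sqrt(d_m))


def simulate_frame(
    spec: SceneSpec,
    geometry: ArrayGeometry,
    plan: MeasurementPlan,
    z_mm: float,
    rng: np.random.Generator,
) -> SParamFrame:
    """Forward-model one frame at axial position ``z_mm``.

    The frame index is set to 0; :func:`simulate_trajectory` renumbers frames.
    """
    if not 0 <= z_mm <= spec.length_mm:
        raise ValueError(f"z={z_mm} mm outside scene [0, {spec.length_mm}] mm")
    freq = 7.6e9
    k = focuser.wavenumber(freq)
    xy = geometry.antenna_xy_mm()
    ang = geometry.angular_positions
    cx, cy = spec.center_offset_mm(z_mm)
    wall_r = spec.wall_radius_mm(z_mm)

    values: dict[tuple[int, int], complex] = {}
    for tx, rx in plan.pairs:
        # clutter: specular return at the pair's mid-bearing; wall distance
        # shrinks on the side the lumen centre-line drifts away from
        mid = np.angle(np.exp(1j * ang[tx]) + np.exp(1j * ang[rx]))
        d_wall = wall_r - geometry.ring_radius_mm - (
            cx * math.cos(mid) + cy * math.sin(mid)
        )
        if d_wall <= 1.0:
            raise ValueError(
                "lumen wall closer than 1 mm to the antenna ring; "
                "scene violates the accessory-fits-inside-lumen invariant"
            )
        v = spec.clutter_amplitude * _spread(2.0 * d_wall, k)

        for polyp in spec.polyps:
            w = _axial_window(z_mm - polyp.z_center_mm, polyp.size_mm)
            if w == 0.0:
                continue
            tau = scattering_amplitude(polyp.props, polyp.background, freq)
            # Born scattering strength scales with lesion volume (10 mm ref.)
            strength = tau * (polyp.size_mm / 10.0) ** 3
            px = polyp.radial_offset_mm * math.cos(polyp.angle_rad) - cx
            py = polyp.radial_offset_mm * math.sin(polyp.angle_rad) - cy
            d_t = math.hypot(px - xy[tx, 0], py - xy[tx, 1])
            d_r = math.hypot(px - xy[rx, 0], py - xy[rx, 1])
            v += strength * w * _spread(d_t, k) * _spread(d_r, k)

        for deb in spec.debris:
            w = _axial_window(z_mm - deb.z_center_mm, deb.extent_mm)
            if w == 0.0:
                continue
            px = deb.radial_offset_mm * math.cos(deb.angle_rad) - cx
            py = deb.radial_offset_mm * math.sin(deb.angle_rad) - cy
            d_t = math.hypot(px - xy[tx, 0], py - xy[tx, 1])
            d_r = math.hypot(px - xy[rx, 0], py - xy[rx, 1])
            v += deb.amplitude * w * _spread(d_t, k) * _spread(d_r, k)

        if spec.noise_sigma > 0:
            s = spec.noise_sigma / math.sqrt(2.0)
            v += complex(rng.normal(0.0, s), rng.normal(0.0, s))
        values[(tx, rx)] = v

    return SParamFrame(frame_index=0, z_mm=z_mm, values=values, frequency_hz=freq)


def simulate_trajectory(
    spec: SceneSpec,
    geometry: ArrayGeometry | None = None,
    step_mm: float = 4.0,
) -> Trajectory:
    """Simulate frames at z = 0, step, ..., <= length_mm.

    Each polyp is recorded as ground truth over
    ``[z_center - size/2, z_center + size/2]``; the sidecar provenance holds
    the seed and scene parameters.  Pure function of (spec, seed).
    """
    if not step_mm > 0:
        raise ValueError("step_mm must be positive")
    if geometry is None:
        geometry = ArrayGeometry()
    if spec.lumen_radius_mm - spec.fold_amplitude_mm - abs(spec.curvature_mm) <= (
        geometry.ring_radius_mm
    ):
        raise ValueError("lumen radius must exceed ring radius everywhere")
    plan = build_measurement_plan(geometry)
    rng = np.random.default_rng(spec.seed)
    n_frames = int(math.floor(spec.length_mm / step_mm)) + 1
    frames = []
    for n in range(n_frames):
        frame = simulate_frame(spec, geometry, plan, n * step_mm, rng)
        frame.frame_index = n
        frames.append(frame)
    lesions = [
        LesionTruth(
            z_start_mm=p.z_center_mm - p.size_mm / 2.0,
            z_end_mm=p.z_center_mm + p.size_mm / 2.0,
            histology_label=p.histology_label,
            size_mm=p.size_mm,
        )
        for p in spec.polyps
    ]
    provenance = {"seed": spec.seed, "scene": _spec_dict(spec)}
    return Trajectory(
        frames=frames,
        step_mm=step_mm,
        geometry=geometry,
        lesions=lesions,
        label=spec.label,
        provenance=provenance,
    )


def _spec_dict(spec: SceneSpec) -> dict:
    d = asdict(spec)
    for p in d["polyps"]:
        p["tau"] = repr(
            scattering_amplitude(
                DielectricProps(**p.pop("props")),
                DielectricProps(**p.pop("background")),
            )
        )
    return d
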