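"""Monofocusing image reconstruction of the cross-sectional dielectric contrast.

Given the calibrated scattered field ``Es`` of one frame, a backprojection-style
focuser forms the contrast image over an XY grid covering the colon slice:

    I(r) = sum_i sum_{j in {i-1, i, i+1}}  Es(Ti, Rj)^2
           * J1(2k |r_Rj - r|) * exp(j (2k |r_Rj - r| + phi_ij))

where ``k = 2 pi f / c`` is the free-space wavenumber (the lumen is insufflated
and behaves like air), ``J1`` is the Bessel function of the first kind of order
one, and ``phi_ij = 2 pi ((j - i) mod N_a) / N_a`` is the angular separation
between transmitter and receiver.  Only the receiver-to-pixel distance enters
the weighting and phase; the transmitter enters through ``Es``.  The stored
image is the magnitude ``|I|``; the complex field is retained for linearity
checks.  ``J1(0) = 0``, so pixels at a receiver position are naturally
suppressed and no guard handling is required.

Reconstruction is linear in ``Es^2``, hence homogeneous of degree two in the
scattered field, and the per-pair kernels depend only on (geometry, grid,
frequency) so they are computed once and cached.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j1

from .calibration import CalibratedFrame
from .frames_io import ArrayGeometry, MeasurementPlan, build_measurement_plan

__all__ = [
    "SPEED_OF_LIGHT_M_S",
    "ImageGrid",
    "MicrowaveImage",
    "wavenumber",
    "reconstruct",
    "per_pair_max",
]

SPEED_OF_LIGHT_M_S = 299_792_458.0


def wavenumber(frequency_hz: float) -> float:
    """Free-space wavenumber k = 2*pi*f/c in rad/m."""
    if not frequency_hz > 0:
        raise ValueError("frequency must be positive")
    return 2.0 * np.pi * frequency_hz / SPEED_OF_LIGHT_M_S


@dataclass(frozen=True)
class ImageGrid:
    """Square XY pixel grid centred on the array axis.

    ``extent_mm`` is the half-width of the window (default 45 mm, covering a
    90 mm maximal colon diameter); ``spacing_mm`` the pixel pitch.  The pixel
    count per axis is odd so the origin is a pixel centre.
    """

    extent_mm: float = 45.0
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if not self.extent_mm >= self.spacing_mm:
            raise ValueError("extent_mm must be at least one pixel")

    @property
    def half_pixels(self) -> int:
        return int(round(self.extent_mm / self.spacing_mm))

    @property
    def axis_mm(self) -> np.ndarray:
        h = self.half_pixels
        return (np.arange(2 * h + 1) - h) * self.spacing_mm

    @property
    def shape(self) -> tuple[int, int]:
        n = 2 * self.half_pixels + 1
        return (n, n)

    def pixel_xy_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-centre coordinates, indexed [iy, ix]."""
        ax = self.axis_mm
        return np.meshgrid(ax, ax, indexing="xy")


@dataclass
class MicrowaveImage:
    """Cross-sectional contrast amplitude map for one frame."""

    grid: ImageGrid
    amplitude: np.ndarray
    frame_index: int
    field: np.ndarray | None = None  # complex image, kept for linearity checks

    def __post_init__(self) -> None:
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @property
    def max_amplitude(self) -> float:
        return float(self.amplitude.max())

    def argmax_xy_mm(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(int(self.amplitude.argmax()), self.amplitude.shape)
        ax = self.grid.axis_mm
        return float(ax[ix]), float(ax[iy])


@lru_cache(maxsize=8)
def _pair_kernels(
    geometry: ArrayGeometry, grid: ImageGrid, frequency_hz: float
) -> np.ndarray:
    """Per-pair complex kernels J1(2k d_R) * exp(j(2k d_R + phi)), shape (P, ny, nx)."""
    plan = build_measurement_plan(geometry)
    k = wavenumber(frequency_hz)
    xy = geometry.antenna_xy_mm()
    px, py = grid.pixel_xy_mm()
    n = geometry.n_antennas_per_ring
    kernels = np.empty((len(plan), *grid.shape), dtype=complex)
    for p, (tx, rx) in enumerate(plan.pairs):
        d_m = np.hypot(px - xy[rx, 0], py - xy[rx, 1]) * 1e-3
        phi = 2.0 * np.pi * ((rx - tx) % n) / n
        arg = 2.0 * k * d_m
        kernels[p] = j1(arg) * np.exp(1j * (arg + phi))
    return kernels


def _check_pairs(cal: CalibratedFrame, geometry: ArrayGeometry) -> MeasurementPlan:
    plan = build_measurement_plan(geometry)
    extra = set(cal.values) - plan.pair_set
    if extra:
        raise ValueError(
            f"calibrated frame {cal.frame_index} has pair {min(extra)} "
            "not present in the array geometry's plan"
        )
    missing = plan.pair_set - set(cal.values)
    if missing:
        raise ValueError(
            f"calibrated frame {cal.frame_index} missing pair {min(missing)}"
        )
    return plan


def reconstruct(
    cal: CalibratedFrame,
    geometry: ArrayGeometry,
    grid: ImageGrid,
    frequency_hz: float,
    field_power: int = 2,
) -> MicrowaveImage:
    """Form the contrast image of one calibrated frame.

    ``field_power`` selects between the monofocusing convention ``Es^2``
    (default) and plain delay-and-sum on ``Es``.
    """
    if field_power not in (1, 2):
        raise ValueError("field_power must be 1 or 2")
    plan = _check_pairs(cal, geometry)
    kernels = _pair_kernels(geometry, grid, frequency_hz)
    es = cal.values_array(plan) ** field_power
    fld = np.tensordot(es, kernels, axes=1)
    return MicrowaveImage(
        grid=grid,
        amplitude=np.abs(fld),
        frame_index=cal.frame_index,
        field=fld,
    )


def per_pair_max(
    cal: CalibratedFrame,
    geometry: ArrayGeometry,
    grid: ImageGrid,
    frequency_hz: float,
    field_power: int = 2,
) -> dict[tuple[int, int], float]:
    """Maximum partial-image amplitude in the angular sector facing each pair.

    For each (tx, rx) pair the single-pair partial image is restricted to the
    sector of half-width ``pi/N_a`` around the pair's mid-bearing (the bisector
    of the two antenna directions), and its maximum amplitude taken.  The
    complex partial images sum pixel-wise to the full reconstruction.  Values
    are normalised to the maximum across pairs (all zeros stay zero).
    """
    if field_power not in (1, 2):
        raise ValueError("field_power must be 1 or 2")
    plan = _check_pairs(cal, geometry)
    kernels = _pair_kernels(geometry, grid, frequency_hz)
    es = cal.values_array(plan) ** field_power
    n = geometry.n_antennas_per_ring
    ang = geometry.angular_positions
    px, py = grid.pixel_xy_mm()
    pixel_ang = np.arctan2(py, px)
    out: dict[tuple[int, int], float] = {}
    for p, (tx, rx) in enumerate(plan.pairs):
        # bisector of the two antenna bearings, robust to the 0/2pi wrap
        mid = np.angle(np.exp(1j * ang[tx]) + np.exp(1j * ang[rx]))
        delta = np.angle(np.exp(1j * (pixel_ang - mid)))
        mask = np.abs(delta) <= np.pi / n
        partial = np.abs(es[p] * kernels[p])
        out[(tx, rx)] = float(partial[mask].max()) if mask.any() else 0.0
    peak = max(out.values())
    if peak > 0:
        out = {pair: v / peak for pair, v in out.items()}
    return out
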