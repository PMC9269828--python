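"""A 15-trajectory synthetic benchmark ensemble.

Emulates the ex vivo validation campaign the algorithm was designed for:
fifteen colon trajectories, one neoplastic lesion each, with the reported
per-sample lesion sizes (10–65 mm) and sample lengths (80–330 mm).  Three
trajectories are curved (an angulation emulated by lateral centre-line drift)
and one carries debris from suboptimal cleaning.  Lesion position and bearing
are drawn per trajectory from a seeded generator; the dielectric contrast is
the nominal +30% permittivity / +90% conductivity of neoplastic tissue.

:func:`study_ensemble` is deterministic in its base seed, and every
trajectory's own noise stream is independent of the placement draws.
"""

from __future__ import annotations

import numpy as np

from .frames_io import ArrayGeometry
from .synthetic import Debris, Polyp, SceneSpec, simulate_trajectory

__all__ = ["STUDY_SAMPLES", "study_scene_specs", "study_ensemble"]

#: (lesion size mm, sample length mm, histology, curved, debris) per sample.
STUDY_SAMPLES: tuple[tuple[float, float, str, bool, bool], ...] = (
    (10, 200, "adenoma_hgd", False, False),
    (50, 220, "adenocarcinoma", False, False),
    (36, 80, "adenocarcinoma", False, False),
    (32, 155, "adenoma_hgd", False, False),
    (48, 190, "adenocarcinoma", False, False),
    (37, 190, "adenocarcinoma", False, False),
    (65, 330, "adenocarcinoma", False, False),
    (15, 320, "adenocarcinoma", False, False),
    (23, 270, "adenoma_hgd", False, False),
    (34, 285, "adenocarcinoma", False, False),
    (32, 260, "adenocarcinoma", True, False),
    (35, 180, "adenocarcinoma", False, True),
    (40, 160, "adenocarcinoma", True, False),
    (37, 228, "adenocarcinoma", True, False),
    (63, 97, "adenocarcinoma", False, False),
)

LUMEN_RADIUS_MM = 25.0
FOLD_AMPLITUDE_MM = 1.5
FOLD_PERIOD_MM = 40.0
CURVATURE_MM = 6.0
STEP_MM = 4.0
WARMUP_MARGIN_MM = 20.0  # keep the dilated lesion extent past the warm-up


def study_scene_specs(seed: int = 1) -> list[SceneSpec]:
    """Build the 15 scene specifications, deterministically from ``seed``."""
    specs = []
    for i, (size, length, histology, curved, debris) in enumerate(
        STUDY_SAMPLES, start=1
    ):
        ss = np.random.SeedSequence([int(seed), i])
        place_ss, noise_ss = ss.spawn(2)
        rng = np.random.default_rng(place_ss)
        lo = size / 2.0 + WARMUP_MARGIN_MM
        hi = length - size / 2.0 - STEP_MM
        z_center = float(rng.uniform(lo, hi))
        angle = float(rng.uniform(0.0, 2.0 * np.pi))
        polyp = Polyp(
            z_center_mm=z_center,
            radial_offset_mm=LUMEN_RADIUS_MM - 6.0,
            angle_rad=angle,
            size_mm=float(size),
            histology_label=histology,
        )
        debris_items: tuple[Debris, ...] = ()
        if debris:
            debris_items = tuple(
                Debris(
                    z_center_mm=float(rng.uniform(0.0, length)),
                    radial_offset_mm=LUMEN_RADIUS_MM - 4.0,
                    angle_rad=float(rng.uniform(0.0, 2.0 * np.pi)),
                )
                for _ in range(3)
            )
        specs.append(
            SceneSpec(
                length_mm=float(length),
                lumen_radius_mm=LUMEN_RADIUS_MM,
                fold_amplitude_mm=FOLD_AMPLITUDE_MM,
                fold_period_mm=FOLD_PERIOD_MM,
                curvature_mm=CURVATURE_MM if curved else 0.0,
                curvature_angle_rad=float(rng.uniform(0.0, 2.0 * np.pi)),
                debris=debris_items,
                polyps=(polyp,),
                seed=int(noise_ss.generate_state(1)[0] % 2**31),
                label=f"sample_{i:02d}",
            )
        )
    return specs


def study_ensemble(seed: int = 1, geometry: ArrayGeometry | None = None):
    """Simulate the full 15-trajectory ensemble."""
    return [
        simulate_trajectory(spec, geometry=geometry, step_mm=STEP_MM)
        for spec in study_scene_specs(seed)
    ]
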