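"""Modified Hausdorff distance, reference selection, and subtraction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from colowave import SParamFrame, build_measurement_plan
from colowave.calibration import (
    NoReferenceError,
    calibrate,
    calibrate_trajectory,
    frame_distance,
    modified_hausdorff_distance,
    select_reference,
)
from colowave.synthetic import Polyp, SceneSpec, simulate_trajectory


def mhd_oracle(a, b):
    """Brute-force double-loop modified Hausdorff distance."""
    def directed(xs, ys):
        total = 0.0
        for x in xs:
            total += min(math.dist(x, y) for y in ys)
        return total / len(xs)
    return max(directed(a, b), directed(b, a))


def make_frame(plan, values, index=0, z=0.0):
    return SParamFrame(frame_index=index, z_mm=z,
                       values=dict(zip(plan.pairs, values)))


class TestModifiedHausdorff:
    def test_identical_sets_zero(self):
        a = np.array([[0.0, 0.0], [1.0, 2.0], [-3.0, 4.0]])
        assert modified_hausdorff_distance(a, a) == 0.0

    def test_single_points_reduce_to_euclidean(self):
        assert modified_hausdorff_distance([[0.0, 0.0]], [[3.0, 4.0]]) == 5.0

    def test_two_against_one_point(self):
        a = [[0.0, 0.0], [1.0, 0.0]]
        b = [[0.0, 1.0]]
        expected = (1.0 + math.sqrt(2.0)) / 2.0  # max(mean(1, sqrt2), 1)
        assert modified_hausdorff_distance(a, b) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            modified_hausdorff_distance(np.empty((0, 2)), [[0.0, 0.0]])

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((24, 2))
        b = rng.standard_normal((24, 2))
        assert modified_hausdorff_distance(a, b) == pytest.approx(
            mhd_oracle(a.tolist(), b.tolist()), rel=1e-12
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((10, 2))
        b = rng.standard_normal((7, 2))
        assert modified_hausdorff_distance(a, b) == modified_hausdorff_distance(b, a)


class TestFrameDistance:
    def test_identical_frames_zero_both_metrics(self, plan, rng):
        f = make_frame(plan, rng.standard_normal(24) + 1j * rng.standard_normal(24))
        assert frame_distance(f, f, plan, metric="mhd") == 0.0
        assert frame_distance(f, f, plan, metric="chebyshev") == 0.0

    def test_single_pair_perturbation_is_chebyshev(self, plan, rng):
        vals = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        f = make_frame(plan, vals)
        vals2 = vals.copy()
        vals2[5] += 0.25
        g = make_frame(plan, vals2, index=1, z=4.0)
        assert frame_distance(f, g, plan, metric="chebyshev") == pytest.approx(0.25)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_mhd_metric_equals_point_set_oracle(self, plan, seed):
        rng = np.random.default_rng(seed)
        v1 = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        v2 = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        f, g = make_frame(plan, v1), make_frame(plan, v2, index=1, z=4.0)
        pts = lambda v: [[x.real, x.imag] for x in v]
        assert frame_distance(f, g, plan) == pytest.approx(
            mhd_oracle(pts(v1), pts(v2)), rel=1e-12
        )

    def test_symmetric(self, plan, rng):
        f = make_frame(plan, rng.standard_normal(24) + 0j)
        g = make_frame(plan, rng.standard_normal(24) + 0j, index=1, z=4.0)
        for metric in ("mhd", "chebyshev"):
            assert frame_distance(f, g, plan, metric=metric) == frame_distance(
                g, f, plan, metric=metric
            )


class TestSelectReference:
    def test_exact_copy_selected(self, plan, rng):
        v = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        pool = [
            make_frame(plan, v + 3.0, index=0, z=0.0),
            make_frame(plan, v, index=1, z=4.0),
            make_frame(plan, v + 1.0, index=2, z=8.0),
        ]
        current = make_frame(plan, v, index=3, z=12.0)
        assert select_reference(current, pool, plan).frame_index == 1

    def test_argmin_over_pool(self, plan, rng):
        v = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        # uniform complex shifts give chebyshev (and mhd) distances 3, 1, 2
        pool = [
            make_frame(plan, v + 3.0, index=0, z=0.0),
            make_frame(plan, v + 1.0, index=1, z=4.0),
            make_frame(plan, v + 2.0, index=2, z=8.0),
        ]
        current = make_frame(plan, v, index=3, z=12.0)
        for metric in ("mhd", "chebyshev"):
            best = select_reference(current, pool, plan, metric=metric)
            dists = [frame_distance(current, p, plan, metric=metric) for p in pool]
            assert dists.index(min(dists)) == 1
            assert best.frame_index == 1

    def test_tie_breaks_to_most_recent(self, plan, rng):
        v = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        pool = [
            make_frame(plan, v + 1.0, index=0, z=0.0),
            make_frame(plan, v + 1.0, index=1, z=4.0),
        ]
        current = make_frame(plan, v, index=2, z=8.0)
        assert select_reference(current, pool, plan).frame_index == 1

    def test_empty_pool_signals_no_reference(self, plan, rng):
        current = make_frame(plan, rng.standard_normal(24) + 0j, index=1, z=4.0)
        with pytest.raises(NoReferenceError):
            select_reference(current, [], plan)


class TestCalibrate:
    def test_self_subtraction_is_zero_field(self, plan, rng):
        f = make_frame(plan, rng.standard_normal(24) + 1j * rng.standard_normal(24),
                       index=1, z=4.0)
        g = make_frame(plan, np.array(list(f.values.values())))
        cal = calibrate(f, g)
        assert all(v == 0 for v in cal.values.values())
        assert cal.reference_index == 0

    def test_additivity(self, plan, rng):
        v = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        delta = rng.standard_normal(24) + 1j * rng.standard_normal(24)
        ref = make_frame(plan, v)
        cur = make_frame(plan, v + delta, index=1, z=4.0)
        cal = calibrate(cur, ref)
        # pairwise subtraction recovers delta up to one float rounding step
        assert np.allclose(cal.values_array(plan), delta, rtol=1e-12)

    def test_polyp_frames_have_positive_residual_energy(self):
        # z_center off the symmetric grid point: mirrored frames would
        # otherwise be exactly identical and subtract to zero
        polyp = Polyp(z_center_mm=61.0, radial_offset_mm=16.0,
                      angle_rad=0.4, size_mm=30.0)
        traj = simulate_trajectory(
            SceneSpec(length_mm=120.0, polyps=(polyp,), noise_sigma=0.0)
        )
        cals = {c.frame_index: c for c in calibrate_trajectory(traj)}
        lesion_frames = [n for n in cals
                         if 47.0 < n * 4.0 < 75.0 and n > 0]
        healthy = [n for n in cals if n * 4.0 < 40.0 and n > 0]
        assert all(cals[n].energy() > 0 for n in lesion_frames)
        assert all(cals[n].energy() == 0 for n in healthy)

    def test_calibration_tracks_curved_trajectory_drift(self):
        # residual energy after AT subtraction must beat frame-0 subtraction
        spec = SceneSpec(length_mm=160.0, curvature_mm=6.0, noise_sigma=0.0)
        traj = simulate_trajectory(spec)
        plan = traj.plan
        cals = calibrate_trajectory(traj)
        at_energy = sum(c.energy() for c in cals[1:])
        first = traj.frames[0]
        fixed_energy = sum(
            calibrate(f, first).energy() for f in traj.frames[1:]
        )
        assert at_energy < fixed_energy


class TestCalibrateTrajectory:
    def test_frame0_is_unscored_sentinel(self):
        traj = simulate_trajectory(SceneSpec(length_mm=40.0, seed=3))
        cals = calibrate_trajectory(traj)
        assert cals[0].reference_index is None
        assert cals[0].energy() == 0.0

    def test_references_precede_frames(self):
        traj = simulate_trajectory(SceneSpec(length_mm=60.0, noise_sigma=0.05))
        for cal in calibrate_trajectory(traj)[1:]:
            assert cal.reference_index < cal.frame_index

    def test_pool_window_limits_references(self):
        traj = simulate_trajectory(SceneSpec(length_mm=60.0, noise_sigma=0.05))
        for cal in calibrate_trajectory(traj, pool_window=2)[1:]:
            assert cal.frame_index - cal.reference_index <= 2
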