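"""Centerline tracking: initialization, wobble, full walks, failure modes."""

import numpy as np
import pytest

from aortatrace import (
    InitializationError,
    PhantomSpec,
    TrackingConfig,
    extrapolate,
    generate_phantom,
    initialize,
    track,
    wobble,
)
from aortatrace.tracker import _connected_areas, detect_branch_exit

from conftest import CANE_KW, synthetic_trace, valid_region_stats


class TestExtrapolate:
    @pytest.mark.parametrize("p0,p1,step,expected", [
        ((0, 0, 0), (0, 0, 1), 1.0, (0, 0, 2)),
        ((0, 0, 0), (0, 1, 1), np.sqrt(2), (0, 2, 2)),
        ((1, 1, 1), (2, 1, 1), 3.0, (5, 1, 1)),
    ])
    def test_closed_form(self, p0, p1, step, expected):
        assert np.allclose(extrapolate(np.array(p0), np.array(p1), step), expected)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            extrapolate(np.ones(3), np.ones(3), 1.0)


class TestInitialize:
    def test_vertical_cylinder_seeds_on_axis(self, tracked):
        mask, _, _, _ = tracked("cylinder_r10")
        p0, p1 = initialize(mask)
        assert np.linalg.norm(p0[:2]) <= 1.0  # within one voxel of (0, 0)
        assert np.linalg.norm(p1[:2]) <= 1.0
        assert p1[2] > p0[2]  # superior direction

    def test_candy_cane_seed_direction_near_vertical(self, tracked):
        mask, _, _, _ = tracked("candy_cane")
        p0, p1 = initialize(mask)
        d = (p1 - p0) / np.linalg.norm(p1 - p0)
        assert np.degrees(np.arccos(d @ [0, 0, 1.0])) < 5.0

    def test_too_little_foreground_rejected(self):
        from aortatrace import AortaMask

        vox = np.zeros((20, 20, 20), dtype=np.uint8)
        vox[10, 10, 5] = 1  # 1 mm^2 slice, below the 10 mm^2 floor
        with pytest.raises(InitializationError):
            initialize(AortaMask(vox, np.eye(4)))


class TestWobble:
    def test_recovers_axis_from_tilted_base(self, tracked):
        mask, _, _, _ = tracked("cylinder_r10")
        t = np.deg2rad(10.0)
        frame, area = wobble(
            mask, np.array([0, 0, 40.0]),
            np.array([np.sin(t), 0, np.cos(t)]), TrackingConfig(), 20.0,
        )
        off = np.degrees(np.arccos(abs(frame.normal @ [0, 0, 1.0])))
        assert off <= 0.5  # within one fine wobble step of the true axis
        assert abs(area - 100 * np.pi) / (100 * np.pi) < 0.05

    def test_optimal_base_kept_by_tie_break(self, tracked):
        mask, _, _, _ = tracked("cylinder_r10")
        frame, _ = wobble(mask, np.array([0, 0, 40.0]),
                          np.array([0.0, 0, 1.0]), TrackingConfig(), 20.0)
        off = np.degrees(np.arccos(abs(frame.normal @ [0, 0, 1.0])))
        assert off <= 0.5

    def test_torus_mid_arch_minimal_area(self):
        mask, truth = generate_phantom(
            PhantomSpec(shape="torus_arch", radius=10, major_radius=40)
        )
        mid = truth.centerline(np.array([truth.length / 2]))[0]
        tangent = np.array([-1.0, 0.0, 0.0])  # travel direction at the apex
        frame, _ = wobble(mask, mid, tangent, TrackingConfig(), 20.0)
        from aortatrace import cross_section_at

        sec = cross_section_at(mask, frame, 20.0, 0.5)
        assert abs(sec.area - 100 * np.pi) / (100 * np.pi) < 0.03


class TestTrack:
    def test_cylinder_step_count_tracks_length(self, tracked):
        _, _, trace, _ = tracked("cylinder_r10")
        assert trace.status == "completed"
        # the walk spans the 80 mm phantom minus ~one radius of end margin
        assert 60 <= len(trace) <= 88
        assert abs(trace.arc_lengths[-1] - (len(trace) - 1)) < 0.1 * len(trace)

    @pytest.mark.parametrize("radius", [8, 10, 15])
    def test_diameter_and_centerline_recovery(self, tracked, radius):
        _, truth, trace, _ = tracked(f"cylinder_r{radius}")
        med, rmse = valid_region_stats(trace, truth)
        assert abs(med - 2 * radius) <= max(2 * 0.5, 0.02 * 2 * radius)
        assert rmse < 1.0  # < 1 voxel

    def test_step_length_conservation(self, tracked):
        for name in ("cylinder_r10", "candy_cane"):
            _, _, trace, _ = tracked(name)
            assert trace.status == "completed"
            step = trace.config.step_mm
            d = np.linalg.norm(np.diff(trace.centers, axis=0), axis=1)
            assert (d >= 0.2 * step).all() and (d <= 3.0 * step).all()

    def test_monotone_arc_length(self, tracked):
        _, _, trace, _ = tracked("candy_cane")
        assert (np.diff(trace.arc_lengths) > 0).all()

    def test_candy_cane_per_step_diameter(self, tracked):
        _, truth, trace, _ = tracked("candy_cane")
        s, _ = truth.project(trace.centers)
        lo, hi = truth.valid_range
        keep = (s >= lo) & (s <= hi)
        d = trace.max_diameters[keep]
        assert (np.abs(d - 24.0) <= 2 * 0.5 + 0.02 * 24.0).all()

    def test_wobble_optimality_of_recorded_normals(self, tracked):
        """Perturbing a chosen normal by two fine steps never reveals a
        meaningfully smaller connected area."""
        mask, _, trace, _ = tracked("cylinder_r10")
        cfg = trace.config
        from aortatrace.cross_section import make_frame
        from aortatrace.tracker import _candidate_normals

        for step in trace.steps[5:-5:15]:
            base = make_frame(step.center, step.frame.normal)
            delta = 2 * cfg.wobble_fine_deg
            pairs, normals, _ = _candidate_normals(
                base, np.array([-delta, 0.0, delta]),
                np.array([-delta, 0.0, delta]), 90.0,
            )
            areas = _connected_areas(mask, step.center, normals, 20.0,
                                     cfg.wobble_pitch_mm)
            chosen = areas[(pairs == 0).all(axis=1)][0]
            assert areas.min() >= chosen * (1 - 0.01)

    def test_deterministic_traces(self, tracked):
        mask, _, trace, _ = tracked("cylinder_r8")
        again = track(mask)
        assert again.status == trace.status
        assert np.array_equal(again.centers, trace.centers)
        assert np.array_equal(again.max_diameters, trace.max_diameters)


class TestFailureModes:
    def test_cavitated_tube_interrupts(self, tracked):
        _, truth, trace, _ = tracked("cavitated")
        assert trace.status in ("stalled", "lost_lumen")
        assert trace.arc_lengths[-1] < 0.7 * truth.length

    def test_branch_phantom_flags_suspicion(self, tracked):
        _, _, trace, _ = tracked("branch")
        assert trace.status == "branch_exit_suspected"

    def test_clean_cane_not_flagged(self, tracked):
        _, _, trace, _ = tracked("candy_cane")
        assert trace.status == "completed"
        assert not detect_branch_exit(trace)


class TestDetectBranchExit:
    def test_collapse_never_recovering_flagged(self):
        areas = [450.0] * 30 + [70.0] * 25
        trace = synthetic_trace(2 * np.sqrt(np.array(areas) / np.pi),
                                areas=areas)
        assert detect_branch_exit(trace)

    def test_recovered_dip_not_flagged(self):
        areas = [450.0] * 20 + [120.0] * 3 + [450.0] * 20
        trace = synthetic_trace(2 * np.sqrt(np.array(areas) / np.pi),
                                areas=areas)
        assert not detect_branch_exit(trace)

    def test_short_trace_not_flagged(self):
        trace = synthetic_trace([20.0] * 5)
        assert not detect_branch_exit(trace)


def test_config_validation():
    with pytest.raises(ValueError):
        TrackingConfig(wobble_fine_deg=5.0, wobble_coarse_deg=3.0)
    with pytest.raises(ValueError):
        TrackingConfig(step_mm=-1.0)
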