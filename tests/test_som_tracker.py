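import numpy as np
import pytest

from mealtrack.pointcloud import PointCloud
from mealtrack.som_tracker import (
    _HOPS,
    JointTrack,
    SkeletonModel,
    TrackerParams,
    _fit_energy,
    build_topology,
    detect_fusion,
    estimate_orientation,
    fit_frame,
    init_model,
    reset_model,
    track_sequence,
)


def _cloud(points):
    points = np.asarray(points, dtype=float)
    return PointCloud(points=points, pixels=np.zeros((len(points), 2), dtype=int))


from tests_support import body_cloud as _body_cloud


class TestTopology:
    def test_node_and_joint_counts(self):
        model = SkeletonModel(np.zeros((50, 3)))
        assert model.nodes.shape == (50, 3)
        assert len(model.head_indices) == 9
        assert model.plane_count == 47
        assert len({model.jhd_index, model.jhl_index, model.jhr_index}) == 3

    def test_topology_is_connected(self):
        assert np.isfinite(_HOPS).all()

    def test_edge_list_is_fixed_and_symmetric_free(self):
        edges, torso_map = build_topology()
        assert len(set(edges)) == len(edges)
        assert len(torso_map) == 33  # 5x7 lattice minus the two front corners


class TestInitModel:
    def test_head_nodes_ring_the_highest_point(self, rng):
        pc = _body_cloud(rng)
        top = pc.points[np.argmin(pc.points[:, 2])]
        model = init_model(pc, 0.0)
        for k in model.head_indices:
            assert np.linalg.norm(model.nodes[k] - top) <= 150.0

    def test_orientation_equivariance_of_the_torso(self, rng):
        pc = _body_cloud(rng)
        m0 = init_model(pc, 0.0)
        # same cloud rotated 90 deg about the vertical axis through origin
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        pc90 = _cloud(pc.points @ rot.T)
        m90 = init_model(pc90, 90.0)
        np.testing.assert_allclose(m90.nodes, m0.nodes @ rot.T, atol=1e-6)

    def test_small_clouds_are_rejected(self, rng):
        with pytest.raises(ValueError):
            init_model(_cloud(rng.normal(size=(10, 3))))
        with pytest.raises(ValueError):
            init_model(_cloud(np.zeros((0, 3))))

    def test_estimated_orientation_points_at_the_arms(self, rng):
        for facing in (0.0, 90.0, -135.0):
            pc = _body_cloud(rng, facing_deg=facing)
            est = estimate_orientation(pc)
            delta = (est - facing + 180.0) % 360.0 - 180.0
            assert abs(delta) < 35.0


class TestFitFrame:
    def test_converged_model_is_a_fixed_point(self, rng):
        pc = _body_cloud(rng)
        params = TrackerParams(seed=0)
        model = init_model(pc, 0.0)
        for _ in range(30):
            model = fit_frame(model, pc, params)
        moved = fit_frame(model, pc, params)
        assert np.linalg.norm(moved.nodes - model.nodes, axis=1).max() < 1.0

    def test_translation_covariance_is_exact(self, rng):
        # fitting a translated cloud from a translated start is the
        # translated fit, to float precision
        pc = _body_cloud(rng)
        params = TrackerParams(seed=0)
        t = np.array([50.0, -30.0, 20.0])
        model = init_model(pc, 0.0)
        plain = fit_frame(model, pc, params)
        moved = fit_frame(
            SkeletonModel(model.nodes + t, 0.0), _cloud(pc.points + t), params
        )
        np.testing.assert_allclose(moved.nodes, plain.nodes + t, atol=1e-6)

    def test_warm_start_follows_a_translated_cloud(self, rng):
        # a 50 mm cloud shift is recovered by warm-started tracking to
        # within the fit's static accuracy on a sparse cloud
        pc = _body_cloud(rng)
        params = TrackerParams(seed=0)
        model = init_model(pc, 0.0)
        for _ in range(20):
            model = fit_frame(model, pc, params)
        shifted = _cloud(pc.points + [50.0, 0.0, 0.0])
        fit_shift = model
        for _ in range(30):
            fit_shift = fit_frame(fit_shift, shifted, params)
        for joint in ("jhd", "jhl", "jhr"):
            expected = getattr(model, joint) + [50.0, 0.0, 0.0]
            assert np.linalg.norm(getattr(fit_shift, joint) - expected) < 30.0

    def test_energy_never_increases(self, rng):
        pc = _body_cloud(rng)
        params = TrackerParams(seed=1)
        model = init_model(pc, 0.0)
        # perturb hard so the fit has work to do
        model.nodes += rng.normal(0, 120, size=model.nodes.shape)
        for _ in range(10):
            before = _fit_energy(model.nodes, pc.points)
            model = fit_frame(model, pc, params)
            after = _fit_energy(model.nodes, pc.points)
            assert after <= before + 1e-9

    def test_nodes_stay_inside_inflated_bounding_box(self, rng):
        pc = _body_cloud(rng)
        params = TrackerParams(seed=2)
        model = init_model(pc, 0.0)
        model.nodes += rng.normal(0, 400, size=model.nodes.shape)
        model = fit_frame(model, pc, params)
        lo = pc.points.min(axis=0) - 100.0
        hi = pc.points.max(axis=0) + 100.0
        assert (model.nodes >= lo).all() and (model.nodes <= hi).all()

    def test_degenerate_cloud_contracts_without_error(self):
        pc = _cloud(np.tile([100.0, 50.0, 1500.0], (60, 1)))
        model = init_model(pc, 0.0)
        for _ in range(5):
            model = fit_frame(model, pc, TrackerParams(seed=0))
        assert np.isfinite(model.nodes).all()

    def test_empty_cloud_is_an_error(self):
        model = SkeletonModel(np.zeros((50, 3)))
        with pytest.raises(ValueError):
            fit_frame(model, _cloud(np.zeros((0, 3))), TrackerParams())


def _track_with_distances(left, right):
    """Handcrafted JointTrack whose distance series are given directly."""
    track = JointTrack()
    jhd = np.zeros(3)
    for i, (dl, dr) in enumerate(zip(left, right)):
        model = SkeletonModel(np.zeros((50, 3)))
        model.nodes[model.jhl_index] = [dl, 0.0, 0.0]
        model.nodes[model.jhr_index] = [dr, 0.0, 0.0]
        track.append(i + 1, model)
    return track


class TestFusionDetection:
    def test_sustained_left_fusion_is_reported(self):
        track = _track_with_distances([100.0] * 150, [400.0] * 150)
        assert detect_fusion(track, TrackerParams()) == "left"

    def test_one_break_in_the_streak_resets_it(self):
        left = [100.0] * 149 + [250.0]
        track = _track_with_distances(left, [400.0] * 150)
        assert detect_fusion(track, TrackerParams()) == "none"

    def test_separated_hands_never_fuse(self):
        track = _track_with_distances([300.0] * 200, [420.0] * 200)
        assert detect_fusion(track, TrackerParams()) == "none"

    def test_short_tracks_report_none(self):
        track = _track_with_distances([100.0] * 10, [100.0] * 10)
        assert detect_fusion(track, TrackerParams()) == "none"


class TestReset:
    def test_post_reset_joints_are_separated(self, rng):
        pc = _body_cloud(rng)
        params = TrackerParams()
        fused = init_model(pc, 0.0)
        fused.nodes[fused.jhl_index] = fused.nodes[fused.jhd_index] + [30.0, 0, 0]
        model = reset_model(fused, pc)
        assert np.linalg.norm(model.jhl - model.jhd) > params.fusion_dist_mm
        assert np.linalg.norm(model.jhr - model.jhd) > params.fusion_dist_mm

    def test_reset_equals_init_and_is_idempotent(self, rng):
        pc = _body_cloud(rng)
        model = init_model(pc, 25.0)
        once = reset_model(model, pc)
        twice = reset_model(once, pc)
        np.testing.assert_array_equal(once.nodes, init_model(pc, 25.0).nodes)
        np.testing.assert_array_equal(once.nodes, twice.nodes)


class TestTrackSequence:
    def test_invalid_bounds_are_an_error(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        with pytest.raises(ValueError):
            track_sequence(
                frames, 50, 10, TrackerParams(), background=background, camera=script.camera
            )

    def test_quiet_meal_has_no_resets_and_is_deterministic(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        params = TrackerParams(subsample=600, seed=3, fusion_frames=210)
        kwargs = dict(
            background=background,
            camera=script.camera,
            min_area_px=int(mini_cfg.person_min_area_px),
        )
        track = track_sequence(frames, truth.sf_true, truth.ef_true, params, **kwargs)
        assert len(track) == truth.ef_true - truth.sf_true + 1
        assert not any(track.reset_flag)
        again = track_sequence(frames, truth.sf_true, truth.ef_true, params, **kwargs)
        np.testing.assert_array_equal(track.to_frame().values, again.to_frame().values)

    def test_long_hold_at_the_head_triggers_a_reset(self, mini_scene, mini_cfg):
        # the scripted action dwells >5 s within the fusion distance, so the
        # default 150-frame window must fire during it
        script, frames, truth, background = mini_scene
        track = track_sequence(
            frames,
            truth.sf_true,
            truth.ef_true,
            TrackerParams(subsample=600, seed=3),
            background=background,
            camera=script.camera,
            min_area_px=int(mini_cfg.person_min_area_px),
        )
        assert sum(track.reset_flag) >= 1
        s, e = truth.action_windows[0]
        reset_frame = track.frames[int(np.flatnonzero(track.reset_flag)[0])]
        assert s <= reset_frame <= e + 25

    def test_absent_person_freezes_the_model(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        v = script.visits[0]
        track = track_sequence(
            frames,
            truth.ef_true,
            len(frames),
            TrackerParams(subsample=600, seed=4),
            background=background,
            camera=script.camera,
            min_area_px=int(mini_cfg.person_min_area_px),
        )
        assert track.absent[-1]
        assert np.isnan(track.distances("left")[-1])

    def test_arm_approaches_the_head_during_an_action(self, mini_scene, mini_cfg):
        script, frames, truth, background = mini_scene
        params = TrackerParams(subsample=600, seed=5, fusion_frames=10**6)
        track = track_sequence(
            frames,
            truth.sf_true,
            truth.ef_true,
            params,
            background=background,
            camera=script.camera,
            min_area_px=int(mini_cfg.person_min_area_px),
        )
        s, e = truth.action_windows[0]
        dist = track.distances("right")
        during = dist[s - truth.sf_true : e - truth.sf_true + 1]
        rest = dist[: max(s - truth.sf_true - 30, 1)]
        assert np.nanmedian(during) < 200.0 < np.nanmin(rest)
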