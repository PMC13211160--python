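"""Convex-hull volumes: exact solids, oracles, invariances, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drivehull import (
    NoDrivesError,
    NoPointsError,
    TrimConfig,
    hull_evolution,
    hull_volume,
    participant_volume,
    trim_centiles,
)

UNIT_CUBE = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
)
TETRAHEDRON = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
)


def mc_volume(points, n_samples, rng):
    """Monte-Carlo rejection-sampling hull volume (independent oracle)."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    box = np.prod(hi - lo)
    draws = rng.uniform(lo, hi, (n_samples, 3))
    inside = np.all(
        draws @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1
    )
    p = inside.mean()
    return box * p, box * np.sqrt(p * (1 - p) / n_samples)


class TestTrimCentiles:
    def test_identical_points_all_retained(self):
        pts = np.tile([0.3, -0.2, -1.0], (100, 1))
        assert len(trim_centiles(pts)) == 100

    def test_disabled_is_identity(self, rng):
        pts = rng.normal(size=(500, 3))
        out = trim_centiles(pts, TrimConfig(enabled=False))
        np.testing.assert_array_equal(out, pts)

    def test_planted_outlier_removed_matches_bruteforce(self, rng):
        pts = np.vstack([rng.standard_normal((1000, 3)), [[50.0, 50.0, 50.0]]])
        out = trim_centiles(pts, TrimConfig(1.0, 99.0))
        assert not np.any(np.all(out == [50.0, 50.0, 50.0], axis=1))
        # brute-force per-axis order-statistic filter
        keep = np.ones(len(pts), dtype=bool)
        for ax in range(3):
            lo = np.percentile(pts[:, ax], 1.0)
            hi = np.percentile(pts[:, ax], 99.0)
            keep &= (pts[:, ax] >= lo) & (pts[:, ax] <= hi)
        assert len(out) == keep.sum()

    def test_empty_cloud_rejected(self):
        with pytest.raises(NoPointsError):
            trim_centiles(np.empty((0, 3)))


class TestHullVolume:
    def test_unit_cube_is_exactly_one(self):
        res = hull_volume(UNIT_CUBE)
        assert res.volume_g3 == 1.0
        assert res.n_hull_vertices == 8
        assert not res.degenerate

    def test_tetrahedron_is_one_sixth(self):
        assert hull_volume(TETRAHEDRON).volume_g3 == pytest.approx(1 / 6, abs=1e-12)

    @pytest.mark.parametrize(
        "pts",
        [
            np.array([[0.0, 0, 0], [1, 1, 1], [2, 2, 2]]),  # 3 points
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),  # coplanar
            np.tile([0.1, 0.2, 0.3], (10, 1)),  # coincident
        ],
    )
    def test_degenerate_clouds_get_zero_volume(self, pts):
        res = hull_volume(pts)
        assert res.volume_g3 == 0.0
        assert res.degenerate

    def test_empty_cloud_is_an_error(self):
        with pytest.raises(NoPointsError):
            hull_volume(np.empty((0, 3)))

    def test_ball_cloud_matches_monte_carlo(self, rng):
        pts = rng.standard_normal((300, 3))
        pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1.0)
        res = hull_volume(pts)
        est, se = mc_volume(pts, 200_000, rng)
        assert abs(res.volume_g3 - est) <= 3 * se

    def test_monotone_under_point_insertion(self, rng):
        pts = rng.standard_normal((40, 3))
        vol = hull_volume(pts).volume_g3
        for extra in rng.standard_normal((10, 3)) * 2:
            new_vol = hull_volume(np.vstack([pts, extra])).volume_g3
            assert new_vol >= vol - 1e-12
            pts, vol = np.vstack([pts, extra]), new_vol


class TestHullInvariances:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((60, 3))
        quat = rng.normal(size=4)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_quat(quat / np.linalg.norm(quat))
        moved = rot.apply(pts) + rng.normal(size=3)
        v0 = hull_volume(pts).volume_g3
        v1 = hull_volume(moved).volume_g3
        assert v1 == pytest.approx(v0, rel=1e-9)

    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0, allow_nan=False),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scaling_law_s_cubed(self, seed, scale):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((40, 3))
        v0 = hull_volume(pts).volume_g3
        v1 = hull_volume(pts * scale).volume_g3
        assert v1 == pytest.approx(v0 * scale**3, rel=1e-9)


class TestHullEvolution:
    def test_single_slice_equals_full_volume(self, rng):
        pts = rng.standard_normal((200, 3))
        (res,) = hull_evolution(pts, 1)
        assert res.volume_g3 == hull_volume(pts).volume_g3

    def test_quarters_nondecreasing_and_terminate_at_full(self, rng):
        pts = rng.standard_normal((400, 3))
        results = hull_evolution(pts, 4)
        vols = [r.volume_g3 for r in results]
        assert vols == sorted(vols)
        assert vols[-1] == hull_volume(pts).volume_g3

    def test_prefix_recomputation_oracle(self, rng):
        pts = rng.standard_normal((100, 3))
        results = hull_evolution(pts, 5)
        for k, res in enumerate(results):
            end = int(round(len(pts) * (k + 1) / 5))
            assert res.volume_g3 == hull_volume(pts[:end]).volume_g3

    def test_constant_signal_all_zero(self):
        pts = np.tile([0.0, 0.0, -1.0], (100, 1))
        assert all(r.volume_g3 == 0.0 for r in hull_evolution(pts, 4))

    def test_time_sliced_matches_count_sliced_on_uniform_grid(self, rng):
        pts = rng.standard_normal((200, 3))
        t = np.arange(200) / 10.0
        a = [r.volume_g3 for r in hull_evolution(pts, 4, t=t)]
        b = [r.volume_g3 for r in hull_evolution(pts, 4)]
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestParticipantVolume:
    def test_single_drive_pooled_equals_mean(self, rng):
        cloud_w = rng.standard_normal((200, 3))
        cloud_v = rng.standard_normal((200, 3)) * 0.1
        pooled = participant_volume("P1", [cloud_w], [cloud_v], aggregation="pooled")
        mean = participant_volume(
            "P1", [cloud_w], [cloud_v], aggregation="mean_per_drive"
        )
        assert pooled.wrist_volume_g3 == pytest.approx(mean.wrist_volume_g3)

    def test_duplicate_clouds_idempotent(self, rng):
        cloud = rng.standard_normal((150, 3))
        pv = participant_volume("P1", [cloud, cloud], [cloud, cloud])
        per_drive = pv.per_drive_volumes[0][1]
        assert pv.wrist_volume_g3 == pytest.approx(per_drive)

    def test_disjoint_clouds_pooled_geq_max(self, rng):
        a = rng.standard_normal((150, 3))
        b = rng.standard_normal((150, 3)) + 10.0
        pv = participant_volume("P1", [a, b], [a * 0.1, b * 0.1])
        assert pv.wrist_volume_g3 >= max(v[1] for v in pv.per_drive_volumes)

    def test_no_drives_is_an_error(self):
        with pytest.raises(NoDrivesError):
            participant_volume("P1", [], [])

    def test_mismatched_lists_rejected(self, rng):
        cloud = rng.standard_normal((50, 3))
        with pytest.raises(ValueError):
            participant_volume("P1", [cloud], [])
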