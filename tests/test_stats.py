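"""SD_UG index, weighted root aggregation, L-function, grid map, group stats."""

import numpy as np
import pytest

from fiberclust import (
    ClusteringIndex,
    NullDistribution,
    correlate,
    generate_csr,
    grid_intensity,
    ground_truth_distance,
    group_compare,
    normalized_l_function,
    sdug,
    simulate_null,
    weighted_root_sdug,
)
from fiberclust.exceptions import ConsistencyError, InsufficientPointsError
from fiberclust.stats import SdugResult, _l_norm

from conftest import make_fascicle


def _null(k=1, n=4, d_s=(1.0, 1.2), **kw):
    return NullDistribution(k=k, n=n, d_s=np.array(d_s), **kw)


class TestGroundTruthDistance:
    def test_square_corner_fascicle(self, unit_square):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        fas = make_fascicle(unit_square, corners)
        assert ground_truth_distance(fas, k=1) == pytest.approx(1.0)

    def test_scope_with_too_few_fibers(self, unit_square):
        fas = make_fascicle(unit_square, np.array([[0.1, 0.1], [0.2, 0.2], [0.3, 0.1]]))
        for f in fas.fibers:
            f.fiber_class = "PPN"
        with pytest.raises(InsufficientPointsError, match="smaller k"):
            ground_truth_distance(fas, k=50, scope="PPN")

    def test_whole_scope_equals_unfiltered(self, unit_square):
        rng = np.random.default_rng(0)
        fas = make_fascicle(unit_square, rng.uniform(0, 1, (30, 2)))
        assert ground_truth_distance(fas, 3, scope="whole") == ground_truth_distance(fas, 3)


class TestSdug:
    def test_zero_when_d_g_equals_d_u(self, unit_square):
        """Constructed null with D_U == observed D_G -> index 0."""
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        fas = make_fascicle(unit_square, corners)
        null = _null(k=1, n=4, d_s=(0.9, 1.1))  # D_U = 1.0 = D_G
        assert sdug(fas, null).sd_ug == pytest.approx(0.0)

    def test_minus_two_sigma(self, unit_square):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        fas = make_fascicle(unit_square, corners)
        sigma = 0.25
        null = _null(k=1, n=4, d_s=(1.5 - sigma / np.sqrt(2), 1.5 + sigma / np.sqrt(2)))
        res = sdug(fas, null)  # D_G=1.0, D_U=1.5 -> (1.0-1.5)/0.25 = -2
        assert res.sd_ug == pytest.approx(-2.0)
        assert res.clustered

    def test_n_mismatch_rejected(self, unit_square):
        fas = make_fascicle(unit_square, np.array([[0, 0], [1, 0], [1, 1]], dtype=float))
        with pytest.raises(ConsistencyError, match="n="):
            sdug(fas, _null(k=1, n=4))

    def test_k_mismatch_rejected(self, unit_square):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        fas = make_fascicle(unit_square, corners)
        with pytest.raises(ConsistencyError, match="k="):
            sdug(fas, _null(k=2, n=4), k=1)

    def test_csr_replicates_approximately_standard_normal(self, root_region):
        """SD_UG of uniform draws scored against their own null: mean ~ 0,
        spread ~ 1 (it is a standardized draw by construction)."""
        ss = np.random.SeedSequence(202)
        vals = []
        for i, child in enumerate(ss.spawn(60)):
            rng = np.random.default_rng(child)
            pat = generate_csr(root_region, 300, rng)
            null = simulate_null(
                root_region, n=300, k=30, n_simulations=80,
                random_state=np.random.SeedSequence((i + 1) * 7919),
            )
            vals.append(sdug(pat.to_fascicle(), null).sd_ug)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 0.3
        assert 0.7 < vals.std(ddof=1) < 1.3

    def test_translation_and_scale_invariance(self, square_with_hole):
        """Rigid translation or uniform scaling of region + fibers leaves
        SD_UG unchanged (same seed stream in the transformed frame)."""
        rng = np.random.default_rng(8)
        pts = generate_csr(square_with_hole, 60, rng).points
        base_fas = make_fascicle(square_with_hole, pts)
        null = simulate_null(square_with_hole, n=60, k=5, n_simulations=40, random_state=1)
        base = sdug(base_fas, null).sd_ug

        c = 2.0
        scaled_fas = make_fascicle(square_with_hole.scaled(c), pts * c)
        null_s = simulate_null(
            square_with_hole.scaled(c), n=60, k=5, n_simulations=40, random_state=1
        )
        assert sdug(scaled_fas, null_s).sd_ug == pytest.approx(base, rel=1e-9)

        moved = square_with_hole.translated(5.0, -3.0)
        moved_fas = make_fascicle(moved, pts + np.array([5.0, -3.0]))
        null_t = simulate_null(moved, n=60, k=5, n_simulations=40, random_state=1)
        assert sdug(moved_fas, null_t).sd_ug == pytest.approx(base, rel=1e-6)


class TestWeightedRootSdug:
    def test_single_fascicle_unchanged(self):
        assert weighted_root_sdug([(100, -7.5)]) == -7.5

    def test_worked_example(self):
        assert weighted_root_sdug([(100, -10.0), (50, -4.0)]) == pytest.approx(-8.0)

    def test_equal_weights_arithmetic_mean(self):
        assert weighted_root_sdug([(10, -2.0), (10, -6.0), (10, -1.0)]) == pytest.approx(-3.0)

    def test_convexity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pairs = [(int(n), float(s)) for n, s in
                     zip(rng.integers(1, 500, 4), rng.normal(-10, 8, 4))]
            w = weighted_root_sdug(pairs)
            vals = [s for _, s in pairs]
            assert min(vals) - 1e-12 <= w <= max(vals) + 1e-12

    def test_empty_and_bad_weights(self):
        with pytest.raises(ValueError):
            weighted_root_sdug([])
        with pytest.raises(ValueError):
            weighted_root_sdug([(0, -1.0)])

    def test_accepts_sdug_results(self):
        null = _null(k=1, n=2)
        a = SdugResult(d_g=1.0, sd_ug=-10.0, k=1, n=100, null=null)
        b = SdugResult(d_g=1.0, sd_ug=-4.0, k=1, n=50, null=null)
        assert weighted_root_sdug([a, b]) == pytest.approx(-8.0)


class TestLFunction:
    def test_csr_within_envelope(self, root_region):
        """A uniform pattern stays inside the 99-simulation envelope at
        >= 95% of radii."""
        rng = np.random.default_rng(12)
        fas = generate_csr(root_region, 300, rng).to_fascicle()
        curve = normalized_l_function(fas, n_simulations=99, random_state=5)
        inside = (curve.l_norm >= curve.envelope_lo) & (curve.l_norm <= curve.envelope_hi)
        assert inside.mean() >= 0.95

    def test_tight_blob_exceeds_envelope(self, root_region):
        """50 points in a tight blob push L(r) - r far above the envelope."""
        rng = np.random.default_rng(13)
        blob = rng.normal(0.0, 2.0, size=(50, 2))  # ~4 µm blob in a 400 µm region
        fas = make_fascicle(root_region, blob)
        curve = normalized_l_function(fas, n_simulations=49, random_state=6)
        above = curve.l_norm > curve.envelope_hi
        assert above[curve.radii >= 8.0].all()

    def test_single_fiber_errors(self, unit_square):
        fas = make_fascicle(unit_square, np.array([[0.5, 0.5]]))
        with pytest.raises(InsufficientPointsError):
            normalized_l_function(fas)

    def test_k_markers_present_and_ordered(self, root_region):
        rng = np.random.default_rng(14)
        fas = generate_csr(root_region, 200, rng).to_fascicle()
        curve = normalized_l_function(
            fas, n_simulations=20, k_markers=(25, 50, 75), random_state=7
        )
        assert set(curve.k_markers) == {25, 50, 75}
        assert curve.k_markers[25] < curve.k_markers[50] < curve.k_markers[75]

    def test_radius_beyond_region_warns(self, unit_square):
        fas = make_fascicle(unit_square, np.random.default_rng(0).uniform(0, 1, (20, 2)))
        with pytest.warns(UserWarning, match="diameter"):
            normalized_l_function(
                fas, radii=np.array([0.5, 5.0]), n_simulations=5, random_state=0
            )

    def test_k_hat_non_decreasing(self, root_region):
        rng = np.random.default_rng(15)
        pts = generate_csr(root_region, 150, rng).points
        radii = np.linspace(1, 120, 60)
        l_norm = _l_norm(pts, root_region.admissible_area, radii)
        k_hat = np.pi * (l_norm + radii) ** 2
        assert (np.diff(k_hat) >= -1e-9).all()


class TestGridIntensity:
    def test_single_center_point(self, unit_square):
        fas = make_fascicle(unit_square, np.array([[0.5, 0.5]]))
        gi = grid_intensity(fas, 6, 6)
        assert gi.counts.sum() == 1
        assert gi.counts.max() == 1

    def test_one_point_per_cell(self, unit_square):
        centers = (np.arange(6) + 0.5) / 6
        pts = np.array([[x, y] for x in centers for y in centers])
        gi = grid_intensity(make_fascicle(unit_square, pts), 6, 6)
        assert (gi.counts == 1).all()

    def test_counts_conserved_random(self, root_region):
        rng = np.random.default_rng(21)
        for n in (1, 17, 400):
            fas = generate_csr(root_region, n, rng).to_fascicle()
            gi = grid_intensity(fas, 6, 6)
            assert gi.counts.sum() == n

    def test_boundary_points_included(self, unit_square):
        """Points on the top/right bbox edges land in the last cells."""
        fas = make_fascicle(unit_square, np.array([[1.0, 1.0], [0.0, 0.0]]))
        gi = grid_intensity(fas, 3, 3)
        assert gi.counts.sum() == 2
        assert gi.counts[2, 2] == 1 and gi.counts[0, 0] == 1

    def test_bad_grid_dimensions(self, unit_square):
        fas = make_fascicle(unit_square, np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            grid_intensity(fas, 0, 6)


class TestGroupStats:
    def test_separated_groups_exact(self):
        res = group_compare([1, 2, 3], [10, 11, 12])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["U"] == pytest.approx(8.0)  # n^2/2
        assert res["p"] > 0.9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        r1 = group_compare(a, b)
        r2 = group_compare(rng.permutation(a), rng.permutation(b))
        assert r1 == r2

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])

    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        res = correlate(x, -2 * x + 1)
        assert res["pearson_r"] == pytest.approx(-1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_correlate_worked_example(self):
        res = correlate([1, 2, 3], [1, 2, 4])
        assert res["pearson_r"] == pytest.approx(0.98198, abs=1e-5)
        assert res["r_squared"] == pytest.approx(0.96429, abs=1e-5)

    def test_constant_y_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 2, 3], [5, 5, 5])


class TestClusteringIndexEstimator:
    def test_fit_sets_attributes_and_score(self, root_region):
        rng = np.random.default_rng(31)
        pts = generate_csr(root_region, 120, rng).points
        est = ClusteringIndex(k=10, n_simulations=50, random_state=0)
        est.fit(pts, region=root_region)
        assert hasattr(est, "sd_ug_") and hasattr(est, "d_g_") and est.null_.k == 10
        assert est.score() == est.sd_ug_

    def test_sklearn_params_round_trip(self):
        est = ClusteringIndex(k=25, n_simulations=10, random_state=3)
        clone = ClusteringIndex(**est.get_params())
        assert clone.get_params() == est.get_params()

    def test_precomputed_null_must_match(self, root_region):
        pts = np.random.default_rng(0).uniform(-50, 50, (30, 2))
        null = _null(k=5, n=29, d_s=(3.0, 3.5))
        with pytest.raises(ConsistencyError):
            ClusteringIndex(k=5).fit(pts, null=null)

    def test_bad_shape_rejected(self, root_region):
        with pytest.raises(ValueError, match=r"\(n, 2\)"):
            ClusteringIndex(k=2).fit(np.zeros((5, 3)), region=root_region)
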