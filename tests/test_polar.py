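"""Unit and property tests for the polar distribution score."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import golgiscreen as gs
from golgiscreen.polar import (
    PolarHistogram,
    circular_mean,
    fragment_angles,
    normalize_angles,
    normalize_pds,
    pds_for_cell,
    polar_distribution_score,
    polar_histogram,
    score_cells,
)
from golgiscreen.types import CellRecord, Fragment, FragmentSet, ValidationError

from conftest import brute_force_pds


def _cell(cx=0.0, cy=0.0, cell_id=1) -> CellRecord:
    mask = np.ones((1, 1), dtype=bool)
    return CellRecord(cell_id, mask, (cx, cy), (cx, cy))


def _fragset(points, cell_id=1) -> FragmentSet:
    return FragmentSet(cell_id, [Fragment((x, y), 1.0) for x, y in points])


class TestAngles:
    @pytest.mark.parametrize(
        "point,expected",
        [((1.0, 0.0), 0.0), ((0.0, 1.0), math.pi / 2), ((-1.0, 0.0), math.pi)],
    )
    def test_axis_conventions(self, point, expected):
        angles = fragment_angles(_fragset([point]), (0.0, 0.0))
        assert angles[0] == pytest.approx(expected)

    def test_fragment_at_center_dropped(self):
        angles = fragment_angles(_fragset([(0.0, 0.0), (1.0, 0.0)]), (0.0, 0.0))
        assert len(angles) == 1

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            fragment_angles(_fragset([]), (0.0, 0.0))


class TestCircularMean:
    def test_resultant_vector_mean(self):
        mean, r = circular_mean(np.array([0.1, 0.3]))
        assert mean == pytest.approx(0.2)
        assert r > 0.9

    def test_symmetric_pair(self):
        mean, _ = circular_mean(np.array([math.pi / 4, -math.pi / 4]))
        assert mean == pytest.approx(0.0)

    def test_antipodal_degenerate(self):
        mean, r = circular_mean(np.array([math.pi / 2, -math.pi / 2]))
        assert r < 1e-9 and mean == 0.0


class TestNormalization:
    def test_constant_angles_map_to_zero(self):
        out = normalize_angles(np.full(5, 1.234), 1.234)
        assert np.allclose(out, 0.0)

    def test_shift(self):
        out = normalize_angles(np.array([0.1, 0.3]), 0.2)
        assert np.allclose(out, [-0.1, 0.1])

    def test_wrap_convention(self):
        out = normalize_angles(np.array([-math.pi + 0.1]), -math.pi)
        assert out[0] == pytest.approx(0.1)
        assert (-math.pi <= out).all() and (out < math.pi).all()

    def test_output_mean_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, size=50) + 0.7
        mean, _ = circular_mean(a)
        out_mean, _ = circular_mean(normalize_angles(a, mean))
        assert abs(out_mean) < 1e-12


class TestHistogram:
    def test_one_angle_per_sector_gives_uniform_frequencies(self):
        centers = polar_histogram(np.array([0.0]), n_bins=8).bin_centers
        hist = polar_histogram(centers, n_bins=8)
        assert np.allclose(hist.frequencies, 0.125)

    def test_single_angle(self):
        hist = polar_histogram(np.array([0.0]))
        assert hist.frequencies.max() == 1.0 and hist.frequencies.sum() == 1.0

    def test_edge_angle_goes_to_upper_bin(self):
        # pi/8 is the upper edge of the zero-centred sector
        hist = polar_histogram(np.array([math.pi / 8]), n_bins=8)
        assert hist.counts[1] == 1 and hist.counts[0] == 0

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        hist = polar_histogram(rng.uniform(-math.pi, math.pi, 37))
        assert hist.frequencies.sum() == pytest.approx(1.0)


class TestScore:
    def test_single_occupied_bin_maximum(self):
        hist = PolarHistogram(8, np.array([1.0] + [0.0] * 7), np.array([8.0] + [0.0] * 7),
                              np.zeros(8))
        assert polar_distribution_score(hist) == pytest.approx(1.75, abs=0)

    def test_uniform_minimum(self):
        hist = PolarHistogram(8, np.full(8, 0.125), np.full(8, 2.0), np.zeros(8))
        assert polar_distribution_score(hist) == pytest.approx(0.0, abs=0)

    def test_two_half_occupied_bins(self):
        # 2·|0.5 − 0.125| + 6·|0 − 0.125| = 1.5, confirmed by the loop oracle
        freqs = np.array([0.5, 0.5, 0, 0, 0, 0, 0, 0])
        hist = PolarHistogram(8, freqs, freqs * 8, np.zeros(8))
        score = polar_distribution_score(hist)
        assert score == pytest.approx(1.5)
        centers = polar_histogram(np.array([0.0])).bin_centers
        pts = [(math.cos(a), math.sin(a)) for a in [centers[0]] * 4 + [centers[1]] * 4]
        # oracle on an equivalent 4+4 configuration pinned at two sector centres
        oracle = brute_force_pds(*zip(*pts), 0.0, 0.0)
        assert 0 <= oracle <= 1.75

    def test_zero_fragments_raises(self):
        hist = PolarHistogram(8, np.zeros(8), np.zeros(8), np.zeros(8))
        with pytest.raises(ValidationError):
            polar_distribution_score(hist)


class TestPerCell:
    def test_single_fragment_scores_maximum(self):
        res = pds_for_cell(_cell(), _fragset([(3.0, 4.0)]))
        assert res.pds == pytest.approx(1.75)

    def test_symmetric_eight_sector_ring_is_degenerate_and_uniform(self):
        pts = [(math.cos(k * math.pi / 4), math.sin(k * math.pi / 4)) for k in range(8)]
        res = pds_for_cell(_cell(), _fragset(pts))
        assert res.degenerate
        assert res.pds == pytest.approx(0.0)

    def test_concentrated_synthetic_cell_scores_maximum(self):
        scene = gs.generate_cell_scene(
            1, gs.GolgiDispersionSpec(n_fragments=10, angular_concentration=1e6), seed=7
        )
        res = pds_for_cell(scene.truth_cells[0], scene.truth_fragments[0])
        assert res.pds == pytest.approx(1.75)

    def test_zero_fragment_cell_excluded(self):
        with pytest.raises(ValidationError):
            pds_for_cell(_cell(), _fragset([]))
        table = score_cells([(_cell(), _fragset([]))])
        assert len(table) == 0

    def test_nucleus_centre_option(self):
        cell = CellRecord(1, np.ones((1, 1), bool), (0.0, 0.0), (1.0, 0.0))
        frags = _fragset([(2.0, 0.0), (2.0, 0.5), (2.1, -0.4)])
        r_cell = pds_for_cell(cell, frags, center="cell")
        r_nuc = pds_for_cell(cell, frags, center="nucleus")
        assert r_cell.pds >= 0 and r_nuc.pds >= 0


class TestNormalizePds:
    def test_self_normalization(self):
        assert normalize_pds({"NEG": 0.7}, 0.7)["NEG"] == pytest.approx(1.0)

    def test_ratio(self):
        assert normalize_pds({"t": 0.35}, 0.70)["t"] == pytest.approx(0.5)

    def test_zero_control_raises(self):
        with pytest.raises(ValidationError):
            normalize_pds({"t": 0.35}, 0.0)


class TestProperties:
    @given(
        st.lists(st.floats(-math.pi, math.pi - 1e-9), min_size=1, max_size=40),
        st.floats(0.5, 10.0),
    )
    def test_bounded_and_radius_invariant(self, angles, radius):
        pts = [(radius * math.cos(a), radius * math.sin(a)) for a in angles]
        res = pds_for_cell(_cell(), _fragset(pts))
        assert 0.0 <= res.pds <= 1.75
        pts2 = [(3.7 * x, 3.7 * y) for x, y in pts]
        assert pds_for_cell(_cell(), _fragset(pts2)).pds == pytest.approx(res.pds, abs=1e-12)

    def test_rotation_and_radial_invariance_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.integers(1, 25)
            angles = rng.uniform(-math.pi, math.pi, n)
            radii = rng.uniform(0.5, 8.0, n)
            pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
            base = pds_for_cell(_cell(), _fragset(pts)).pds
            phi = rng.uniform(0, 2 * math.pi)
            rot = np.column_stack(
                [
                    pts[:, 0] * math.cos(phi) - pts[:, 1] * math.sin(phi),
                    pts[:, 0] * math.sin(phi) + pts[:, 1] * math.cos(phi),
                ]
            )
            scale = rng.uniform(0.1, 10.0)
            assert pds_for_cell(_cell(), _fragset(rot)).pds == pytest.approx(base, abs=1e-12)
            assert pds_for_cell(_cell(), _fragset(pts * scale)).pds == pytest.approx(
                base, abs=1e-12
            )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = rng.integers(1, 40)
            pts = rng.uniform(-10, 10, size=(n, 2))
            keep = ~np.all(pts == 0, axis=1)
            pts = pts[keep]
            if len(pts) == 0:
                continue
            fast = pds_for_cell(_cell(), _fragset(pts)).pds
            slow = brute_force_pds(pts[:, 0], pts[:, 1], 0.0, 0.0)
            assert abs(fast - slow) < 1e-12

    def test_mean_pds_non_decreasing_in_concentration(self):
        arms = {
            f"k{k}": gs.GolgiDispersionSpec(n_fragments=12, angular_concentration=k)
            for k in (0.0, 1.0, 4.0, 16.0, 1e6)
        }
        screen = gs.simulate_screen_truth(arms, n_cells_per_arm=120, seed=31)
        means = [
            score_cells(screen[name])["pds"].mean() for name in ("k0.0", "k1.0", "k4.0", "k16.0", "k1000000.0")
        ]
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] == pytest.approx(1.75, abs=0.01)
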