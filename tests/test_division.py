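"""Tests for pole detection, division angles, rotation tracking, and rose
histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import square_contour
from mitopolar import _angles, division, synthgen
from mitopolar.errors import DetectionError, GeometryError, InputError, RangeError


def blob_image(centers, sigma=2.0, size=64, amplitude=100.0):
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for cx, cy in centers:
        img += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return img


class TestDetectPoles:
    def test_two_clean_blobs_within_half_pixel(self):
        img = blob_image([(20.0, 20.0), (30.0, 20.0)])
        contour = square_contour(cx=25, cy=20, half=15)
        (xa, ya), (xb, yb) = division.detect_poles(img, contour)
        found = sorted([(xa, ya), (xb, yb)])
        assert abs(found[0][0] - 20.0) < 0.5 and abs(found[0][1] - 20.0) < 0.5
        assert abs(found[1][0] - 30.0) < 0.5 and abs(found[1][1] - 20.0) < 0.5

    def test_single_blob_raises(self):
        img = blob_image([(25.0, 25.0)])
        contour = square_contour(cx=25, cy=25, half=15)
        with pytest.raises(DetectionError):
            division.detect_poles(img, contour)

    def test_horizontal_axis_is_ninety_degrees(self):
        img = blob_image([(20.0, 30.0), (40.0, 30.0)])
        contour = square_contour(cx=30, cy=30, half=20)
        poles = division.detect_poles(img, contour)
        assert abs(division.spindle_axis_angle(*poles)) == pytest.approx(90.0, abs=1.0)


class TestAxisAngle:
    def test_parallel_to_ap_is_zero(self):
        assert division.spindle_axis_angle((10, 10), (10, 30)) == pytest.approx(0.0)

    def test_perpendicular_is_ninety(self):
        assert division.spindle_axis_angle((10, 10), (30, 10)) == pytest.approx(90.0)

    def test_undirected_equivalence_at_150(self):
        # a directed bearing of 150 deg from AP is the -30 deg axis
        dx, drow = _angles.axis_direction(150.0)
        a = (50.0, 50.0)
        b = (50.0 + 20 * dx, 50.0 + 20 * drow)
        assert division.spindle_axis_angle(a, b) == pytest.approx(-30.0)

    def test_coincident_poles_rejected(self):
        with pytest.raises(GeometryError):
            division.spindle_axis_angle((5, 5), (5, 5))

    @given(
        theta=st.floats(-89.9, 90.0),
        x=st.floats(10, 100),
        y=st.floats(10, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_pole_swap_and_reflection_invariance(self, theta, x, y):
        dx, drow = _angles.axis_direction(theta)
        a = (x, y)
        b = (x + 15 * dx, y + 15 * drow)
        ang = division.spindle_axis_angle(a, b)
        swapped = division.spindle_axis_angle(b, a)
        assert division.fold_angle(ang) == pytest.approx(
            division.fold_angle(swapped), abs=1e-6
        )
        # reflecting about the AP axis (x -> -x) preserves the folded angle
        ar = (-a[0], a[1])
        br = (-b[0], b[1])
        reflected = division.spindle_axis_angle(ar, br)
        assert division.fold_angle(reflected) == pytest.approx(
            division.fold_angle(ang), abs=1e-6
        )
        assert reflected == pytest.approx(
            _angles.wrap_axial(-ang), abs=1e-6
        ) or division.fold_angle(ang) == pytest.approx(90.0, abs=1e-6)


class TestFoldAngle:
    @pytest.mark.parametrize("signed,folded", [(0.0, 0.0), (-30.0, 30.0), (90.0, 90.0)])
    def test_examples(self, signed, folded):
        assert division.fold_angle(signed) == folded

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            division.fold_angle(120.0)


def obs_series(angles, cell="c"):
    out = []
    for f, ang in enumerate(angles):
        dx, drow = _angles.axis_direction(ang)
        a = (50.0, 50.0)
        b = (50.0 + 20 * dx, 50.0 + 20 * drow)
        out.append(division.observation(cell, f, a, b))
    return out


class TestTrackRotation:
    def test_constant_series_is_none(self):
        rec = division.track_rotation(obs_series([15.0] * 5), anaphase_frame=4)
        assert rec.rotation_direction == "none"
        assert rec.total_rotation == pytest.approx(0.0, abs=1e-6)

    def test_decreasing_series_is_clockwise(self):
        rec = division.track_rotation(obs_series([80.0, 40.0, 10.0, 10.0]),
                                      anaphase_frame=3)
        assert rec.rotation_direction == "cw"
        assert rec.folded_angle == pytest.approx(10.0, abs=1e-6)
        assert rec.total_rotation == pytest.approx(70.0, abs=1e-6)

    def test_unordered_frames_rejected(self):
        obs = obs_series([10.0, 20.0, 30.0])
        shuffled = [obs[0], obs[2], obs[1]]
        with pytest.raises(InputError):
            division.track_rotation(shuffled, anaphase_frame=2)

    def test_anaphase_beyond_sequence_rejected(self):
        with pytest.raises(InputError):
            division.track_rotation(obs_series([10.0, 20.0]), anaphase_frame=5)

    def test_rotation_across_axial_boundary(self):
        # 80 -> 90 -> -80: a 20-degree ccw rotation through the boundary
        rec = division.track_rotation(obs_series([80.0, 90.0, -80.0]),
                                      anaphase_frame=2)
        assert rec.rotation_direction == "ccw"
        assert rec.total_rotation == pytest.approx(20.0, abs=1e-6)

    def test_timelapse_recovery_direction_and_angle(self, small_config):
        """Noise-free rendered time-lapse: angles within 2 deg, direction
        exact for every cell rotating at least 5 deg."""
        geometry, truth = synthgen.generate_domain(small_config)
        stack = synthgen.render_spindle_timelapse(truth, small_config,
                                                  apply_noise=False)
        by_id = dict(zip(truth.cell_id, truth.index))
        for contour in geometry.mitotic:
            obs = []
            for f in range(stack.shape[0]):
                poles = division.detect_poles(stack[f], contour)
                obs.append(division.observation(contour.cell_id, f, *poles))
            rec = division.track_rotation(obs, small_config.anaphase_frame)
            row = truth.loc[by_id[contour.cell_id]]
            err = abs(_angles.axial_difference(
                rec.final_signed_angle, row.true_final_division_angle_signed))
            assert err <= 2.0
            if row.true_total_rotation >= 5.0:
                assert rec.rotation_direction == row.true_rotation_direction


class TestRoseHistogram:
    def test_folded_percentages(self):
        h = division.rose_histogram([5, 25, 45, 65, 85], bin_width=30.0)
        # 5, 25 -> [0, 30); 45 -> [30, 60); 65, 85 -> [60, 90]
        assert np.allclose(h.percentages, [40.0, 20.0, 40.0])
        assert h.n == 5

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            division.rose_histogram([])

    def test_bad_bin_width_rejected(self):
        with pytest.raises(InputError):
            division.rose_histogram([10.0], bin_width=25.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(RangeError):
            division.rose_histogram([95.0])

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        h = division.rose_histogram(rng.uniform(0, 90, size=137), bin_width=15.0)
        assert h.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_folded_equals_absolute_signed(self):
        rng = np.random.default_rng(1)
        signed = rng.uniform(-89.0, 90.0, size=200)
        h1 = division.rose_histogram(np.abs(signed), bin_width=15.0)
        h2 = division.rose_histogram(np.abs(signed), bin_width=15.0, range_kind="folded")
        assert np.allclose(h1.percentages, h2.percentages)

    def test_mirrored_cohorts_reflect(self):
        """Signed histograms of mirrored synthetic sides are reflections."""
        _, truth = synthgen.generate_domain(
            synthgen.SyntheticDomainConfig(
                n_cells_per_side=200, image_size=1024,
                crescent_angle_sd=0.0, division_coupling_sd=8.0, seed=2,
            )
        )
        left = truth.loc[truth.side == "left", "true_final_division_angle_signed"]
        right = truth.loc[truth.side == "right", "true_final_division_angle_signed"]
        hl = division.rose_histogram(left, bin_width=30.0, range_kind="signed")
        hr = division.rose_histogram(right, bin_width=30.0, range_kind="signed")
        # reflected bins should agree within sampling error (5 pp)
        assert np.allclose(hl.percentages, hr.percentages[::-1], atol=5.0)


class TestEmbryoMeans:
    def _rec(self, cell, embryo, folded):
        return division.DivisionRecord(
            cell_id=cell, embryo_id=embryo, domain_id="MD1", side="left",
            final_signed_angle=folded, folded_angle=folded,
            rotation_direction="none", total_rotation=0.0,
        )

    def test_single_embryo_mean(self):
        out = division.embryo_mean_angles(
            [self._rec("a", "E1", 10.0), self._rec("b", "E1", 30.0)]
        )
        assert out["mean_folded_angle"].iloc[0] == pytest.approx(20.0)

    def test_uniform_angles_mean_near_45(self):
        rng = np.random.default_rng(3)
        recs = [self._rec(f"c{i}", "E1", a)
                for i, a in enumerate(rng.uniform(0, 90, size=3000))]
        out = division.embryo_mean_angles(recs)
        assert out["mean_folded_angle"].iloc[0] == pytest.approx(45.0, abs=2.0)

    def test_one_row_per_embryo_regardless_of_counts(self):
        recs = [self._rec(f"a{i}", "E1", 10.0) for i in range(20)]
        recs += [self._rec("b", "E2", 50.0)]
        out = division.embryo_mean_angles(recs)
        assert len(out) == 2
        assert set(out["embryo_id"]) == {"E1", "E2"}
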