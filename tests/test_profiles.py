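"""Tests for cortical profile extraction, orientation, normalization,
resampling and hierarchical averaging."""

import numpy as np
import pytest

from conftest import square_contour
from mitopolar import profiles, synthgen
from mitopolar.errors import (
    BoundsError,
    ConsistencyError,
    InputError,
    LabelingError,
    NormalizationError,
)
from mitopolar.profiles import CellContour, CorticalProfile


def make_profile(values, side="right", traversal="ccw", normalized=False):
    n = len(values)
    values = np.asarray(values, dtype=float)
    return CorticalProfile(
        cell_id="c",
        embryo_id="e",
        side=side,
        channel="polarity",
        arclength_fraction=np.arange(n) / n,
        angular_position=synthgen._angles.wrap_full(np.arange(n) * 360.0 / n),
        raw_intensity=values,
        normalized_intensity=values.copy() if normalized else None,
        cytoplasm_mean=1.0 if normalized else None,
        traversal=traversal,
    )


class TestSampling:
    def test_uniform_ring_recovered(self, small_config):
        """Membrane render, noise and PSF off: profile is near base everywhere."""
        import dataclasses

        config = dataclasses.replace(small_config, psf_sigma=0.0)
        geometry, _ = synthgen.generate_domain(config)
        img = synthgen.render_membrane_image(geometry, apply_noise=False)
        base = config.membrane_cortex_intensity
        p = profiles.sample_perimeter_intensity(img, geometry.mitotic[0],
                                                smooth_sigma=None)
        assert np.all(np.abs(p.raw_intensity - base) / base < 0.15)

    def test_ring_flat_after_psf(self, small_domain):
        """With the PSF on, the uniform ring stays flat around the perimeter."""
        geometry, _ = small_domain
        img = synthgen.render_membrane_image(geometry, apply_noise=False)
        p = profiles.sample_perimeter_intensity(img, geometry.mitotic[0],
                                                smooth_sigma=None)
        rel = p.raw_intensity / p.raw_intensity.mean()
        assert np.ptp(rel) < 0.25

    def test_wider_line_reduces_noise_variance(self, small_domain, small_config):
        geometry, _ = small_domain
        contour = geometry.mitotic[0]
        var1, var3 = [], []
        clean = synthgen.render_membrane_image(geometry, apply_noise=False)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 20.0, size=clean.shape)
            p1 = profiles.sample_perimeter_intensity(noisy, contour, line_width=1,
                                                     smooth_sigma=None)
            p3 = profiles.sample_perimeter_intensity(noisy, contour, line_width=3,
                                                     smooth_sigma=None)
            var1.append(np.var(p1.raw_intensity))
            var3.append(np.var(p3.raw_intensity))
        assert np.mean(var3) < np.mean(var1)

    def test_contour_outside_raster_rejected(self):
        img = np.zeros((64, 64))
        contour = square_contour(cx=60.0, cy=32.0, half=10.0)
        with pytest.raises(BoundsError):
            profiles.sample_perimeter_intensity(img, contour)

    def test_starts_at_reference_point(self):
        img = np.ones((64, 64))
        contour = square_contour(cx=32, cy=32, half=8)
        p = profiles.sample_perimeter_intensity(img, contour, smooth_sigma=None)
        assert p.arclength_fraction[0] == 0.0
        # first sample sits at the reference vertex
        ref = contour.vertices[contour.reference_point]
        # angular position of start is that of the reference vertex
        c = contour.centroid
        from mitopolar._angles import position_angle

        expect = position_angle(ref[0] - c[0], ref[1] - c[1])
        assert p.angular_position[0] == pytest.approx(expect, abs=1e-6)


class TestOrientation:
    def test_left_cell_forced_clockwise(self):
        p = make_profile([1, 2, 3, 4, 5, 6, 7, 8], side="left", traversal="ccw")
        out = profiles.orient_profile(p)
        assert out.traversal == "cw"
        # start stays first, remainder reversed
        assert out.raw_intensity[0] == 1
        assert list(out.raw_intensity[1:]) == [8, 7, 6, 5, 4, 3, 2]

    def test_right_cell_ccw_unchanged(self):
        p = make_profile([1, 2, 3, 4, 5, 6, 7, 8], side="right", traversal="ccw")
        out = profiles.orient_profile(p)
        assert np.array_equal(out.raw_intensity, p.raw_intensity)
        assert out.traversal == "ccw"

    def test_idempotent(self):
        p = make_profile(np.arange(10.0), side="left", traversal="ccw")
        once = profiles.orient_profile(p)
        twice = profiles.orient_profile(once)
        assert np.array_equal(once.raw_intensity, twice.raw_intensity)
        assert np.array_equal(once.arclength_fraction, twice.arclength_fraction)

    def test_unassigned_side_rejected(self):
        p = make_profile(np.arange(8.0), side="unassigned")
        with pytest.raises(LabelingError):
            profiles.orient_profile(p)


class TestNormalization:
    def test_scalar_mean(self):
        p = make_profile([10.0, 20.0, 30.0])
        out = profiles.normalize_profile(p, 10.0)
        assert np.allclose(out.normalized_intensity, [1.0, 2.0, 3.0])
        assert np.array_equal(out.raw_intensity, p.raw_intensity)

    def test_flat_at_cytoplasm_level(self):
        p = make_profile([7.0, 7.0, 7.0])
        out = profiles.normalize_profile(p, 7.0)
        assert np.allclose(out.normalized_intensity, 1.0)

    def test_zero_mean_rejected(self):
        p = make_profile([1.0, 2.0, 3.0])
        with pytest.raises(NormalizationError):
            profiles.normalize_profile(p, 0.0)

    def test_region_mean_from_image(self):
        img = np.full((64, 64), 5.0)
        p = make_profile([10.0, 20.0, 30.0])
        region = square_contour(cx=32, cy=32, half=5).vertices
        out = profiles.normalize_profile(p, region, image=img)
        assert out.cytoplasm_mean == pytest.approx(5.0)

    def test_renormalizing_with_unit_mean_is_identity(self):
        p = profiles.normalize_profile(make_profile([2.0, 4.0, 8.0]), 2.0)
        again = profiles.normalize_profile(
            make_profile(p.normalized_intensity), 1.0
        )
        assert np.allclose(again.normalized_intensity, p.normalized_intensity)


class TestResampling:
    def test_constant_profile_stays_constant(self):
        p = make_profile(np.full(32, 3.5))
        out = profiles.resample_profile(p, 16)
        assert np.allclose(out.raw_intensity, 3.5)

    def test_identity_on_uniform_grid(self):
        p = make_profile(np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False)))
        out = profiles.resample_profile(p, 64)
        assert np.allclose(out.raw_intensity, p.raw_intensity, atol=1e-12)

    def test_cosine_roundtrip_error_bounded(self):
        f = np.arange(128) / 128
        p = make_profile(np.cos(2 * np.pi * f))
        down = profiles.resample_profile(p, 64)
        back = profiles.resample_profile(down, 128)
        # piecewise-linear interpolation error ~ (h^2 / 8) |f''| ~ 1.2e-3
        assert np.max(np.abs(back.raw_intensity - p.raw_intensity)) < 5e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            profiles.resample_profile(make_profile(np.arange(16.0)), 4)

    def test_angular_positions_recomputed_circularly(self):
        p = make_profile(np.arange(36.0))
        out = profiles.resample_profile(p, 72)
        # positions remain a ccw sweep: consecutive wrapped diffs all positive
        d = np.diff(out.angular_position)
        d = (d + 180) % 360 - 180
        assert np.all(d > 0)


class TestAveraging:
    def test_single_embryo_identical_profiles(self):
        ps = [make_profile([1.0, 2.0, 3.0, 4.0]) for _ in range(3)]
        per, grand, _ = profiles.average_profiles(ps)
        assert np.allclose(grand, [1, 2, 3, 4])

    def test_grand_mean_weights_embryos_equally(self):
        a = [make_profile(np.full(8, 1.0)) for _ in range(9)]
        b = [make_profile(np.full(8, 3.0))]
        for p in a:
            p.embryo_id = "A"
        for p in b:
            p.embryo_id = "B"
        per, grand, _ = profiles.average_profiles(a + b)
        assert np.allclose(per["A"], 1.0)
        assert np.allclose(per["B"], 3.0)
        assert np.allclose(grand, 2.0)  # not the pooled mean 1.2

    def test_mixed_grids_rejected(self):
        with pytest.raises(ConsistencyError):
            profiles.average_profiles(
                [make_profile(np.arange(8.0)), make_profile(np.arange(16.0))]
            )

    def test_mixed_normalization_rejected(self):
        with pytest.raises(ConsistencyError):
            profiles.average_profiles(
                [
                    make_profile(np.arange(8.0)),
                    make_profile(np.arange(8.0), normalized=True),
                ]
            )

    def test_averaging_shrinks_noise_variance(self):
        rng = np.random.default_rng(4)
        ps = []
        for e in range(3):
            for _ in range(10):
                p = make_profile(5.0 + rng.normal(0, 1.0, size=32))
                p.embryo_id = f"E{e}"
                ps.append(p)
        _, grand, _ = profiles.average_profiles(ps)
        assert np.var(grand) < np.var(ps[0].raw_intensity)


class TestContourValidation:
    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(Exception):
            CellContour("x", "e", "left", bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(Exception):
            CellContour("x", "e", "left", np.array([[0, 0], [1, 1]], dtype=float))
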