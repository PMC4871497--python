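"""Length, area, depth and volume estimators."""

import math

import numpy as np
import pytest

from nlcmorph.axis_models import (
    CentroidSequence,
    build_polygonal_axis,
    fit_polynomial_axis,
)
from nlcmorph.morphometry import (
    axial_area_profile,
    axial_length,
    canal_volume,
    compute_all,
    end_to_end_length,
    mean_sectional_area,
    min_area_depth,
    min_sectional_area,
    orthogonal_area_profile,
    polygonal_length,
    polynomial_length,
    resliced_orthogonal_area,
)
from nlcmorph.reference import REFERENCE_AXIS_MODELS, synthetic_centroid_sequence

DELTA = 0.625


def _seq(x, y, z, delta=DELTA):
    return CentroidSequence(points=np.column_stack([x, y, z]), delta=delta)


class TestLengths:
    def test_axial_length_is_p_delta(self, waisted_phantom):
        _, _, _, seg = waisted_phantom
        assert axial_length(seg) == pytest.approx(16 * DELTA)  # 10 mm

    def test_end_to_end_345_triangle(self):
        # axis displaced 3 mm laterally over a 4 mm domain
        z = np.array([0.5, 1.5, 2.5, 3.5])
        x = 3.0 / 4.0 * (z + 0.5)
        axis = build_polygonal_axis(_seq(x, np.zeros(4), z, delta=1.0))
        assert end_to_end_length(axis) == pytest.approx(5.0)

    def test_reference_model_end_to_end_matches_horner_oracle(self):
        row = REFERENCE_AXIS_MODELS[23]
        cents = synthetic_centroid_sequence(23)
        axis = fit_polynomial_axis(cents, 3)

        def horner(coeffs_hi, z):
            acc = 0.0
            for c in coeffs_hi:
                acc = acc * z + c
            return acc

        lo, hi = row["z_min"], row["z_max"]
        p0 = np.array([horner(row["x"], lo), horner(row["y"], lo), lo])
        p1 = np.array([horner(row["x"], hi), horner(row["y"], hi), hi])
        oracle = np.linalg.norm(p1 - p0)
        assert end_to_end_length(axis) == pytest.approx(oracle, abs=2e-3)

    def test_polygonal_zigzag(self):
        # two 3-4-5 segments (dz=4, dx=+-3) plus two vertical-ish extensions
        z = np.array([0.0, 4.0, 8.0])
        x = np.array([0.0, 3.0, 0.0])
        cents = _seq(x, np.zeros(3), z, delta=4.0)
        axis = build_polygonal_axis(cents)
        ext = 2 * 2.5  # each extension: dz=2 along slope 3/4 -> length 2.5
        assert polygonal_length(axis) == pytest.approx(10.0 + ext)

    def test_polygonal_at_least_end_to_end(self, curved_phantom):
        _, _, _, seg = curved_phantom
        axis = build_polygonal_axis(CentroidSequence.from_segmentation(seg))
        assert polygonal_length(axis) >= end_to_end_length(axis)

    def test_straight_arc_length(self):
        z = DELTA * np.arange(16)
        axis = fit_polynomial_axis(_seq(np.full(16, 2.0), np.full(16, 3.0), z), 3)
        assert polynomial_length(axis) == pytest.approx(16 * DELTA, abs=1e-6)

    def test_diagonal_arc_length_closed_form(self):
        z = np.linspace(0.5, 9.5, 10)
        axis = fit_polynomial_axis(_seq(z.copy(), np.zeros(10), z, delta=1.0), 2)
        assert polynomial_length(axis) == pytest.approx(10 * math.sqrt(2), abs=1e-6)

    def test_reference_arc_length_against_riemann_oracle(self):
        cents = synthetic_centroid_sequence(23)
        axis = fit_polynomial_axis(cents, 3)
        lo, hi = axis.domain
        # brute-force midpoint Riemann sum, 10^6 steps, independent of quad
        n = 1_000_000
        zm = lo + (np.arange(n) + 0.5) * (hi - lo) / n
        da = np.polynomial.polynomial.polyder(axis.a_coeffs)
        db = np.polynomial.polynomial.polyder(axis.b_coeffs)
        dx = np.polynomial.polynomial.polyval(zm, da)
        dy = np.polynomial.polynomial.polyval(zm, db)
        oracle = np.sqrt(1 + dx * dx + dy * dy).sum() * (hi - lo) / n
        assert polynomial_length(axis) == pytest.approx(oracle, abs=1e-3)


class TestAreas:
    def test_axial_profile_pixel_count(self, straight_phantom):
        _, _, truth, seg = straight_phantom
        profile = axial_area_profile(seg)
        assert len(profile) == seg.n_slices
        for (z, area), region in zip(profile, seg.regions):
            assert area == region.pixel_count * seg.geometry.pixel_area
            assert z == pytest.approx(region.slice_index * DELTA)

    def test_constant_lumen_constant_profile(self, straight_phantom):
        _, _, truth, seg = straight_phantom
        areas = np.array([a for _, a in axial_area_profile(seg)])
        true = math.pi * 4.0
        assert np.all(np.abs(areas - true) / true < 0.05)

    def test_projection_vertical_axis_identity(self, straight_phantom):
        _, _, _, seg = straight_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 2)
        for (z, a), (z2, a_perp, cosb) in zip(
            axial_area_profile(seg), orthogonal_area_profile(seg, axis)
        ):
            assert cosb == pytest.approx(1.0, abs=1e-9)
            assert a_perp == pytest.approx(a, rel=1e-9)

    def test_projection_60_degree_halving(self, tilted60_phantom):
        _, _, _, seg = tilted60_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 2)
        for z, a_perp, cosb in orthogonal_area_profile(seg, axis):
            assert cosb == pytest.approx(0.5, abs=0.01)
        ax_areas = dict(axial_area_profile(seg))
        for z, a_perp, cosb in orthogonal_area_profile(seg, axis):
            assert a_perp == pytest.approx(ax_areas[z] * cosb, rel=1e-12)

    def test_projection_recovers_true_section_on_tilted_cylinder(self, tilted60_phantom):
        _, _, truth, seg = tilted60_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 2)
        true = math.pi * 4.0
        for z, a_perp, _ in orthogonal_area_profile(seg, axis):
            assert abs(a_perp - true) / true <= 0.03

    def test_projection_inequality_everywhere(self, curved_phantom, waisted_phantom):
        for _, _, _, seg in (curved_phantom, waisted_phantom):
            cents = CentroidSequence.from_segmentation(seg)
            for axis in (
                build_polygonal_axis(cents),
                fit_polynomial_axis(cents, 2),
                fit_polynomial_axis(cents, 3),
                fit_polynomial_axis(cents, 4),
            ):
                ax_areas = dict(axial_area_profile(seg))
                for z, a_perp, cosb in orthogonal_area_profile(seg, axis):
                    assert 0 < cosb <= 1.0
                    assert a_perp <= ax_areas[z] + 1e-12

    def test_doubling_back_axis_rejected(self, straight_phantom):
        _, _, _, seg = straight_phantom

        class _BackwardAxis:
            """Stub whose tangent points against the scan direction."""

            domain = (0.0, 100.0)

            def tangent(self, z):
                return np.array([0.0, 0.8, -0.6])

        with pytest.raises(ValueError, match="doubles back"):
            orthogonal_area_profile(seg, _BackwardAxis())


class TestReslice:
    def test_vertical_cylinder_matches_axial(self, straight_phantom):
        _, volume, _, seg = straight_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 2)
        mid = seg.regions[len(seg.regions) // 2]
        area = resliced_orthogonal_area(volume, axis, float(mid.centroid[2]))
        assert area == pytest.approx(mid.axial_area, rel=0.02)

    def test_60_degree_true_section_within_5pct(self, tilted60_phantom):
        _, volume, _, seg = tilted60_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 2)
        true = math.pi * 4.0  # 12.566 mm^2
        zs = [r.centroid[2] for r in seg.regions[2:-2]]
        for z in zs:
            area = resliced_orthogonal_area(volume, axis, float(z))
            assert area is not None
            assert abs(area - true) / true <= 0.05

    def test_agrees_with_projection_on_smooth_phantom(self, curved_phantom):
        _, volume, _, seg = curved_phantom
        axis = fit_polynomial_axis(CentroidSequence.from_segmentation(seg), 3)
        for z, a_proj, _ in orthogonal_area_profile(seg, axis)[2:-2]:
            a_res = resliced_orthogonal_area(volume, axis, z)
            assert a_res is not None
            assert abs(a_res - a_proj) / a_proj <= 0.05

    def test_plane_exiting_volume_rejected(self, straight_phantom):
        _, volume, _, _ = straight_phantom

        class _OutsideAxis:
            """Vertical axis whose domain extends below the grid."""

            domain = (-5.0, 5.0)

            def __call__(self, z):
                return np.array([8.0, 8.0, z])

            def tangent(self, z):
                return np.array([0.3, 0.0, 0.9539392])  # oblique, no lattice snap

        with pytest.raises(ValueError, match="exits"):
            resliced_orthogonal_area(volume, _OutsideAxis(), -2.0)


class TestProfileStatistics:
    def test_mean(self):
        assert mean_sectional_area([(0, 10.0), (1, 20.0), (2, 30.0)]) == 20.0

    def test_min_monotone_decreasing(self):
        area, z = min_sectional_area([(0, 30.0), (1, 20.0), (2, 10.0)])
        assert (area, z) == (10.0, 2)

    def test_min_tie_breaks_cranial(self):
        area, z = min_sectional_area([(0, 5.0), (1, 3.0), (2, 3.0)])
        assert (area, z) == (3.0, 1)

    def test_taper_mean_matches_integral_oracle(self):
        from nlcmorph.phantom import (
            PhantomSpec,
            generate_phantom,
            radius_taper,
        )
        from nlcmorph.ct_io import check_tag_consistency
        from nlcmorph.segmentation import segment_canal

        first, last = 2, 13
        z0 = first * DELTA - DELTA / 2
        z1 = last * DELTA + DELTA / 2
        spec = PhantomSpec(
            x_coeffs=[8.0],
            y_coeffs=[8.0],
            radius_profile=radius_taper(2.4, 1.4, z0, z1),
            first_slice=first,
            last_slice=last,
            n_slices=16,
            shape_rc=(60, 60),
            pixel_spacing=0.3,
        )
        volume, _ = generate_phantom(spec)
        check_tag_consistency(volume)
        seg = segment_canal(volume, "right", seed=(8.0, 8.0))
        measured = mean_sectional_area(axial_area_profile(seg))
        # closed form: mean over slice centres of pi r(z)^2
        zs = DELTA * np.arange(first, last + 1)
        oracle = float(np.mean(math.pi * spec.radius_profile(zs) ** 2))
        assert measured == pytest.approx(oracle, rel=0.05)


class TestDepthAndVolume:
    def test_depth_zero_at_cranial_plane(self, waisted_phantom):
        _, _, _, seg = waisted_phantom
        z_lo = seg.first_slice * DELTA - DELTA / 2
        assert min_area_depth(z_lo, seg, "low-z") == 0.0

    def test_depth_full_axl_at_caudal_end(self, waisted_phantom):
        _, _, _, seg = waisted_phantom
        z_hi = seg.last_slice * DELTA + DELTA / 2
        assert min_area_depth(z_hi, seg, "low-z") == pytest.approx(axial_length(seg))

    def test_waist_depth_recovered_within_delta(self, waisted_phantom):
        _, _, _, seg = waisted_phantom
        area, z_min = min_sectional_area(axial_area_profile(seg))
        depth = min_area_depth(z_min, seg, "low-z")
        assert abs(depth - 4.0) <= DELTA

    def test_volume_identity_with_area_sum(self, curved_phantom):
        _, _, _, seg = curved_phantom
        vol = canal_volume(seg)
        total = sum(a for _, a in axial_area_profile(seg)) * DELTA
        assert vol == pytest.approx(total, rel=1e-12)

    def test_cylinder_volume_within_3pct(self, straight_phantom):
        _, _, truth, seg = straight_phantom
        assert abs(canal_volume(seg) - truth.volume) / truth.volume <= 0.03

    def test_volume_error_bounded_and_shrinking_with_finer_pixels(self):
        # discretisation consistency: the relative volume error stays
        # inside a bound that halves with the pixel spacing (pointwise
        # monotonicity can fail when a coarse error luckily cancels)
        from nlcmorph.phantom import PhantomSpec, generate_phantom, radius_constant
        from nlcmorph.ct_io import check_tag_consistency
        from nlcmorph.segmentation import segment_canal

        for ps, npx, bound in ((0.45, 38, 0.03), (0.225, 76, 0.015)):
            spec = PhantomSpec(
                x_coeffs=[8.0, 0.1],
                y_coeffs=[8.0],
                radius_profile=radius_constant(2.0),
                first_slice=2,
                last_slice=9,
                n_slices=12,
                shape_rc=(npx, npx),
                pixel_spacing=ps,
            )
            volume, truth = generate_phantom(spec)
            check_tag_consistency(volume)
            seg = segment_canal(volume, "right", seed=(8.2, 8.0))
            rel = abs(canal_volume(seg) - truth.volume) / truth.volume
            assert rel <= bound


class TestComputeAll:
    def test_degenerate_straight_phantom_equalities(self, straight_phantom):
        _, volume, _, seg = straight_phantom
        res = compute_all(volume, seg)
        lengths = [res.AxL, res.ExL, res.PolygL, res.Polyn2L, res.Polyn3L, res.Polyn4L]
        assert (max(lengths) - min(lengths)) / min(lengths) <= 1e-6
        areas = [res.SecA, res.SecPolygA, res.SecPolyn2A, res.SecPolyn3A, res.SecPolyn4A]
        assert (max(areas) - min(areas)) / min(areas) <= 1e-6

    def test_curved_phantom_recovery(self, curved_phantom):
        from nlcmorph.phantom import ground_truth_morphometry

        spec, volume, _, seg = curved_phantom
        res = compute_all(volume, seg)
        gt = ground_truth_morphometry(spec)
        assert abs(res.Polyn3L - gt.Polyn3L) / gt.Polyn3L <= 0.01
        assert abs(res.Vol - gt.Vol) / gt.Vol <= 0.03

    def test_length_ordering(self, curved_phantom, waisted_phantom, tilted60_phantom):
        for _, volume, _, seg in (curved_phantom, waisted_phantom, tilted60_phantom):
            res = compute_all(volume, seg)
            assert res.AxL <= res.ExL + 1e-9 <= res.PolygL + 1e-9

    def test_small_p_marks_infeasible_models_absent(self):
        from nlcmorph.phantom import PhantomSpec, generate_phantom, radius_constant
        from nlcmorph.ct_io import check_tag_consistency
        from nlcmorph.segmentation import segment_canal

        spec = PhantomSpec(
            x_coeffs=[8.0],
            y_coeffs=[8.0],
            radius_profile=radius_constant(2.0),
            first_slice=2,
            last_slice=5,  # p = 4: degree-4 underdetermined
            n_slices=8,
            shape_rc=(54, 54),
            pixel_spacing=0.3,
        )
        volume, _ = generate_phantom(spec)
        check_tag_consistency(volume)
        seg = segment_canal(volume, "right", seed=(8.0, 8.0))
        res = compute_all(volume, seg)
        assert res.Polyn4L is None and res.SecPolyn4A is None
        assert res.Polyn3L is not None and res.Polyn2L is not None
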