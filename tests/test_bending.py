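"""Three-point-bending analysis: beam formulas, yield detection, round trips."""

import math

import numpy as np
import pytest

from osteomech.bending import (
    BendingResult,
    BodySize,
    LoadDisplacementCurve,
    TubeGeometry,
    analyze_curve,
    cross_sectional_area,
    detect_popins,
    elastic_modulus,
    find_yield,
    inner_radius_from_ratio,
    key_points,
    linear_slope,
    moment_of_inertia,
    normalize_by_body_size,
    stress_at,
)
from osteomech.synthetic import expected_offset_yield, generate_bending_curve

from conftest import make_truth


class TestTubeFormulas:
    @pytest.mark.parametrize(
        "co, ci, expected_2dp",
        [
            (0.685, 0.45, 0.14),  # OVX-group mean diameters
            (0.73, 0.43, 0.20),  # control-group mean diameters
            (1.0, 0.0, 0.79),  # solid rod, pi/4
        ],
    )
    def test_moment_of_inertia_reference_tubes(self, co, ci, expected_2dp):
        assert round(moment_of_inertia(TubeGeometry(co, ci)), 2) == expected_2dp

    def test_moment_of_inertia_solid_rod_closed_form(self):
        assert moment_of_inertia(TubeGeometry(1.0, 0.0)) == pytest.approx(math.pi / 4)

    @pytest.mark.parametrize(
        "do, di, expected_2dp",
        [(1.37, 0.90, 0.84), (1.46, 0.86, 1.09)],
    )
    def test_annulus_area_reference_tubes(self, do, di, expected_2dp):
        area = cross_sectional_area(TubeGeometry(do / 2, di / 2))
        assert round(area, 2) == expected_2dp

    def test_area_vanishes_for_degenerate_annulus(self):
        thin = TubeGeometry(0.7, 0.7 - 1e-9)
        assert cross_sectional_area(thin) == pytest.approx(0.0, abs=1e-8)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TubeGeometry(outer_radius=0.5, inner_radius=0.5)
        with pytest.raises(ValueError):
            TubeGeometry(outer_radius=0.5, inner_radius=0.6)

    def test_raster_oracle_annulus_area(self):
        # pixel-count integration of the 1.46/0.86 mm annulus at 5 um
        co, ci, h = 0.73, 0.43, 0.005
        coords = np.arange(-0.8, 0.8, h) + h / 2
        xx, yy = np.meshgrid(coords, coords)
        r2 = xx**2 + yy**2
        raster = np.count_nonzero((r2 >= ci**2) & (r2 < co**2)) * h**2
        analytic = cross_sectional_area(TubeGeometry(co, ci))
        assert raster == pytest.approx(analytic, rel=0.01)

    def test_voxel_oracle_second_moment(self, ovx_geometry, control_geometry):
        # centroidal second moment by summation over 10 um pixels
        for geom in (ovx_geometry, control_geometry):
            co, ci, h = geom.outer_radius, geom.inner_radius, 0.010
            coords = np.arange(-co - 0.05, co + 0.05, h) + h / 2
            xx, yy = np.meshgrid(coords, coords)
            ring = (xx**2 + yy**2 >= ci**2) & (xx**2 + yy**2 < co**2)
            cy = yy[ring].mean()
            i_voxel = float(np.sum((yy[ring] - cy) ** 2)) * h**2
            assert i_voxel == pytest.approx(moment_of_inertia(geom), rel=0.02)


class TestStress:
    def test_zero_load_zero_stress(self, ovx_geometry):
        assert stress_at(0.0, ovx_geometry) == 0.0

    def test_hand_oracle(self):
        # independent arithmetic: F L co / (4I), F=10 N, co=0.7, ci=0.4, L=6
        geom = TubeGeometry(0.7, 0.4, span=6.0)
        i_hand = math.pi / 4 * (0.7**4 - 0.4**4)
        expected = 10.0 * 6.0 * 0.7 / (4.0 * i_hand)
        assert stress_at(10.0, geom) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(62.33, abs=0.005)

    def test_linear_in_load(self, ovx_geometry):
        assert stress_at(8.0, ovx_geometry) == pytest.approx(
            2 * stress_at(4.0, ovx_geometry)
        )

    def test_negative_load_rejected(self, ovx_geometry):
        with pytest.raises(ValueError):
            stress_at(-1.0, ovx_geometry)


class TestLinearSlope:
    def test_exact_line(self):
        d = np.linspace(0.0, 1.0, 50)
        slope, r2 = linear_slope(LoadDisplacementCurve(d, 50.0 * d))
        assert slope == pytest.approx(50.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_bilinear_round_trip(self, ovx_geometry):
        truth = make_truth(ovx_geometry)
        curve = generate_bending_curve(truth, sampling_step=0.002)
        slope, r2 = linear_slope(curve)
        assert slope == pytest.approx(truth.elastic_slope, rel=1e-3)
        assert r2 > 0.99

    def test_noisy_slope_within_three_se(self, ovx_geometry):
        """The fitted slope is unbiased: planted value within 3 SE in >=95% of seeds."""
        truth = make_truth(ovx_geometry)
        estimates = []
        for seed in range(200):
            curve = generate_bending_curve(
                truth, sampling_step=0.002, noise_sd=0.2, seed=seed
            )
            estimates.append(linear_slope(curve)[0])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1)
        hits = np.abs(estimates - truth.elastic_slope) <= 3 * se
        assert hits.mean() >= 0.95

    def test_window_validation(self):
        d = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            linear_slope(LoadDisplacementCurve(d, 50 * d), fit_window=1.5)


class TestElasticModulus:
    def test_recovers_planted_modulus(self, ovx_geometry):
        truth = make_truth(ovx_geometry, e_true=4.63)
        curve = generate_bending_curve(truth, sampling_step=0.002)
        slope, _ = linear_slope(curve)
        assert elastic_modulus(slope, ovx_geometry) == pytest.approx(4.63, rel=0.01)

    def test_inverse_proportionality_in_moment(self):
        g1 = TubeGeometry(0.685, 0.45)
        # halving I at fixed slope doubles E
        e1 = elastic_modulus(60.0, g1)
        i1 = moment_of_inertia(g1)
        e_mpa = 60.0 * g1.span**3 / (48.0 * (i1 / 2)) / 1000.0
        assert e_mpa == pytest.approx(2 * e1)

    def test_hand_oracle(self):
        # S L^3 / (48 I): 60 N/mm, L=6 mm, I=0.2 mm^4 -> 1.35 GPa
        g = TubeGeometry(1.0, 0.0, span=6.0)
        e = 60.0 * 6.0**3 / (48.0 * moment_of_inertia(g)) / 1000.0
        assert elastic_modulus(60.0, g) == pytest.approx(e)
        e_ref = 60.0 * 216.0 / (48.0 * 0.2) / 1000.0
        assert e_ref == pytest.approx(1.35)


class TestFindYield:
    def test_purely_linear_curve_has_no_yield(self):
        d = np.linspace(0, 1, 100)
        curve = LoadDisplacementCurve(d, 60.0 * d)
        assert find_yield(curve, slope=60.0) is None

    def test_flat_hardening_geometric_construction(self):
        # kink at (0.20 mm, 12 N), hardening slope 0: the offset line
        # S (d - 0.015) reaches 12 N at d = 12/S + 0.015 = 0.215 mm
        s = 60.0
        d = np.arange(0.0, 0.6, 0.005)
        load = np.minimum(s * d, 12.0)
        curve = LoadDisplacementCurve(d, load)
        yp = find_yield(curve, slope=s)
        assert yp is not None
        assert yp[0] == pytest.approx(0.215, abs=0.005)
        assert yp[1] == pytest.approx(12.0, abs=0.3)

    def test_zero_offset_limit_returns_kink(self):
        s = 60.0
        d = np.arange(0.0, 0.6, 0.005)
        load = np.minimum(s * d, 12.0)
        curve = LoadDisplacementCurve(d, load)
        yp = find_yield(curve, slope=s, offset=1e-9)
        assert yp[0] == pytest.approx(0.2, abs=0.005)

    def test_matches_analytic_offset_intersection(self, ovx_geometry):
        truth = make_truth(ovx_geometry)
        step = 0.002
        curve = generate_bending_curve(truth, sampling_step=step)
        slope, _ = linear_slope(curve)
        yp = find_yield(curve, slope=slope)
        expected = expected_offset_yield(truth)
        assert yp[0] == pytest.approx(expected[0], abs=step)


class TestKeyPoints:
    def test_pyd_round_trip(self, ovx_geometry):
        truth = make_truth(ovx_geometry, pyd=0.47)
        step = 0.002
        curve = generate_bending_curve(truth, sampling_step=step)
        slope, _ = linear_slope(curve)
        yp = find_yield(curve, slope=slope)
        _, fracture, flagged = key_points(curve)
        assert not flagged
        expected_yield = expected_offset_yield(truth)
        pyd = fracture[0] - yp[0]
        expected_pyd = truth.fracture_displacement - expected_yield[0]
        assert pyd == pytest.approx(expected_pyd, abs=2 * step)

    def test_monotone_curve_flagged(self):
        d = np.linspace(0, 1, 100)
        curve = LoadDisplacementCurve(d, 60 * d)
        ultimate, fracture, flagged = key_points(curve)
        assert flagged
        assert ultimate == fracture  # sigma_u == sigma_f for a censored test

    def test_small_popins_do_not_shift_ultimate(self, ovx_geometry):
        clean = make_truth(ovx_geometry)
        popped = make_truth(
            ovx_geometry, popins=((clean.yield_displacement + 0.1, 0.08),)
        )
        c1 = generate_bending_curve(clean, sampling_step=0.002)
        c2 = generate_bending_curve(popped, sampling_step=0.002)
        u1, *_ = key_points(c1)
        u2, *_ = key_points(c2)
        assert abs(u1[0] - u2[0]) < 0.01


class TestPopins:
    def test_monotone_curve_has_none(self):
        d = np.linspace(0, 1, 200)
        assert detect_popins(LoadDisplacementCurve(d, 60 * d)) == []

    def test_two_planted_drops_recovered(self, ovx_geometry):
        truth = make_truth(ovx_geometry)
        d_y = truth.yield_displacement
        planted = ((d_y + 0.10, 0.10), (d_y + 0.25, 0.10))
        truth = make_truth(ovx_geometry, popins=planted)
        step = 0.002
        curve = generate_bending_curve(truth, sampling_step=step)
        events = detect_popins(curve)
        assert len(events) == 2
        for ev, (dp, frac) in zip(events, planted):
            assert ev.displacement == pytest.approx(dp, abs=step)
            assert ev.fraction == pytest.approx(frac, rel=0.05)

    def test_threshold_monotonicity(self, ovx_geometry):
        truth = make_truth(
            ovx_geometry,
            popins=((make_truth(ovx_geometry).yield_displacement + 0.1, 0.10),),
        )
        curve = generate_bending_curve(truth, sampling_step=0.002)
        assert len(detect_popins(curve, drop_fraction=0.05)) == 1
        assert detect_popins(curve, drop_fraction=0.5) == []


def _result(**overrides) -> BendingResult:
    base = dict(
        yield_stress=100.0, ultimate_stress=140.0, fracture_stress=120.0,
        elastic_modulus=4.0, pyd=0.4, area=0.9, moment_of_inertia=0.15,
        yield_point=(0.2, 10.0), ultimate_point=(0.5, 14.0),
        fracture_point=(0.6, 12.0), stiffness=60.0, fit_r_squared=1.0,
    )
    base.update(overrides)
    return BendingResult(**base)


class TestNormalization:
    def test_unit_factor_is_identity(self):
        res = normalize_by_body_size(_result(), BodySize(20.0, 20.0))
        assert res.yield_stress == 100.0
        assert res.normalized

    def test_linearity(self):
        res = normalize_by_body_size(_result(), BodySize(40.0, 20.0))
        assert res.ultimate_stress == pytest.approx(70.0)
        assert res.elastic_modulus == pytest.approx(2.0)

    def test_weight_ratio_algebra(self):
        # same raw strength, weights 45.09 vs 28.05 g at equal length:
        # normalized values scale as the inverse weight ratio
        heavy = normalize_by_body_size(_result(), BodySize(45.09, 20.0))
        light = normalize_by_body_size(_result(), BodySize(28.05, 20.0))
        assert heavy.ultimate_stress / light.ultimate_stress == pytest.approx(
            28.05 / 45.09
        )

    def test_double_normalization_rejected(self):
        res = normalize_by_body_size(_result(), BodySize(20.0, 10.0))
        with pytest.raises(ValueError):
            normalize_by_body_size(res, BodySize(20.0, 10.0))

    def test_invertible_to_machine_precision(self):
        raw = _result()
        res = normalize_by_body_size(raw, BodySize(37.3, 19.1))
        k = res.normalization_factor
        for attr in ("yield_stress", "ultimate_stress", "fracture_stress", "elastic_modulus"):
            assert getattr(res, attr) * k == pytest.approx(
                getattr(raw, attr), rel=1e-12
            )


class TestInnerRadiusFromRatio:
    def test_constant_ratio(self):
        pairs = [(0.5, 1.0), (1.0, 2.0), (0.25, 0.5)]
        assert inner_radius_from_ratio(0.7, pairs) == pytest.approx(0.35)

    def test_single_section_forced_arithmetic(self):
        # (di, do) = (0.90, 1.37) applied to outer radius 0.685 mm
        assert inner_radius_from_ratio(0.685, [(0.90, 1.37)]) == pytest.approx(
            0.45, abs=5e-4
        )

    def test_mean_of_ratios_not_ratio_of_means(self):
        # pairs (1,2) and (1,4): mean of ratios 0.375, ratio of means 1/3
        pairs = [(1.0, 2.0), (1.0, 4.0)]
        assert inner_radius_from_ratio(1.0, pairs) == pytest.approx(0.375)
        assert inner_radius_from_ratio(1.0, pairs) != pytest.approx(2.0 / 6.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            inner_radius_from_ratio(0.7, [])


class TestAnalyzeCurve:
    def test_stress_ordering_invariant(self, ovx_geometry):
        for seed in range(5):
            truth = make_truth(
                ovx_geometry,
                popins=((make_truth(ovx_geometry).yield_displacement + 0.1, 0.06),),
            )
            curve = generate_bending_curve(
                truth, sampling_step=0.002, noise_sd=0.05, seed=seed
            )
            res = analyze_curve(curve, ovx_geometry)
            assert res.ultimate_stress >= res.yield_stress - 1e-9
            assert res.ultimate_stress >= res.fracture_stress - 1e-9
            assert res.yield_stress >= 0

    def test_full_round_trip_grid(self):
        """Noise-free recovery of E, offset yield and PYD over a parameter grid."""
        step = 0.002
        for co, ci in [(0.685, 0.45), (0.73, 0.43), (0.695, 0.36)]:
            geom = TubeGeometry(co, ci, span=6.0)
            for e_true in (2.85, 4.63):
                for pyd in (0.28, 0.47):
                    truth = make_truth(geom, e_true=e_true, pyd=pyd)
                    curve = generate_bending_curve(truth, sampling_step=step)
                    res = analyze_curve(curve, geom)
                    assert res.elastic_modulus == pytest.approx(e_true, rel=0.01)
                    expected = expected_offset_yield(truth)
                    assert res.yield_point[0] == pytest.approx(expected[0], abs=step)
                    expected_pyd = truth.fracture_displacement - expected[0]
                    assert res.pyd == pytest.approx(expected_pyd, abs=2 * step)
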