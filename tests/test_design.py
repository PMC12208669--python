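"""Design calculus: closed-form relations and the tile planner."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfspim import design
from lfspim.design import (
    ExpansionSpec,
    LensSpec,
    SensorSpec,
    depth_of_field,
    effective_resolution,
    etendue,
    light_collection_ratio,
    megavoxel_rate,
    native_volume,
    nyquist_resolution,
    object_sampling,
    plan_tiles,
    round_half_up,
    sensor_geometry,
    voxel_rate,
)


class TestEtendue:
    @pytest.mark.parametrize(
        "fov, na, expected",
        [(6.0, 0.47, 6.25), (14.0, 0.35, 18.86), (5.0, 0.6, 7.07)],
    )
    def test_published_lens_etendues(self, fov, na, expected):
        assert round_half_up(etendue(fov, na), 2) == expected

    def test_zero_field_gives_zero(self):
        assert etendue(0.0, 0.47) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            etendue(-1.0, 0.3)

    @given(
        fov=st.floats(0.1, 50),
        na=st.floats(0.01, 1.3),
        a=st.floats(0.1, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_quadratic_homogeneity(self, fov, na, a):
        assert etendue(a * fov, na) == pytest.approx(a**2 * etendue(fov, na), rel=1e-12)


class TestSamplingChain:
    def test_object_sampling_examples(self):
        assert object_sampling(3.76, 5.0) == pytest.approx(0.752)
        assert round_half_up(object_sampling(3.76, 5.0), 2) == 0.75
        assert object_sampling(3.76, 1.0) == 3.76
        assert object_sampling(1.0, 2.0) == 0.5

    def test_nyquist_doubles_sampling(self):
        assert nyquist_resolution(0.752) == pytest.approx(1.504)
        assert round_half_up(nyquist_resolution(0.752), 1) == 1.5
        assert nyquist_resolution(0.5) == 1.0
        assert nyquist_resolution(3.76) == 7.52

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            object_sampling(3.76, 0.0)
        with pytest.raises(ValueError):
            nyquist_resolution(0.0)


class TestSensorGeometry:
    def test_large_format_sensor(self):
        lens = LensSpec(fov_mm=16.8, na=0.305, magnification=5.0)
        sensor = SensorSpec(14192, 10640, 3.76)
        g = sensor_geometry(sensor, lens)
        assert round_half_up(g.diag_mm, 1) == 13.3
        assert int(round_half_up(g.megapixels, 0)) == 151
        assert g.fov_w_mm == pytest.approx(10.67, abs=0.01)
        assert g.fov_h_mm == pytest.approx(8.00, abs=0.01)

    def test_single_pixel_sensor(self):
        lens = LensSpec(fov_mm=1.0, na=0.1, magnification=1.0)
        g = sensor_geometry(SensorSpec(1, 1, 1000.0), lens)
        assert g.fov_w_mm == g.fov_h_mm == 1.0
        assert g.diag_mm == pytest.approx(math.sqrt(2))

    def test_pythagorean_triple(self):
        lens = LensSpec(fov_mm=1.0, na=0.1, magnification=1.0)
        g = sensor_geometry(SensorSpec(3, 4, 1000.0), lens)
        assert g.diag_mm == pytest.approx(5.0)


class TestVoxelRate:
    @pytest.mark.parametrize(
        "row, lt, expected_mvox",
        [(14192, 15.00, 946), (14192, 45.44, 312)],
    )
    def test_published_rates(self, row, lt, expected_mvox):
        assert megavoxel_rate(row, lt) == expected_mvox

    def test_one_voxel_per_second(self):
        assert voxel_rate(1, 1e6) == pytest.approx(1.0)

    def test_rate_decreases_with_line_time(self):
        rates = [voxel_rate(14192, lt) for lt in (15.0, 20.15, 45.44)]
        assert rates == sorted(rates, reverse=True)


class TestExpansionArithmetic:
    def test_effective_resolution(self):
        assert effective_resolution(1.5, ExpansionSpec(3.0)) == 0.5
        assert effective_resolution(3.0, 3.0) == 1.0
        assert effective_resolution(2.2, 1.0) == 2.2

    def test_round_trip_exact(self):
        for r, k in [(1.5, 3.0), (0.9, 4.0), (2.0, 1.5)]:
            assert effective_resolution(r, k) * k == pytest.approx(r, rel=1e-15)

    def test_native_volume(self):
        nv = native_volume((200.0, 52.0, 35.0), 3.0)
        assert tuple(round_half_up(v, 0) for v in nv) == (67.0, 17.0, 12.0)
        assert native_volume((30.0, 30.0, 30.0), 3.0) == (10.0, 10.0, 10.0)
        assert native_volume((5.0, 6.0, 7.0), 1.0) == (5.0, 6.0, 7.0)

    def test_expansion_below_one_rejected(self):
        with pytest.raises(ValueError):
            effective_resolution(1.5, 0.5)


class TestLightCollection:
    def test_aperture_ratios(self):
        assert light_collection_ratio(1.0, 0.305) == pytest.approx(10.75, abs=0.005)
        assert light_collection_ratio(1.0, 0.305) >= 10.0
        assert round_half_up(light_collection_ratio(0.5, 0.305), 1) == 2.7
        assert light_collection_ratio(0.4, 0.4) == 1.0

    def test_zero_na_rejected(self):
        with pytest.raises(ValueError):
            light_collection_ratio(0.0, 0.3)


class TestDepthOfField:
    def test_convention_values(self):
        assert depth_of_field(0.305, 0.520, 1.33) == pytest.approx(7.43, abs=0.005)
        assert depth_of_field(0.1, 0.520, 1.33) == pytest.approx(69.2, abs=0.05)

    def test_quadratic_na_scaling(self):
        assert depth_of_field(0.1, 0.5) == pytest.approx(4 * depth_of_field(0.2, 0.5))


def _coverage_oracle(origins, fov, extent, overlap):
    """Exhaustive 1-D interval-union check: full coverage + pairwise overlap."""
    iv = sorted((o, o + fov) for o in origins)
    assert iv[0][0] <= 0.0 + 1e-9
    assert iv[-1][1] >= extent - 1e-9
    for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
        assert b0 <= a1 + 1e-9, "gap between adjacent tiles"
        assert a1 - b0 >= overlap * fov - 1e-9, "insufficient overlap"


class TestPlanTiles:
    def test_ceiling_arithmetic(self):
        plan = plan_tiles((30.0, 24.0), (10.6, 8.0), 0.0)
        assert (plan.nx, plan.ny, plan.n_tiles) == (3, 3, 9)

    def test_fits_in_one_tile(self):
        plan = plan_tiles((10.0, 7.0), (10.6, 8.0), 0.15)
        assert plan.n_tiles == 1

    def test_coverage_and_overlap(self):
        plan = plan_tiles((50.0, 24.0), (10.6, 8.0), 0.15)
        xs = sorted({o[0] for o in plan.origins})
        ys = sorted({o[1] for o in plan.origins})
        _coverage_oracle(xs, 10.6, 50.0, 0.15)
        _coverage_oracle(ys, 8.0, 24.0, 0.15)

    def test_random_triples_against_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            extent = rng.uniform(1.0, 100.0)
            fov = rng.uniform(0.5, 20.0)
            overlap = rng.uniform(0.0, 0.9)
            plan = plan_tiles((extent, extent), (fov, fov), overlap)
            xs = sorted({o[0] for o in plan.origins})
            _coverage_oracle(xs, fov, extent, overlap if plan.nx > 1 else 0.0)

    def test_overlap_one_rejected(self):
        with pytest.raises(ValueError):
            plan_tiles((10.0, 10.0), (1.0, 1.0), 1.0)


class TestSpecs:
    def test_lens_invariants(self):
        with pytest.raises(ValueError):
            LensSpec(fov_mm=-1.0, na=0.3)
        with pytest.raises(ValueError):
            LensSpec(fov_mm=1.0, na=1.5, medium_ri=1.33)
        with pytest.raises(ValueError):
            LensSpec(fov_mm=1.0, na=0.3, magnification=0.0)

    def test_sensor_invariants(self):
        with pytest.raises(ValueError):
            SensorSpec(0, 10, 3.76)
        with pytest.raises(ValueError):
            SensorSpec(10, 10, 3.76, {12: -1.0})

    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "specs.yaml"
        cfg.write_text(
            "lens: {fov_mm: 16.8, na: 0.305, magnification: 5.0}\n"
            "sensor: {pixels_h: 14192, pixels_v: 10640, pitch_um: 3.76,\n"
            "         line_time_us: {12: 15.0, 14: 20.15, 16: 45.44}}\n"
            "expansion: 3.0\n"
        )
        specs = design.load_specs(cfg)
        assert specs["lens"].na == 0.305
        assert specs["sensor"].line_time_us[14] == 20.15
        assert specs["expansion"].factor == 3.0

    def test_design_report_is_consistent(self):
        lens = LensSpec(fov_mm=16.8, na=0.305, magnification=5.0)
        sensor = SensorSpec(14192, 10640, 3.76, {12: 15.0, 16: 45.44})
        report = design.design_report(lens, sensor, ExpansionSpec(3.0))
        assert report["readout"]["12"]["megavoxels_per_s"] == 946
        assert report["readout"]["16"]["megavoxels_per_s"] == 312
        assert report["nyquist_resolution_rounded"] == 1.5
        assert report["effective_lateral_resolution_um"] == pytest.approx(0.5, abs=0.002)
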