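import numpy as np
import pandas as pd
import pytest

import nearsource as ns
from nearsource.dispersion import CalmHourError, PlumeParams


def _source(**kw):
    defaults = dict(source_id="S", x=0.0, y=0.0, stack_height=40.0,
                    stack_diameter=3.0, exit_velocity=20.0,
                    exit_temperature=450.0, annual_emissions=4267.0)
    defaults.update(kw)
    return ns.PointSourceSpec(**defaults)


class TestPlumeRise:
    def test_no_buoyancy_no_momentum_gives_stack_height(self):
        src = _source(exit_velocity=0.0, exit_temperature=293.0)
        assert ns.briggs_plume_rise(src, 5.0, 293.0, "D") == 40.0

    def test_buoyant_neutral_rise_matches_formula_chain(self):
        # F = 9.80665*20*1.5^2*(450-293)/450 = 153.96 m^4/s^3 (> 55), so
        # x* = 34 F^(2/5) and dh = 1.6 F^(1/3) (3.5 x*)^(2/3) / u
        src = _source()
        H = ns.briggs_plume_rise(src, 5.0, 293.0, "D")
        assert H == pytest.approx(198.9645, abs=1e-3)

    def test_momentum_rise_halves_when_wind_doubles(self):
        src = _source(exit_temperature=280.0)  # Ts <= Ta: momentum only
        h1 = ns.briggs_plume_rise(src, 2.0, 293.0, "D") - 40.0
        h2 = ns.briggs_plume_rise(src, 4.0, 293.0, "D") - 40.0
        assert h1 == pytest.approx(2 * h2, rel=1e-12)

    def test_stable_rise_uses_stability_parameter(self):
        src = _source()
        hE = ns.briggs_plume_rise(src, 5.0, 293.0, "E")
        hF = ns.briggs_plume_rise(src, 5.0, 293.0, "F")
        assert hE > hF > 40.0  # weaker restoring force in E lets it rise more

    def test_calm_hour_rejected(self):
        with pytest.raises(CalmHourError):
            ns.briggs_plume_rise(_source(), 0.2, 293.0, "D")


class TestSigmaCurves:
    def test_class_d_at_1km(self):
        sy, sz = ns.sigma_yz("D", 1000.0)
        assert sy == pytest.approx(76.28, abs=0.01)
        assert sz == pytest.approx(37.95, abs=0.01)

    @pytest.mark.parametrize("cls", list("ABCDEF"))
    def test_sigma_y_strictly_increasing(self, cls):
        x = np.linspace(10, 50000, 500)
        sy, _ = ns.sigma_yz(cls, x)
        assert np.all(np.diff(sy) > 0)

    def test_unstable_spreads_faster_than_stable(self):
        x = np.logspace(1, 4.5, 50)
        _, szA = ns.sigma_yz("A", x)
        _, szF = ns.sigma_yz("F", x)
        assert np.all(szA > szF)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ns.sigma_yz("D", 0.0)


class TestPlumeEquation:
    def test_centerline_closed_form(self):
        p = PlumeParams(effective_height=50.0, sigma_y=100.0, sigma_z=50.0,
                        emission_rate=100.0, wind_speed=5.0)
        c = ns.plume_concentration(p, 0.0, 0.0, np.inf)
        assert c == pytest.approx(7.723e-4, rel=1e-4)

    def test_crosswind_symmetry_and_decay(self):
        p = PlumeParams(50.0, 100.0, 50.0, 100.0, 5.0)
        for y in (50.0, 200.0, 1000.0):
            assert ns.plume_concentration(p, y) == ns.plume_concentration(p, -y)
        assert ns.plume_concentration(p, 1e6) == pytest.approx(0.0, abs=1e-30)

    def test_linearity_in_emission_rate(self):
        p1 = PlumeParams(50.0, 100.0, 50.0, 100.0, 5.0)
        p7 = PlumeParams(50.0, 100.0, 50.0, 700.0, 5.0)
        c1 = ns.plume_concentration(p1, 30.0, 0.0, 800.0)
        c7 = ns.plume_concentration(p7, 30.0, 0.0, 800.0)
        assert c7 == pytest.approx(7.0 * c1, rel=1e-14)

    def test_mass_conservation_across_transect(self):
        # crosswind-vertical trapezoidal integral of C*u recovers Q
        Q, u, H = 100.0, 5.0, 100.0
        sy, sz = ns.sigma_yz("D", 2000.0)
        p = PlumeParams(H, sy, sz, Q, u)
        ys = np.linspace(-8 * sy, 8 * sy, 801)
        zs = np.linspace(0.0, H + 8 * sz, 801)
        C = np.array([ns.plume_concentration(p, ys, receptor_z=z)
                      for z in zs])
        flux = np.trapezoid(np.trapezoid(C, ys, axis=1), zs) * u
        assert flux == pytest.approx(Q, rel=0.005)

    @pytest.mark.parametrize("sz", [200.0, 600.0, 1200.0])
    def test_four_reflections_suffice(self, sz):
        # N=4 image sources match N=50 within 0.1% while sigma_z <= 1.6 zi
        zi = 800.0
        p = PlumeParams(100.0, 100.0, sz, 100.0, 5.0)
        c4 = ns.plume_concentration(p, 0.0, 0.0, zi, n_reflections=4)
        c50 = ns.plume_concentration(p, 0.0, 0.0, zi, n_reflections=50)
        assert c4 == pytest.approx(c50, rel=1e-3)

    def test_ground_centerline_unimodal_for_elevated_release(self):
        xs = np.logspace(1.3, np.log10(50000), 800)
        cs = []
        for x in xs:
            sy, sz = ns.sigma_yz("D", x)
            cs.append(ns.plume_concentration(
                PlumeParams(150.0, sy, sz, 100.0, 5.0), 0.0))
        d = np.diff(cs)
        d = d[d != 0]
        assert np.sum(np.diff(np.sign(d)) != 0) == 1
        assert 0 < np.argmax(cs) < len(cs) - 1


class TestHourlyField:
    def _met_row(self, wind_dir, u=5.0, stability="D"):
        idx = pd.date_range("2022-06-01", periods=1, freq="h")
        return pd.DataFrame({
            "wind_speed": [u], "wind_dir_from": [wind_dir],
            "temperature": [293.0], "cloud_fraction": [0.2],
            "stability": [stability], "mixing_height": [1200.0],
            "calm": [u < 0.5],
        }, index=idx)

    def test_only_downwind_receptors_see_plume(self, small_region):
        met = self._met_row(wind_dir=180.0)  # from south -> transport north
        field = ns.simulate_hourly_field(small_region.source, small_region, met)
        row = field.iloc[0]
        for bg in small_region.block_groups:
            if bg.centroid_y <= small_region.source.y:
                assert row[bg.bg_id] == 0.0
        north = [bg.bg_id for bg in small_region.block_groups
                 if bg.centroid_y > small_region.source.y]
        assert (row[north] > 0).any()

    def test_all_calm_met_gives_all_missing_field(self, small_region):
        met = self._met_row(wind_dir=180.0, u=0.1)
        field = ns.simulate_hourly_field(small_region.source, small_region, met)
        assert field.isna().all().all()
        assert field.attrs["calm_fraction"] == 1.0

    def test_annual_mean_decays_beyond_peak_along_bearing(self):
        # receptors on a fixed northward ray, uniform wind rose
        src = _source()
        bgs = []
        dists = np.linspace(2.0, 48.0, 24)
        for i, d in enumerate(dists):
            bgs.append(ns.BlockGroup(
                bg_id=f"R{i:02d}", centroid_x=0.0, centroid_y=d * 1000.0,
                distance_km=float(d), pop_by_age=(100,) * 9,
                poc_frac=0.5, li_frac=0.5,
                baseline_mortality_by_age=(100.0,) * 9,
                asthma_incidence_0_14=1000.0))
        region = ns.RegionScenario(source=src, block_groups=bgs,
                                   ozone_background=37.0)
        met = ns.generate_met_year(2022, ns.WindroseSpec(), seed=13)
        field = ns.simulate_hourly_field(src, region, met)
        annual = field.mean(axis=0, skipna=True).to_numpy()
        peak = int(np.argmax(annual))
        assert np.all(np.diff(annual[peak:]) < 0)

    def test_empty_met_rejected(self, small_region):
        empty = self._met_row(0.0).iloc[0:0]
        with pytest.raises(ValueError):
            ns.simulate_hourly_field(small_region.source, small_region, empty)
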