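import copy
import dataclasses

import numpy as np
import pytest

from vesselheal import ScenarioConfig, VesselModel, run_case
from vesselheal.injury import calibrate_profile
from vesselheal.parameters import RemodelParams


class TestHomeostasis:
    def test_laplace_balance_at_reference(self, small_vessel):
        g = small_vessel.geom
        target = g.pressure * g.inner_radius / g.thickness
        assert target == pytest.approx(0.08125)
        sig = small_vessel.mean_sigma(1.0, 1.0)
        assert abs((sig[1] - sig[0]) - target) < 1e-8

    def test_equilibrium_stretch_is_unity(self, small_vessel):
        assert small_vessel.solve_equilibrium() == pytest.approx(1.0, abs=1e-10)

    def test_unpressurized_passive_solve(self, registry):
        params = dataclasses.replace(registry)
        params.geometry = dataclasses.replace(registry.geometry, pressure=0.0)
        m = VesselModel.homeostatic(params, n_theta=2, n_r=1)
        sig = m.mean_sigma(1.0, 1.0)
        assert abs(sig[1] - sig[0]) < 1e-8

    def test_pressure_radius_monotonicity(self, registry):
        """Equilibrium radius is non-decreasing in pressure over 0-20 kPa."""
        m = VesselModel.homeostatic(registry, n_theta=2, n_r=1)
        radii = []
        for p in np.linspace(0.0, 0.02, 9):
            m.geom = dataclasses.replace(registry.geometry, pressure=p)
            radii.append(m.solve_equilibrium())
        assert all(a <= b + 1e-12 for a, b in zip(radii, radii[1:]))


class TestClamp:
    def test_zero_load_leaves_state_bitwise_unchanged(self, small_vessel):
        before = copy.deepcopy(small_vessel.points)
        phi_before = small_vessel.phi_ec
        small_vessel.apply_clamp(None)
        assert small_vessel.phi_ec == phi_before
        for pt0, pt1 in zip(before, small_vessel.points):
            assert pt0.state.rho_csmc == pt1.state.rho_csmc
            assert pt0.state.beta_hist == pt1.state.beta_hist
            for f0, f1 in zip(pt0.state.families, pt1.state.families):
                assert np.array_equal(f0.m, f1.m)
                assert np.array_equal(f0.q, f1.q)

    @pytest.mark.parametrize("load,phi,csmc,coll", [
        (0.6, 0.3113, 0.7170, 0.9076),
        (1.27, 0.2719, 0.7190, 0.9071),
    ])
    def test_acute_damage_matches_calibration_targets(self, registry, load, phi, csmc, coll):
        m = VesselModel.homeostatic(registry, n_theta=48, n_r=3)
        m.solve_equilibrium()
        m.apply_clamp(calibrate_profile(load, registry, 48, 3))
        fr = m.constituent_fractions()
        assert fr["endothelium"] == pytest.approx(phi, abs=2e-3)
        assert fr["csmc"] == pytest.approx(csmc, abs=2e-3)
        assert fr["collagen"] == pytest.approx(coll, abs=0.02)
        assert fr["ssmc"] == pytest.approx(1.0, abs=1e-12)
        assert fr["elastin"] == 1.0
        assert m.lambda_t > 1.0  # acute dilatation

    def test_profile_grid_mismatch_rejected(self, registry, small_vessel):
        prof = calibrate_profile(0.6, registry, 12, 2)  # wrong grid
        with pytest.raises(ValueError, match="grid"):
            small_vessel.apply_clamp(prof)


class TestHealing:
    def test_month_trajectory_shape(self, registry):
        """Healing from the heavy-clamp acute state shows the contractile
        dip, synthetic/collagen overshoot, mid-month recovery of the
        stretch deviation and partial return toward baseline."""
        m = VesselModel.homeostatic(registry, n_theta=8, n_r=1)
        m.solve_equilibrium()
        m.init_from_acute_fractions(collagen=0.9071, csmc=0.7190, ssmc=1.0,
                                    endothelium=0.2719)
        df = m.heal(31)
        csmc = df["csmc"].to_numpy()
        ssmc = df["ssmc"].to_numpy()
        coll = df["collagen"].to_numpy()
        lam = df["lambda_t"].to_numpy()
        # contractile dip below the acute value, then partial recovery
        assert csmc.min() < csmc[0]
        assert csmc[-1] > csmc.min()
        # synthetic overshoot and partial return
        assert ssmc.max() > 1.2
        assert ssmc[-1] < ssmc.max()
        # collagen overshoots its homeostatic level
        assert coll.max() > 1.0 > coll[0]
        # the stretch deviation vanishes mid-month (stiffness restored)
        cross = np.where(np.diff(np.sign(lam - 1.0)))[0]
        assert cross.size >= 1
        assert 7 <= df["day"].iloc[cross[0]] <= 25

    def test_variant_damping_and_oscillation(self, registry):
        """The original phenotype law oscillates beyond one month; the
        no-redifferentiation variant stabilizes with a much smaller
        synthetic-cell swing and a non-increasing contractile pool."""
        hist = {}
        for variant in ("original", "no_redifferentiation"):
            m = VesselModel.homeostatic(registry, n_theta=4, n_r=1)
            m.solve_equilibrium()
            m.init_from_acute_fractions(collagen=0.9071, csmc=0.7190, ssmc=1.0,
                                        endothelium=0.2719)
            hist[variant] = m.heal(91, RemodelParams(variant=variant))
        late = {v: df[(df.day >= 31) & (df.day <= 91)] for v, df in hist.items()}
        p2p = {v: float(df["ssmc"].max() - df["ssmc"].min()) for v, df in late.items()}
        assert p2p["no_redifferentiation"] < p2p["original"]
        csmc = hist["no_redifferentiation"]["csmc"].to_numpy()
        assert np.all(np.diff(csmc) <= 1e-12)
        # oscillation of the original model: interior extrema of collagen
        coll = late["original"]["collagen"].to_numpy()
        interior = coll[1:-1]
        has_max = np.any((interior > coll[:-2]) & (interior > coll[2:]))
        has_min = np.any((interior < coll[:-2]) & (interior < coll[2:]))
        assert has_max and has_min

    def test_laplace_residual_at_every_step(self, registry):
        from vesselheal.remodeling import remodeling_step
        m = VesselModel.homeostatic(registry, n_theta=2, n_r=1)
        m.solve_equilibrium()
        m.init_from_acute_fractions(collagen=0.95, csmc=0.8, ssmc=1.0, endothelium=0.5)
        for _ in range(5):
            remodeling_step(m, registry.remodeling)
            # the equilibrium stretch found for the current wall state
            # satisfies the Laplace balance to solver tolerance
            lam = m.solve_equilibrium()
            sig = m.mean_sigma(lam, 1.0)
            assert abs((sig[1] - sig[0]) - m.laplace_target(lam, 1.0)) < 1e-8


class TestExcisionAndMyograph:
    def test_excised_ring_recoils_and_is_traction_free(self, small_vessel):
        lt, lz = small_vessel.excise()
        assert lt < 1.0
        assert lz < 1.0
        sig = small_vessel.mean_sigma(lt, lz, include_active=True)
        assert abs(sig[1] - sig[0]) < 1e-7
        assert abs(sig[2] - sig[0]) < 1e-7

    def test_force_displacement_has_three_zones(self, small_vessel):
        res = small_vessel.myograph()
        d_slack, d_taut = res.zones
        assert 0.0 < d_slack < d_taut < res.gap_preload
        f = res.force
        d = res.displacement
        assert np.all(f[d <= d_slack] == 0.0)
        mid = f[(d > d_slack) & (d <= d_taut)]
        assert mid.size > 0 and np.all(mid < 0.05 * f.max())
        assert f[-1] == f.max() > 0.0
        # stiffening: the last segment is much steeper than the straightening zone
        straight_slope = mid.max() / (d_taut - d_slack)
        final_slope = (f[-1] - f[-2]) / (d[-1] - d[-2])
        assert final_slope > 10 * straight_slope

    def test_preload_is_reached(self, small_vessel):
        res = small_vessel.myograph()
        assert res.stage_forces["baseline"] == pytest.approx(0.0133, rel=5e-3)

    def test_dose_signature(self, small_vessel):
        forces = small_vessel.myograph().stage_forces
        assert forces["PE"] > forces["baseline"]
        assert forces["PE+NO"] < forces["PE+ACh"] < forces["PE"]


class TestCases:
    def test_control_case_stays_homeostatic(self, registry):
        res = run_case(ScenarioConfig(case_id="A0", n_theta=8, n_r=2), registry)
        for k in ("elastin", "collagen", "csmc", "ssmc", "endothelium"):
            assert res.final_fractions[k] == pytest.approx(1.0, abs=1e-9)
        assert res.final_fractions["inflammation"] == pytest.approx(0.0, abs=1e-9)

    def test_healed_control_matches_acute_control(self, registry):
        a0 = run_case(ScenarioConfig(case_id="A0", n_theta=8, n_r=2), registry)
        r0 = run_case(ScenarioConfig(case_id="R0", n_theta=8, n_r=2), registry)
        assert np.allclose(a0.myograph.force, r0.myograph.force, rtol=1e-6, atol=1e-12)
        for k, v in a0.myograph.stage_forces.items():
            assert r0.myograph.stage_forces[k] == pytest.approx(v, rel=1e-6)

    def test_rerun_is_bit_reproducible(self, registry):
        cfg = ScenarioConfig(case_id="A1", n_theta=16, n_r=2)
        r1 = run_case(cfg, registry)
        r2 = run_case(cfg, registry)
        assert r1.myograph.stage_forces == r2.myograph.stage_forces
        assert np.array_equal(r1.myograph.force, r2.myograph.force)
        assert r1.final_fractions == r2.final_fractions

    def test_two_clamp_loads_nearly_indistinguishable(self, registry):
        """The two acute clamp cases differ little, mirroring the small
        measured difference between the 0.6 N and 1.27 N injuries."""
        a1 = run_case(ScenarioConfig(case_id="A1", n_theta=24, n_r=2), registry)
        a2 = run_case(ScenarioConfig(case_id="A2", n_theta=24, n_r=2), registry)
        f1, f2 = a1.myograph.force, a2.myograph.force
        scale = f1.max()
        # compare on a common displacement grid
        d = np.linspace(0, min(a1.myograph.displacement[-1], a2.myograph.displacement[-1]), 40)
        c1 = np.interp(d, a1.myograph.displacement, f1)
        c2 = np.interp(d, a2.myograph.displacement, f2)
        assert np.max(np.abs(c1 - c2)) < 0.01 * scale

    def test_ach_response_smaller_acutely_than_healed(self, registry):
        acute = run_case(ScenarioConfig(case_id="A1", n_theta=16, n_r=2), registry)
        healed = run_case(ScenarioConfig(case_id="R1", n_theta=16, n_r=2), registry)
        drop = lambda r: r.myograph.stage_forces["PE"] - r.myograph.stage_forces["PE+ACh"]
        assert drop(acute) < drop(healed)
        assert acute.final_fractions["endothelium"] == pytest.approx(0.3113, abs=3e-3)
        assert healed.final_fractions["endothelium"] == pytest.approx(0.8463, abs=3e-3)
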