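"""Terrestrial launch: stall speed, sprinting, flap-running, leaping, WAIR."""
import math

import numpy as np
import pytest

from paleoflight import (AeroConfig, SchemaError, fit_sprint_allometry,
                         flap_run_simulate, leap_takeoff, sprint_speed,
                         takeoff_analysis, takeoff_speed, wair_capability,
                         wingbeat_frequency)
from paleoflight.wings import WingPlanform, build_wing_model


class TestTakeoffSpeed:
    def test_quadrupling_area_halves_speed(self, cfg):
        small = WingPlanform(model="MFW", span_b_m=1.0, area_S_m2=0.05)
        large = WingPlanform(model="MFW", span_b_m=1.0, area_S_m2=0.20)
        assert takeoff_speed(0.4, small, 1.5, cfg) == \
            pytest.approx(2 * takeoff_speed(0.4, large, 1.5, cfg), rel=1e-12)

    def test_forced_arithmetic(self):
        cfg = AeroConfig(rho_air=1.0)
        planform = WingPlanform(model="MFW", span_b_m=3.0, area_S_m2=1.0)
        cl = 2 * 1.0 * cfg.g / 25.0   # makes 2 m g/(rho S Cl) = 25
        assert takeoff_speed(1.0, planform, cl, cfg) == pytest.approx(5.0, rel=1e-12)

    def test_vto_times_sqrt_cl_invariant(self, cfg, simple_planform):
        values = {cl: takeoff_speed(0.4, simple_planform, cl, cfg) * math.sqrt(cl)
                  for cl in (0.5, 1.0, 1.5, 2.0)}
        ref = values[1.0]
        for v in values.values():
            assert v == pytest.approx(ref, rel=1e-12)

    def test_yi_stall_vs_sprint_ratio_in_published_band(self, yi, cfg):
        """For the permutations that cannot take off by running alone, minimum
        flight speed is 1.1-2.9x the sprint speed."""
        v_sprint = sprint_speed(yi, cfg)
        for model in ("MFW", "BBW"):
            planform = build_wing_model(yi, model, cfg)
            for mass in yi.mass_hypotheses_kg:
                ratio = takeoff_speed(mass, planform, max(cfg.cl_set), cfg) / v_sprint
                assert 1.1 <= ratio <= 2.9


class TestSprint:
    def test_linear_in_coefficient(self, yi, cfg):
        doubled = cfg.replace(sprint_coeff_a=2 * cfg.sprint_coeff_a)
        assert sprint_speed(yi, doubled) == pytest.approx(2 * sprint_speed(yi, cfg))

    def test_longer_legs_run_faster(self, make_specimen, cfg):
        short = make_specimen()
        segments = dict(short.segments_m)
        segments["hindlimb_total"] *= 1.5
        long = make_specimen(specimen_id="T-2", segments_m=segments)
        assert sprint_speed(long, cfg) > sprint_speed(short, cfg)

    def test_missing_hindlimb_raises(self, make_specimen, cfg):
        spec = make_specimen(segments_m={"femur": 0.05})
        with pytest.raises(SchemaError, match="hindlimb"):
            sprint_speed(spec, cfg)

    def test_allometry_parameter_recovery(self):
        """Speeds simulated from known (a, p, q) plus noise refit to estimates
        whose confidence intervals cover the truth."""
        rng = np.random.default_rng(12)
        a, p, q = 9.0, 0.45, 0.08
        leg = rng.uniform(0.05, 0.4, 200)
        mass = rng.uniform(0.05, 2.0, 200)
        v = a * leg ** p * mass ** q * rng.lognormal(0, 0.05, 200)
        res = fit_sprint_allometry(leg, mass, v)
        ci = res.conf_int()
        assert ci[0][0] <= math.log(a) <= ci[0][1]
        assert ci[1][0] <= p <= ci[1][1]
        assert ci[2][0] <= q <= ci[2][1]


class TestFlapRun:
    def test_no_flapping_no_takeoff(self, yi, cfg):
        planform = build_wing_model(yi, "BBW", cfg)
        still = cfg.replace(flap_amplitude_rad=0.0)
        res = flap_run_simulate(yi, planform, 2.0, "bird", still, mass_kg=0.38)
        assert res.t_takeoff_s is None
        assert res.lift_fraction.max() < 1.0

    def test_yi_bat_wing_model_published_takeoff_pattern(self, yi, cfg):
        """Bat-area wing + bird wingbeat: take-off around 5-6 s at the two
        lighter masses, none at the heaviest; slower at Cl 1.5 (beyond 7 s)
        and never at Cl 1."""
        planform = build_wing_model(yi, "BBW", cfg)
        t38 = flap_run_simulate(yi, planform, 2.0, "bird", cfg, mass_kg=0.38)
        t45 = flap_run_simulate(yi, planform, 2.0, "bird", cfg, mass_kg=0.45)
        t70 = flap_run_simulate(yi, planform, 2.0, "bird", cfg, mass_kg=0.70)
        assert t38.achieved and t45.achieved and not t70.achieved
        assert 4.0 < t38.t_takeoff_s < t45.t_takeoff_s < 8.0
        cl15 = flap_run_simulate(yi, planform, 1.5, "bird", cfg, mass_kg=0.38)
        assert cl15.achieved and cl15.t_takeoff_s > 7.0
        assert not flap_run_simulate(yi, planform, 1.0, "bird", cfg,
                                     mass_kg=0.38).achieved

    def test_ambopteryx_never_achieves_flap_running(self, ambopteryx, cfg):
        for model in ("MFW", "BBW"):
            planform = build_wing_model(ambopteryx, model, cfg)
            for mass in ambopteryx.mass_hypotheses_kg:
                for freq in ("bird", "bat"):
                    res = flap_run_simulate(ambopteryx, planform, 2.0, freq,
                                            cfg, mass_kg=mass)
                    assert not res.achieved

    def test_takeoff_time_monotone_in_cl_frequency_and_area(self, yi, cfg):
        planform = build_wing_model(yi, "BBW", cfg)
        t_cl = [flap_run_simulate(yi, planform, cl, "bird", cfg,
                                  mass_kg=0.38).t_takeoff_s for cl in (1.8, 2.0, 2.2)]
        assert t_cl[0] > t_cl[1] > t_cl[2]
        fast = cfg.replace(bat_frequency_factor=0.9)
        t_f = [flap_run_simulate(yi, planform, 2.0, m, c, mass_kg=0.38).t_takeoff_s
               for m, c in (("bat", fast), ("bird", cfg))]
        assert t_f[0] is None or t_f[0] > t_f[1]
        bigger = WingPlanform(model="BBW", span_b_m=planform.span_b_m,
                              area_S_m2=1.15 * planform.area_S_m2)
        assert flap_run_simulate(yi, bigger, 2.0, "bird", cfg,
                                 mass_kg=0.38).t_takeoff_s < t_cl[1]

    def test_integration_converges_under_step_halving(self, yi, cfg):
        planform = build_wing_model(yi, "BBW", cfg)
        t1 = flap_run_simulate(yi, planform, 2.0, "bird", cfg, mass_kg=0.38,
                               dt=0.01).t_takeoff_s
        t2 = flap_run_simulate(yi, planform, 2.0, "bird", cfg, mass_kg=0.38,
                               dt=0.005).t_takeoff_s
        assert abs(t1 - t2) / t1 < 0.02


class TestLeap:
    def test_zero_leap_coefficient_never_launches(self, yi, cfg):
        planform = build_wing_model(yi, "MFW", cfg)
        grounded = cfg.replace(leap_coeff=0.0)
        # zero launch speed: only flapping airspeed remains, far below stall speed
        res = leap_takeoff(yi, planform, grounded, with_flapping=True)
        assert not res.achieves_takeoff

    def test_scansoriopterygids_never_leap_to_takeoff(self, fixtures, cfg):
        for sid in ("STM 31-2", "STM 0-144"):
            spec = fixtures.get(sid)
            for model in spec.wing_geometry:
                planform = build_wing_model(spec, model, cfg)
                for mass in spec.mass_hypotheses_kg:
                    for flapping in (False, True):
                        res = leap_takeoff(spec, planform, cfg,
                                           with_flapping=flapping, mass_kg=mass)
                        assert not res.achieves_takeoff

    def test_constructed_boundary_case_achieves(self, make_specimen, cfg):
        # enormous wing: stall speed below the leap launch speed
        spec = make_specimen(wing_geometry={"MFW": {"span_m": 4.0, "area_m2": 4.0}})
        planform = build_wing_model(spec, "MFW", cfg)
        res = leap_takeoff(spec, planform, cfg, with_flapping=False)
        assert res.V_takeoff_m_s < res.launch_velocity_m_s
        assert res.achieves_takeoff


class TestWair:
    def test_no_flapping_means_no_wair(self, yi, cfg):
        planform = build_wing_model(yi, "BBW", cfg)
        still = cfg.replace(flap_amplitude_rad=0.0, wair_speed=1e-6)
        res = wair_capability(yi, planform, 1.5, "bird", still)
        assert res.lift_fraction_of_weight == pytest.approx(0.0, abs=1e-9)
        assert res.level == "none"

    def test_yi_reaches_level_one_across_masses_with_bird_flapping(self, yi, cfg):
        for model in ("MFW", "BBW"):
            planform = build_wing_model(yi, model, cfg)
            for mass in yi.mass_hypotheses_kg:
                res = wair_capability(yi, planform, 1.5, "bird", cfg, mass_kg=mass)
                assert res.level in ("I", "II")

    def test_bat_frequency_curtails_yi_wair(self, yi, cfg):
        for model in ("MFW", "BBW"):
            planform = build_wing_model(yi, model, cfg)
            bird = wair_capability(yi, planform, 1.5, "bird", cfg, mass_kg=0.70)
            bat = wair_capability(yi, planform, 1.5, "bat", cfg, mass_kg=0.70)
            assert bat.lift_fraction_of_weight < bird.lift_fraction_of_weight

    def test_ambopteryx_only_bat_area_with_bird_flapping(self, ambopteryx, cfg):
        reached = {}
        for model in ("MFW", "BBW"):
            planform = build_wing_model(ambopteryx, model, cfg)
            for freq in ("bird", "bat"):
                levels = [wair_capability(ambopteryx, planform, 1.5, freq, cfg,
                                          mass_kg=m).level
                          for m in ambopteryx.mass_hypotheses_kg]
                reached[(model, freq)] = any(lv != "none" for lv in levels)
        assert reached == {("MFW", "bird"): False, ("MFW", "bat"): False,
                           ("BBW", "bird"): True, ("BBW", "bat"): False}

    def test_level_monotone_in_lift_fraction(self, yi, cfg):
        planform = build_wing_model(yi, "BBW", cfg)
        fractions, ranks = [], []
        order = {"none": 0, "I": 1, "II": 2}
        for cl in (0.2, 0.8, 1.5, 3.0, 6.0):
            res = wair_capability(yi, planform, cl, "bird", cfg, mass_kg=0.38)
            fractions.append(res.lift_fraction_of_weight)
            ranks.append(order[res.level])
        assert fractions == sorted(fractions)
        assert ranks == sorted(ranks)


def test_takeoff_analysis_bundles_consistently(yi, cfg):
    planform = build_wing_model(yi, "BBW", cfg)
    res = takeoff_analysis(yi, planform, 1.5, "bird", cfg, mass_kg=0.38)
    assert res.ratio_takeoff_sprint == pytest.approx(
        res.V_takeoff_m_s / res.V_sprint_m_s, rel=1e-12)
    assert res.V_takeoff_m_s == pytest.approx(
        takeoff_speed(0.38, planform, 1.5, cfg), rel=1e-12)


def test_bird_frequency_exceeds_bat(yi, cfg):
    planform = build_wing_model(yi, "BBW", cfg)
    f_bird = wingbeat_frequency(0.38, planform, cfg, "bird")
    f_bat = wingbeat_frequency(0.38, planform, cfg, "bat")
    assert f_bat == pytest.approx(cfg.bat_frequency_factor * f_bird, rel=1e-12)
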