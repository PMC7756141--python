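"""Wing planforms, wing loading thresholds and anatomical ratios."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleoflight import (AeroConfig, ValidationError, anatomical_ratios,
                         build_wing_model, polygon_area, wing_loading)
from paleoflight.specimens import SchemaError
from paleoflight.wings import WingPlanform


class TestPlanform:
    def test_explicit_geometry_pass_through(self, make_specimen, cfg):
        spec = make_specimen(wing_geometry={"MFW": {"span_m": 1.0, "area_m2": 0.1}})
        planform = build_wing_model(spec, "MFW", cfg)
        assert planform.span_b_m == 1.0
        assert planform.area_S_m2 == 0.1
        assert planform.aspect_ratio_Ra == pytest.approx(10.0, rel=1e-12)

    def test_rectangle_template_area(self):
        # half-span 0.5, chord 0.1: one wing 0.05 m^2, doubled, zero body strip
        rect = [(0.0, 0.0), (0.0, 0.5), (0.1, 0.5), (0.1, 0.0)]
        assert polygon_area(rect) == pytest.approx(0.05, rel=1e-12)

    def test_model_area_ordering(self, make_specimen, cfg):
        spec = make_specimen(wing_geometry={})
        areas = {m: build_wing_model(spec, m, cfg).area_S_m2
                 for m in ("MFW", "BBW", "PTW", "FRW")}
        assert areas["FRW"] <= areas["MFW"] <= areas["BBW"]
        assert areas["MFW"] <= areas["PTW"]

    def test_missing_anchor_error_lists_segments(self, make_specimen, cfg):
        spec = make_specimen(wing_geometry={}, segments_m={"femur": 0.05})
        with pytest.raises(SchemaError, match="humerus"):
            build_wing_model(spec, "MFW", cfg)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 3.0))
    def test_polygon_area_invariances(self, seed, scale):
        """Translation/rotation leave area unchanged; scaling lengths by c
        multiplies area by c^2."""
        rng = np.random.default_rng(seed)
        # jittered spokes around the full circle keep the polygon simple
        theta = 2 * np.pi * (np.arange(6) + rng.uniform(0, 0.9, 6)) / 6
        r = rng.uniform(0.2, 1.0, 6)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        base = polygon_area(pts)
        shift = pts + rng.uniform(-5, 5, 2)
        rot = math.radians(rng.uniform(0, 360))
        R = np.array([[math.cos(rot), -math.sin(rot)],
                      [math.sin(rot), math.cos(rot)]])
        assert polygon_area(shift) == pytest.approx(base, rel=1e-9)
        assert polygon_area(pts @ R.T) == pytest.approx(base, rel=1e-9)
        assert polygon_area(pts * scale) == pytest.approx(base * scale ** 2, rel=1e-9)

    def test_doubling_segments_quadruples_area_doubles_span(self, make_specimen, cfg):
        spec = make_specimen(wing_geometry={})
        big = make_specimen(wing_geometry={}, specimen_id="T-2",
                            segments_m={k: 2 * v for k, v in spec.segments_m.items()})
        p1 = build_wing_model(spec, "BBW", cfg)
        p2 = build_wing_model(big, "BBW", cfg)
        assert p2.area_S_m2 == pytest.approx(4 * p1.area_S_m2, rel=1e-9)
        assert p2.span_b_m == pytest.approx(2 * p1.span_b_m, rel=1e-9)


class TestWingLoading:
    def test_forced_arithmetic(self, cfg):
        planform = WingPlanform(model="MFW", span_b_m=10.0, area_S_m2=9.81)
        assert wing_loading(1.0, planform, cfg).wing_loading_N_m2 == \
            pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("wl, flight, envelope", [
        (244.0, True, False),    # just under the any-flight ceiling
        (245.0, True, False),    # inclusive bound
        (246.0, False, False),
        (143.0, True, True),     # glider envelope upper bound inclusive
        (157.0, True, False),    # beyond extant gliders
        (9.0, True, True),
        (8.9, True, False),
    ])
    def test_threshold_classification(self, cfg, wl, flight, envelope):
        planform = WingPlanform(model="MFW", span_b_m=3.0, area_S_m2=cfg.g / wl)
        cls = wing_loading(1.0, planform, cfg)
        assert cls.wing_loading_N_m2 == pytest.approx(wl, rel=1e-12)
        assert cls.flight_possible is flight
        assert cls.in_glider_envelope is envelope

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.05, 5.0), st.floats(0.2, 5.0))
    def test_homogeneity(self, mass, c):
        cfg = AeroConfig()
        planform = WingPlanform(model="MFW", span_b_m=1.0, area_S_m2=0.08)
        scaled_area = WingPlanform(model="MFW", span_b_m=1.0,
                                   area_S_m2=0.08 * c)
        base = wing_loading(mass, planform, cfg).wing_loading_N_m2
        assert wing_loading(mass * c, planform, cfg).wing_loading_N_m2 == \
            pytest.approx(base * c, rel=1e-12)
        assert wing_loading(mass, scaled_area, cfg).wing_loading_N_m2 == \
            pytest.approx(base / c, rel=1e-12)


class TestAnatomicalRatios:
    def test_equal_segments_give_one_third(self, make_specimen):
        spec = make_specimen(segments_m={"humerus": 1.0, "ulna": 1.0,
                                         "styliform": 1.0},
                             wing_geometry={})
        assert anatomical_ratios(spec)["styliform_fraction"] == \
            pytest.approx(1 / 3, rel=1e-12)

    def test_fixture_ratios_match_published_values(self, fixtures):
        yi = anatomical_ratios(fixtures.get("STM 31-2"))
        ambo = anatomical_ratios(fixtures.get("STM 0-144"))
        assert yi["styliform_fraction"] == pytest.approx(0.42, abs=0.005)
        assert ambo["styliform_fraction"] == pytest.approx(0.32, abs=0.005)
        assert yi["forelimb_femur"] == pytest.approx(4.65, abs=0.01)
        assert ambo["forelimb_femur"] == pytest.approx(4.65, abs=0.01)
        assert yi["dpc_fraction"] == pytest.approx(0.19, abs=0.005)
        assert ambo["dpc_fraction"] == pytest.approx(0.22, abs=0.005)
        assert yi["phalangeal_index_III"] == pytest.approx(1.7, abs=0.01)
        assert yi["phalangeal_index_IV"] == pytest.approx(4.35, abs=0.01)

    def test_crural_index_contrast(self, fixtures):
        epidendrosaurus = anatomical_ratios(fixtures.get("IVPP V12653"))
        epidexipteryx = anatomical_ratios(fixtures.get("IVPP V15471"))
        assert epidendrosaurus["crural_index"] == pytest.approx(1.17, abs=0.005)
        assert epidexipteryx["crural_index"] == pytest.approx(1.25, abs=0.005)

    def test_missing_segment_omits_ratio(self, make_specimen):
        spec = make_specimen(segments_m={"tibia": 0.06, "femur": 0.05},
                             wing_geometry={})
        ratios = anatomical_ratios(spec)
        assert "crural_index" in ratios
        assert "styliform_fraction" not in ratios

    def test_forelimb_definition_with_and_without_manus(self, yi):
        without = anatomical_ratios(yi)["forelimb_femur"]
        including = anatomical_ratios(yi, include_manus_in_forelimb=True)
        assert including["forelimb_femur"] > without
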