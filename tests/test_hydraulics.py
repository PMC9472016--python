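import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spiralsort import (
    ChannelCrossSection,
    DeformationCurve,
    balance_outlet_flows,
    deformation_ratio,
    make_outlet_network,
    mean_velocity,
    rect_channel_resistance,
    rect_channel_resistance_approx,
    required_outlet_resistances,
)
from spiralsort.geometry import UM
from spiralsort.hydraulics import MBAR, si_to_ul_min, ul_min_to_si

CS_MAIN = ChannelCrossSection.from_um(300, 85)
L_MAIN = 0.334  # m


class TestMeanVelocity:
    @pytest.mark.parametrize(
        "q_ul_min, w, h, v_mm_s, tol",
        [
            (880, 300, 84, 582.0, 0.5),
            (940, 300, 89, 586.8, 0.5),  # printed as 586 mm/s
        ],
    )
    def test_working_point_velocities(self, q_ul_min, w, h, v_mm_s, tol):
        cs = ChannelCrossSection.from_um(w, h)
        assert mean_velocity(ul_min_to_si(q_ul_min), cs) * 1e3 == pytest.approx(
            v_mm_s, abs=tol
        )

    def test_unit_identity(self):
        # 1 ul/s over 1 mm^2 is 1 mm/s
        cs = ChannelCrossSection(1e-3, 1e-3)
        assert mean_velocity(1e-9, cs) == pytest.approx(1e-3)

    @given(q=st.floats(min_value=1, max_value=5000), k=st.floats(min_value=0.5, max_value=4))
    def test_linear_in_flow_inverse_in_area(self, q, k):
        v = mean_velocity(ul_min_to_si(q), CS_MAIN)
        assert mean_velocity(ul_min_to_si(k * q), CS_MAIN) == pytest.approx(k * v)
        big = ChannelCrossSection(CS_MAIN.width * k, CS_MAIN.height)
        assert mean_velocity(ul_min_to_si(q), big) == pytest.approx(v / k)


class TestRectResistance:
    def test_spiral_resistance_magnitude(self):
        # independent oracle: series evaluated at high truncation
        r = rect_channel_resistance(CS_MAIN, L_MAIN, n_terms=50)
        assert r == pytest.approx(2.6e13, rel=0.03)

    def test_pressure_drop_near_four_bar_at_design_flow(self):
        dp = rect_channel_resistance(CS_MAIN, L_MAIN) * ul_min_to_si(860)
        assert dp == pytest.approx(4e5, rel=0.10)

    def test_linearity_in_length(self):
        r1 = rect_channel_resistance(CS_MAIN, L_MAIN)
        assert rect_channel_resistance(CS_MAIN, 2 * L_MAIN) == pytest.approx(2 * r1)

    def test_closed_form_within_one_percent_for_shallow_ducts(self):
        for h_um in (30, 60, 85, 90):  # h/w in [0.1, 0.3]
            cs = ChannelCrossSection.from_um(300, h_um)
            exact = rect_channel_resistance(cs, L_MAIN)
            approx = rect_channel_resistance_approx(cs, L_MAIN)
            assert approx == pytest.approx(exact, rel=0.01)

    def test_series_converges(self):
        for h_um in (30, 100, 200, 300):  # h/w in [0.1, 1]
            cs = ChannelCrossSection.from_um(300, h_um)
            r10 = rect_channel_resistance(cs, L_MAIN, n_terms=10)
            r100 = rect_channel_resistance(cs, L_MAIN, n_terms=100)
            assert abs(r10 - r100) / r100 < 1e-3

    def test_transposed_duct_gives_same_resistance(self):
        a = rect_channel_resistance(ChannelCrossSection.from_um(300, 85), L_MAIN)
        b = rect_channel_resistance(ChannelCrossSection.from_um(85, 300), L_MAIN)
        assert a == pytest.approx(b, rel=1e-12)

    @given(
        w=st.floats(min_value=100, max_value=500),
        h=st.floats(min_value=20, max_value=100),
        grow=st.floats(min_value=1.01, max_value=2.0),
    )
    def test_monotone_decreasing_in_dimensions(self, w, h, grow):
        base = rect_channel_resistance(ChannelCrossSection.from_um(w, h), L_MAIN)
        wider = rect_channel_resistance(ChannelCrossSection.from_um(w * grow, h), L_MAIN)
        taller = rect_channel_resistance(ChannelCrossSection.from_um(w, h * grow), L_MAIN)
        assert wider < base and taller < base


def wb1_network():
    return make_outlet_network(
        [("inner", 70, 85, 10.0), ("middle", 145, 85, 10.0), ("outer", 85, 85, 10.0)],
        upstream_width_um=300,
    )


def wb1r_network():
    return make_outlet_network(
        [("inner", 103, 85, 10.0), ("outer", 412, 85, 10.0)],
        upstream_width_um=500,
    )


class TestOutletBalance:
    def test_identical_outlets_split_evenly(self):
        net = make_outlet_network(
            [("a", 100, 85, 10.0), ("b", 100, 85, 10.0)], upstream_width_um=300
        )
        flows = balance_outlet_flows(net, 100.0)
        assert flows["a"] == pytest.approx(50.0)
        assert flows["b"] == pytest.approx(50.0)

    def test_wb1r_bifurcation_exact_four_to_one(self):
        flows = balance_outlet_flows(wb1r_network(), 940.0)
        assert flows["inner"] == pytest.approx(752.0, rel=1e-12)
        assert flows["outer"] == pytest.approx(188.0, rel=1e-12)

    def test_wb1_trifurcation_against_linear_solve_oracle(self):
        # oracle: solve the two balance equations + conservation directly
        areas = np.array([70 * 85, 145 * 85, 85 * 85], dtype=float)
        A = np.array(
            [
                [areas[0], -areas[1], 0.0],
                [0.0, areas[1], -areas[2]],
                [1.0, 1.0, 1.0],
            ]
        )
        expected = np.linalg.solve(A, np.array([0.0, 0.0, 860.0]))
        flows = balance_outlet_flows(wb1_network(), 860.0)
        got = np.array([flows["inner"], flows["middle"], flows["outer"]])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx([372.9, 180.0, 307.1], abs=0.05)

    @given(q=st.floats(min_value=1.0, max_value=5000.0))
    def test_mass_conservation_and_equal_qs_products(self, q):
        net = wb1_network()
        flows = balance_outlet_flows(net, q)
        assert sum(flows.values()) == pytest.approx(q, rel=1e-15)
        products = [flows[o.label] * o.cross_section.area for o in net.outlets]
        assert max(products) - min(products) <= 1e-12 * max(products)


class TestRequiredOutletResistances:
    def test_identical_outlets_need_equal_lengths(self):
        net = make_outlet_network(
            [("a", 100, 85, 10.0), ("b", 100, 85, 10.0)], upstream_width_um=300
        )
        table = required_outlet_resistances(net, ul_min_to_si(860))
        assert table["length_required_mm"].nunique() == 1

    def test_required_lengths_invariant_to_flow_scale(self):
        net = wb1_network()
        t1 = required_outlet_resistances(net, ul_min_to_si(860))
        t2 = required_outlet_resistances(net, ul_min_to_si(1720))
        assert t1["length_required_mm"].to_numpy() == pytest.approx(
            t2["length_required_mm"].to_numpy(), rel=1e-12
        )

    def test_baseline_imbalance_reported_for_trifurcation(self):
        table = required_outlet_resistances(wb1_network(), ul_min_to_si(860))
        dp = table.set_index("outlet")["dP_baseline_mbar"]
        # the narrow inner outlet carries the most flow through the most
        # resistive duct: largest pressure drop at equal baseline lengths
        assert dp["inner"] > dp["middle"] and dp["inner"] > dp["outer"]
        assert table["dP_target_mbar"].max() == pytest.approx(dp.max())
        # balanced flows echoed in the report
        assert table.set_index("outlet")["Q_ul_min"]["inner"] == pytest.approx(
            372.9, abs=0.05
        )


class TestDeformation:
    def test_rigid_device_ratio_is_one(self):
        r = rect_channel_resistance(CS_MAIN, L_MAIN)
        p = 2800 * MBAR
        ratio, ok = deformation_ratio(p / r, CS_MAIN, L_MAIN, p)
        assert ratio == pytest.approx(1.0, rel=1e-12)
        assert ok

    def test_five_percent_deformation_at_threshold(self):
        r = rect_channel_resistance(CS_MAIN, L_MAIN)
        p = 2800 * MBAR
        ratio, ok = deformation_ratio(1.05 * p / r, CS_MAIN, L_MAIN, p)
        assert ratio == pytest.approx(1.05, rel=1e-12)
        assert ok  # boundary value still within the 5% band

    def test_ratio_is_plain_division(self):
        # 903/860 at the same theoretical flow
        r = rect_channel_resistance(CS_MAIN, L_MAIN)
        p = ul_min_to_si(860.0) * r  # pressure at which Q_th is 860 ul/min
        ratio, _ = deformation_ratio(ul_min_to_si(903), CS_MAIN, L_MAIN, p)
        assert ratio == pytest.approx(903 / 860, rel=1e-12)

    def test_curve_interpolation_and_extrapolation(self):
        curve = DeformationCurve(
            pressures=(1000 * MBAR, 2000 * MBAR, 4000 * MBAR),
            ratios=(1.0, 1.02, 1.10),
        )
        assert curve(1500 * MBAR) == pytest.approx(1.01)
        assert curve(500 * MBAR) == pytest.approx(1.0)   # constant below range
        assert curve(9000 * MBAR) == pytest.approx(1.10)  # constant above range

    def test_curve_rejects_dilation_below_one(self):
        with pytest.raises(ValueError):
            DeformationCurve(pressures=(1e5, 2e5), ratios=(0.98, 1.01))
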