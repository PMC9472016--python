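import numpy as np
import pytest

from spiralsort import (
    FlowCondition,
    LiftModel,
    ParticleSpec,
    SpiralGeometry,
    StreamlineMeasurement,
    equilibrium_distance,
    focusing_length,
    model_comparison,
    normalized_error,
)
from spiralsort.focusing import (
    DEFAULT_EQUILIBRIUM_OFFSET_FRACTION,
    net_lateral_force,
)
from spiralsort.geometry import UM
from spiralsort.hydraulics import ul_min_to_si
from spiralsort.inertial import force_ratio
from spiralsort.io import FixtureSpec, generate_fixture

SIZES_UM = (6, 8, 10, 12, 16, 20)


def predict(dev, a_um, cond=None):
    return equilibrium_distance(
        ParticleSpec.from_um(a_um), cond or dev.design_flow, dev.cross_section,
        dev.spiral, dev.lift_model, k=dev.calibration_k, fluid=dev.fluid,
    )


class TestEquilibriumDistance:
    def test_size_ordering_at_wb1_working_point(self, wb1):
        d = {a: predict(wb1, a).distance for a in (6, 8, 10, 12, 20)}
        assert d[20] < d[12] < d[10] < d[8] < d[6]

    def test_size_monotone_across_range_on_both_devices(self, wb1, wb1r):
        for dev in (wb1, wb1r):
            focused = [predict(dev, a) for a in SIZES_UM]
            dists = [p.distance for p in focused if p.focused]
            assert all(b < a for a, b in zip(dists, dists[1:]))

    def test_straight_channel_limit_recovers_lift_only_offset(self, wb1):
        # a near-infinite curvature radius kills the Dean drag
        straight = SpiralGeometry(loop_radii=(1e6,), total_length=0.334)
        pred = equilibrium_distance(
            ParticleSpec.from_um(10), wb1.design_flow, wb1.cross_section,
            straight, wb1.lift_model, k=wb1.calibration_k,
        )
        x_eq = DEFAULT_EQUILIBRIUM_OFFSET_FRACTION * wb1.cross_section.width
        assert pred.distance == pytest.approx(x_eq, abs=0.5 * UM)

    def test_root_matches_dense_grid_sign_scan(self, wb1):
        # brute-force oracle: first sign change over 1e5 uniform points
        p = ParticleSpec.from_um(10)
        fb = force_ratio(p, wb1.design_flow, wb1.spiral, wb1.cross_section,
                         wb1.lift_model, k=wb1.calibration_k)
        w = wb1.cross_section.width
        x_eq = DEFAULT_EQUILIBRIUM_OFFSET_FRACTION * w
        xs = np.linspace(p.diameter / 2, w - p.diameter / 2, 100_000)
        f = net_lateral_force(xs, fb.lift, fb.drag, fb.k, w, x_eq)
        flip = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0][0]
        step = xs[1] - xs[0]
        assert abs(predict(wb1, 10).distance - xs[flip]) <= step

    def test_below_confinement_flagged_unfocused(self, wb1):
        pred = predict(wb1, 4)
        assert not pred.focused
        assert np.isnan(pred.distance)

    def test_continuous_in_flow_over_working_range(self, wb1):
        # dense sweep: no root-jumping between neighbouring flows
        flows = np.linspace(500, 1500, 101)
        d = np.array(
            [
                predict(wb1, 9, FlowCondition.from_flow_ul_min(q)).distance
                for q in flows
            ]
        )
        steps = np.abs(np.diff(d))
        assert steps.max() < 2 * UM
        assert np.all(np.diff(d) > 0)  # monotone outward with increasing flow


class TestFocusingLength:
    def test_wb1_cutoff_focuses_within_device(self, wb1):
        lf = focusing_length(
            ParticleSpec.from_um(9), wb1.design_flow, wb1.cross_section,
            wb1.lift_model,
        )
        assert lf == pytest.approx(49e-3, rel=0.02)
        assert lf <= wb1.spiral.total_length

    def test_inverse_in_momentum_at_pinned_lift_coefficient(self, wb1):
        p = ParticleSpec.from_um(9)
        lf1 = focusing_length(p, FlowCondition.from_flow_ul_min(860),
                              wb1.cross_section, wb1.lift_model,
                              pinned_lift_coefficient=0.0102)
        lf2 = focusing_length(p, FlowCondition.from_flow_ul_min(1720),
                              wb1.cross_section, wb1.lift_model,
                              pinned_lift_coefficient=0.0102)
        assert lf2 == pytest.approx(lf1 / 2, rel=1e-12)

    def test_geometric_model_length_invariant_in_flow(self, wb1):
        # the geometric C_L ~ 1/Re cancels the U_m in the denominator exactly
        p = ParticleSpec.from_um(9)
        lf1 = focusing_length(p, FlowCondition.from_flow_ul_min(860),
                              wb1.cross_section, wb1.lift_model)
        lf2 = focusing_length(p, FlowCondition.from_flow_ul_min(1720),
                              wb1.cross_section, wb1.lift_model)
        assert lf2 == pytest.approx(lf1, rel=1e-12)

    def test_monotone_decreasing_in_size_under_geometric_model(self, wb1):
        lfs = [
            focusing_length(ParticleSpec.from_um(a), wb1.design_flow,
                            wb1.cross_section, wb1.lift_model)
            for a in SIZES_UM
        ]
        assert all(b < a for a, b in zip(lfs, lfs[1:]))


class TestNormalizedError:
    def test_zero_iff_equal(self):
        assert normalized_error(12.0, 12.0) == 0.0
        assert normalized_error(1.5, 1.0) == pytest.approx(0.5)

    def test_vectorized_matches_scalar_loop(self):
        sim = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        exp = np.array([11.0, 19.0, 33.0, 40.0, 45.0])
        vec = normalized_error(sim, exp)
        loop = [normalized_error(s, e) for s, e in zip(sim, exp)]
        assert vec == pytest.approx(loop)

    def test_zero_measurement_rejected(self):
        with pytest.raises(ValueError):
            normalized_error(1.0, 0.0)


def _measurements_from_fixture(dev, **kwargs):
    df, _ = generate_fixture(FixtureSpec(**kwargs), dev)
    return df, [
        StreamlineMeasurement(r.size_um * UM, r.pressure_mbar * 100,
                              r.dist_mean_um * UM, r.dist_sd_um * UM)
        for r in df.itertuples()
    ]


ALL_MODELS = [
    LiftModel.from_name(n)
    for n in ("dimensionless_geometric", "exp_fit_a", "exp_fit_b")
]


class TestModelComparison:
    @pytest.mark.parametrize("generating", ["dimensionless_geometric", "exp_fit_a"])
    def test_recovers_generating_model_with_zero_error(self, wb1, generating):
        _, ms = _measurements_from_fixture(
            wb1, seed=3, noise_um=0.0,
            pressures_mbar=(2000.0, 2800.0, 3600.0), model=generating,
        )
        table = model_comparison(ms, wb1, ALL_MODELS)
        mean_err = table.groupby("model")["error"].mean()
        assert mean_err[generating] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[table["model"] == generating, "rank"].iloc[0] == 1
        others = mean_err.drop(generating)
        assert (others > 1e-4).all()

    def test_multiplicative_perturbation_error_band(self, wb1):
        # d_exp = 1.1 * d_sim => |d - 1.1 d| / 1.1 d = 1/11 for every row
        _, ms = _measurements_from_fixture(
            wb1, seed=3, noise_um=0.0, pressures_mbar=(2800.0,)
        )
        perturbed = [
            StreamlineMeasurement(m.size, m.pressure, 1.1 * m.mean_distance, m.sd)
            for m in ms
        ]
        table = model_comparison(
            perturbed, wb1, [LiftModel.from_name("dimensionless_geometric")]
        )
        assert table["error"].to_numpy() == pytest.approx(
            np.full(len(table), 1 / 11), rel=1e-9
        )

    def test_emits_models_times_sizes_rows(self, wb1):
        _, ms = _measurements_from_fixture(
            wb1, seed=3, noise_um=0.0, pressures_mbar=(2800.0,)
        )
        table = model_comparison(ms, wb1, ALL_MODELS)
        assert len(table) == len(ALL_MODELS) * len(ms)
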