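import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shearclot.kinetics import (
    RateFunction,
    adp_activation_rate,
    binding_affinity_g,
    default_params,
    evaluate_rate,
    hindrance_W,
    reaction_rhs,
)

RATE_CASES = [
    # (form kwargs, gamma, expected as function of (a, b))
    (dict(form="linear"), 300.0, lambda a, b: a),
    (dict(form="linear"), 1500.0, lambda a, b: b),
    (dict(form="linear"), 900.0, lambda a, b: a + 0.5 * (b - a)),
    (dict(form="piecewise_linear", truncation_shear=10000.0), 12000.0,
     lambda a, b: a + 9700.0 / 1200.0 * (b - a)),
    (dict(form="piecewise_linear", truncation_shear=2000.0), 5000.0,
     lambda a, b: a + 1700.0 / 1200.0 * (b - a)),
    (dict(form="constant"), 5000.0, lambda a, b: a),
]


class TestEvaluateRate:
    @pytest.mark.parametrize("kwargs,gamma,expected", RATE_CASES)
    def test_printed_values(self, kwargs, gamma, expected):
        a, b = 0.7, 2.9
        rf = RateFunction(a=a, b=b, **kwargs)
        assert evaluate_rate(rf, gamma) == pytest.approx(expected(a, b), rel=1e-12)

    @pytest.mark.parametrize("form", ["linear", "piecewise_linear",
                                      "tanh_saturating",
                                      "exponential_saturating"])
    def test_anchors_at_calibration_shears(self, form):
        rf = RateFunction(form=form, a=0.31, b=1.7)
        assert evaluate_rate(rf, 300.0) == pytest.approx(0.31, rel=1e-12)
        assert evaluate_rate(rf, 1500.0) == pytest.approx(1.7, rel=1e-12)

    @pytest.mark.parametrize("form", ["linear", "piecewise_linear",
                                      "tanh_saturating",
                                      "exponential_saturating", "constant"])
    def test_continuity(self, form):
        rf = RateFunction(form=form, a=0.5, b=2.0)
        g = np.linspace(0.0, 15000.0, 40001)
        v = evaluate_rate(rf, g)
        jumps = np.abs(np.diff(v))
        # a continuous function has increments vanishing with the grid step
        assert jumps.max() < 5e-3 * (np.abs(v).max() + 1)

    def test_saturating_forms_flat_beyond_saturation(self):
        tanh_rf = RateFunction(form="tanh_saturating", a=0.5, b=2.0)
        v1 = evaluate_rate(tanh_rf, 8000.0)
        v2 = evaluate_rate(tanh_rf, 20000.0)
        assert v2 == pytest.approx(v1, rel=1e-12)
        pw = RateFunction(form="piecewise_linear", a=0.5, b=2.0,
                          truncation_shear=5000.0)
        assert evaluate_rate(pw, 5000.0) == pytest.approx(
            evaluate_rate(pw, 50000.0), rel=1e-12)

    def test_off_rate_family_ordering(self):
        """For b > a on (2000, 8000): trunc2000 <= trunc5000 <= trunc8000 <= linear."""
        a, b = 0.5, 2.0
        forms = [RateFunction(form="piecewise_linear", a=a, b=b,
                              truncation_shear=t) for t in (2000, 5000, 8000)]
        lin = RateFunction(form="linear", a=a, b=b)
        g = np.linspace(2000.0, 8000.0, 101)
        vals = [evaluate_rate(rf, g) for rf in forms] + [evaluate_rate(lin, g)]
        for lo, hi in zip(vals[:-1], vals[1:]):
            assert np.all(lo <= hi + 1e-14)

    def test_exponential_off_below_trunc8000(self):
        a, b = 0.5, 2.0
        expf = RateFunction(form="exponential_saturating", a=a, b=b, shape=1.0)
        trunc = RateFunction(form="piecewise_linear", a=a, b=b,
                             truncation_shear=8000.0)
        g = np.linspace(2100.0, 20000.0, 200)
        assert np.all(evaluate_rate(expf, g) < evaluate_rate(trunc, g) + 1e-14)

    def test_negative_shear_errors(self):
        with pytest.raises(ValueError):
            evaluate_rate(RateFunction(a=1, b=2), -1.0)

    def test_activation_threshold_floor(self):
        rf = RateFunction(form="linear", a=0.1, b=1.0, activation_threshold=500.0)
        assert evaluate_rate(rf, 300.0) == 0.0
        assert evaluate_rate(rf, 600.0) > 0.0


class TestBindingAffinity:
    @pytest.mark.parametrize("eta_t,eta_star", [(0.2, 0.5), (0.0, 0.3),
                                                (0.5, 1.0), (0.2, 0.3)])
    def test_normalization_g_of_one(self, eta_t, eta_star):
        assert binding_affinity_g(1.0, eta_t, eta_star) == pytest.approx(1.0, abs=1e-14)

    def test_zero_at_and_below_threshold(self):
        assert binding_affinity_g(0.2, 0.2, 0.5) == 0.0
        assert binding_affinity_g(0.1, 0.2, 0.5) == 0.0
        assert binding_affinity_g(0.0, 0.2, 0.5) == 0.0

    @given(st.floats(0.0, 0.9), st.floats(0.05, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing(self, eta_t, eta_star):
        eta = np.linspace(0, 1, 201)
        g = binding_affinity_g(eta, eta_t, eta_star)
        assert np.all(np.diff(g) >= -1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            binding_affinity_g(0.5, 1.0, 0.5)
        with pytest.raises(ValueError):
            binding_affinity_g(0.5, 0.2, 0.0)


class TestHindrance:
    def test_values(self):
        assert hindrance_W(1.0) == pytest.approx(0.0, abs=1e-14)
        assert hindrance_W(0.0) == pytest.approx(np.tanh(np.pi), rel=1e-12)
        assert hindrance_W(0.5) == pytest.approx(np.tanh(np.pi / 2), rel=1e-12)

    def test_strictly_decreasing_and_clamped(self):
        t = np.linspace(0, 1, 101)
        w = hindrance_W(t)
        assert np.all(np.diff(w) < 0)
        assert hindrance_W(1.3) == 0.0


class TestADPActivation:
    def test_zero_and_saturation(self, params):
        assert adp_activation_rate(0.0, params) == 0.0
        assert adp_activation_rate(1e9, params) == pytest.approx(
            params.adp_act_rate, rel=1e-6)

    def test_half_maximum_at_threshold(self, params):
        v = adp_activation_rate(params.adp_act_threshold, params)
        assert v == pytest.approx(0.5 * params.adp_act_rate, rel=1e-9)

    def test_nondecreasing(self, params):
        c = np.linspace(0, 20, 500)
        v = adp_activation_rate(c, params)
        assert np.all(np.diff(v) >= 0)


class TestReactionNetwork:
    def test_all_zero_state_gives_zero_rhs(self, params):
        from shearclot.kinetics import PlateletFields

        f = PlateletFields.zeros(10, params.P_max)
        d = reaction_rhs(f, np.full(10, 300.0), np.zeros(10), np.zeros(10),
                         np.ones(10), params)
        for v in d.values():
            assert np.all(v == 0.0)

    def test_platelet_conservation_over_random_states(self, params, random_state):
        """Reaction terms over the seven species sum to zero pointwise."""
        rng = np.random.default_rng(7)
        f = random_state(10000)
        gam = rng.uniform(0, 9000, 10000)
        eU = rng.uniform(0, 1, 10000)
        eA = rng.uniform(0, 1, 10000)
        H = rng.integers(0, 2, 10000).astype(float)
        d = reaction_rhs(f, gam, eU, eA, H, params)
        total = sum(d[n] for n in
                    ("P_mu", "P_ma", "P_bvu", "P_bva", "P_bfa", "P_seu", "P_sea"))
        scale = max(np.abs(d[n]).max() for n in d)
        assert np.abs(total).max() <= 1e-12 * max(scale, 1.0)

    def test_negative_density_rejected(self, params):
        from shearclot.kinetics import PlateletFields

        f = PlateletFields.zeros(4, params.P_max)
        f.P_mu[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            reaction_rhs(f, np.zeros(4), np.zeros(4), np.zeros(4),
                         np.zeros(4), params)

    def test_nan_rejected(self, params):
        from shearclot.kinetics import PlateletFields

        f = PlateletFields.zeros(4, params.P_max)
        f.ADP[1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            reaction_rhs(f, np.zeros(4), np.zeros(4), np.zeros(4),
                         np.zeros(4), params)

    def test_pure_unbinding_decay(self, params):
        """With no adhesion surface, no cohesion neighborhood and no ADP, bound
        vWF species decay back to the mobile pools at their off-rates."""
        from dataclasses import replace

        from shearclot.kinetics import PlateletFields

        p = replace(params, k_act_col=0.0,
                    k_act_vwf=RateFunction("constant", a=0.0, b=0.0))
        f = PlateletFields.zeros(1, p.P_max)
        f.P_bvu[:] = 1000.0
        gam = np.array([300.0])
        d = reaction_rhs(f, gam, np.zeros(1), np.zeros(1), np.zeros(1), p)
        koff = evaluate_rate(p.k_coh_vwf_off, 300.0)
        assert d["P_bvu"][0] == pytest.approx(-koff * 1000.0, rel=1e-12)
        assert d["P_mu"][0] == pytest.approx(koff * 1000.0, rel=1e-12)

    def test_theta_identities(self, random_state):
        f = random_state(100)
        assert np.allclose(f.theta_U + f.theta_A, f.theta_B, rtol=1e-12)
        assert np.all(f.theta_B <= f.theta_T + 1e-15)


class TestRateFunctionSerialization:
    def test_round_trip(self):
        rf = RateFunction("tanh_saturating", a=1.25e-9, b=7.5e-9,
                          transition_start=2000, transition_end=8000, shape=3.0)
        assert RateFunction.from_dict(rf.to_dict()) == rf
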