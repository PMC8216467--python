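"""Normalization, integrated rate laws, rate fitting and derived summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import strandkinetics as sk
from strandkinetics.traces import FluorescenceTrace, NormalizedTrace

from conftest import K_GRID, replicate_fit, simulate_normalized


def _trace(times, values, role, label=""):
    return FluorescenceTrace(np.asarray(times, float), np.asarray(values, float),
                             role=role, label=label)


class TestNormalization:
    times = np.arange(0.0, 100.0, 10.0)

    def _controls(self, fc=300.0, f0=100.0):
        n = self.times.size
        return (_trace(self.times, np.full(n, fc), "pre_activated"),
                _trace(self.times, np.full(n, f0), "negative"))

    def test_quenched_baseline_maps_to_zero(self):
        fc, f0 = self._controls()
        rxn = _trace(self.times, f0.values.copy(), "reaction")
        nt = sk.normalize_trace(rxn, fc, f0)
        np.testing.assert_allclose(nt.fn, 0.0, atol=1e-12)

    def test_fully_activated_maps_to_one(self):
        fc, f0 = self._controls()
        rxn = _trace(self.times, fc.values.copy(), "reaction")
        nt = sk.normalize_trace(rxn, fc, f0)
        np.testing.assert_allclose(nt.fn, 1.0, atol=1e-12)

    def test_gain_invariance(self):
        """Multiplying every raw trace by a common gain leaves fn unchanged."""
        fc, f0 = self._controls()
        raw = f0.values + 0.37 * (fc.values - f0.values)
        nt1 = sk.normalize_trace(_trace(self.times, raw, "reaction"), fc, f0)
        g = 7.3
        nt2 = sk.normalize_trace(
            _trace(self.times, g * raw, "reaction"),
            _trace(self.times, g * fc.values, "pre_activated"),
            _trace(self.times, g * f0.values, "negative"))
        np.testing.assert_allclose(nt2.fn, nt1.fn, rtol=1e-12)

    def test_mismatched_grid_rejected(self):
        fc, f0 = self._controls()
        rxn = _trace(self.times + 5.0, np.full(self.times.size, 200.0), "reaction",
                     label="offgrid")
        with pytest.raises(ValueError, match="offgrid"):
            sk.normalize_trace(rxn, fc, f0)

    def test_degenerate_controls_flagged(self):
        """Points where Fc - F0 collapses are masked, not divided through."""
        fc, f0 = self._controls()
        fc_vals = fc.values.copy()
        fc_vals[3] = f0.values[3]  # zero denominator at one time point
        nt = sk.normalize_trace(
            _trace(self.times, f0.values + 50.0, "reaction"),
            _trace(self.times, fc_vals, "pre_activated"), f0)
        assert not nt.mask[3] and nt.mask.sum() == self.times.size - 1


class TestRateLaws:
    def test_lhs_zero_at_zero_conversion(self):
        assert sk.eq2_lhs(np.array([0.0]), 1.5e-7, 1e-7)[0] == 0.0

    def test_lhs_at_derived_conversion(self):
        """At the closed-form conversion for kt(ai0-in0) = -0.5 the
        linearized LHS equals exactly that exponent."""
        out = sk.closed_form_conversion(np.array([1000.0]), 1e4, 1.5e-7, 1e-7) * 1e-7
        assert abs(sk.eq2_lhs(out, 1.5e-7, 1e-7)[0] - (-0.5)) < 1e-9

    def test_lhs_singular_at_completion(self):
        with pytest.raises(ValueError, match="singular"):
            sk.eq2_lhs(np.array([1e-7]), 1.5e-7, 1e-7)

    def test_closed_form_boundary_values(self, regime_a):
        t = np.array([0.0, 1e9])
        fn = sk.closed_form_conversion(t, 1e4, regime_a.in0, regime_a.ai0)
        assert fn[0] == 0.0
        assert abs(fn[1] - 1.0) < 1e-12  # excess input completes the reaction

    @pytest.mark.parametrize("k", K_GRID)
    @pytest.mark.parametrize("regime", ["a", "b"])
    def test_algebraic_identity_eq2_eq3(self, k, regime, regime_a, regime_b):
        """Substituting the closed form into the linearized LHS returns
        (ai0 - in0) k t to 1e-10 relative, away from the saturation cap."""
        cond = regime_a if regime == "a" else regime_b
        t = np.linspace(0.0, 1e4, 257)
        fn = sk.closed_form_conversion(t, k, cond.in0, cond.ai0)
        keep = (fn <= 0.95) & (t > 0)
        lhs = sk.eq2_lhs(fn[keep] * cond.ai0, cond.in0, cond.ai0)
        rhs = (cond.ai0 - cond.in0) * k * t[keep]
        assert np.max(np.abs(lhs - rhs) / np.abs(rhs)) < 1e-10

    @pytest.mark.parametrize("k", K_GRID)
    def test_closed_form_matches_runge_kutta(self, k, regime_a):
        t = np.linspace(0.0, 1e4, 200)
        ode = sk.integrate_single_step(k, regime_a.in0, regime_a.ai0, t)
        cf = sk.closed_form_conversion(t, k, regime_a.in0, regime_a.ai0) * regime_a.ai0
        err = np.abs(ode - cf) / np.maximum(np.abs(cf), 1e-6 * regime_a.ai0)
        assert np.max(err) < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(log10k=st.floats(2.0, 6.0), tmax=st.floats(10.0, 1e4))
    def test_identity_property(self, log10k, tmax):
        k = 10.0 ** log10k
        in0, ai0 = 1.5e-7, 1.0e-7
        t = np.linspace(0, tmax, 33)[1:]
        fn = sk.closed_form_conversion(t, k, in0, ai0)
        keep = fn <= 0.95
        if keep.sum() == 0:
            return
        lhs = sk.eq2_lhs(fn[keep] * ai0, in0, ai0)
        rhs = (ai0 - in0) * k * t[keep]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(log10k=st.floats(2.0, 6.0))
    def test_conversion_monotone_and_bounded(self, log10k):
        k = 10.0 ** log10k
        t = np.linspace(0, 1e4, 100)
        fn = sk.closed_form_conversion(t, k, 1.5e-7, 1.0e-7)
        assert np.all(np.diff(fn) >= -1e-15)
        assert np.all((fn >= 0) & (fn <= 1))


class TestRateFitting:
    def test_linearized_recovers_noiseless_slow_rate(self, regime_a):
        trace, _, _ = simulate_normalized(1e2, regime_a)
        res = sk.fit_rate_linearized(trace, regime_a)
        assert res.success and abs(res.k - 1e2) / 1e2 < 1e-3
        assert res.method == "linearized_eq2"

    def test_flat_trace_is_failed_fit(self, regime_a):
        t = np.linspace(0, 1000, 50)
        trace = NormalizedTrace(t, np.zeros_like(t), conditions=regime_a)
        res = sk.fit_rate_linearized(trace, regime_a)
        assert not res.success and np.isnan(res.k)

    def test_closed_form_recovers_noiseless_fast_rate(self, regime_b):
        trace, _, _ = simulate_normalized(1e5, regime_b)
        res = sk.fit_rate_closed_form(trace, regime_b)
        assert res.success and abs(res.k - 1e5) / 1e5 < 1e-3
        assert res.method == "closed_form_eq3"

    def test_regime_selection_routes_by_completion(self, regime_a):
        slow, _, _ = simulate_normalized(1e2, regime_a)   # ends well below 0.5
        fast, _, _ = simulate_normalized(1e5, regime_a)   # runs to completion
        assert sk.select_and_fit(slow, regime_a).method == "linearized_eq2"
        assert sk.select_and_fit(fast, regime_a).method == "closed_form_eq3"

    def test_both_fitters_agree_on_noiseless_data(self, regime_a):
        trace, _, _ = simulate_normalized(1e3, regime_a)
        k_lin = sk.fit_rate_linearized(trace, regime_a).k
        k_cf = sk.fit_rate_closed_form(trace, regime_a).k
        assert abs(k_lin - k_cf) / k_cf < 0.01

    def test_noisy_replicates_recover_within_ten_percent(self, regime_a):
        res = replicate_fit(1e3, regime_a, seed=11)
        assert res.success and len(res.replicate_ks) == 3
        assert abs(res.replicate_mean - 1e3) / 1e3 < 0.10
        assert res.replicate_sd is not None

    def test_fitted_k_invariant_under_gain_rescaling(self, regime_a):
        """Scaling all raw wells by a common factor leaves k unchanged."""
        _, wells, spec = simulate_normalized(1e4, regime_a, noise_sd=0.01, seed=3)
        def fit(scale):
            scaled = {
                r: FluorescenceTrace(w.times, w.values * scale, role=w.role)
                for r, w in wells.items()}
            nt = sk.normalize_trace(scaled["reaction"], scaled["pre_activated"],
                                    scaled["negative"], conditions=regime_a)
            return sk.select_and_fit(nt, regime_a).k
        assert fit(1.0) == pytest.approx(fit(13.7), rel=1e-9)

    def test_fn_cap_exclusion_enforced(self, regime_a):
        """No point above the cap ever enters a linearized fit."""
        trace, _, _ = simulate_normalized(1e5, regime_a)  # saturating trace
        est = sk.SecondOrderRateFit(in0=regime_a.in0, ai0=regime_a.ai0,
                                    method="linearized")
        est.fit(trace.times, trace.fn)
        n_below_cap = int(np.sum(trace.fn <= est.fn_cap))
        assert est.n_points_used_ <= n_below_cap

    def test_equal_concentration_fallback(self):
        """in0 == ai0 is singular for both standard routes; the
        equal-concentration integrated law takes over."""
        cond = sk.ReactionConditions(in0=1e-7, ai0=1e-7, r0=3e-7)
        t = np.linspace(0, 5e3, 200)
        k = 1e4
        x = cond.ai0 * k * t
        fn = x / (1 + x)
        trace = NormalizedTrace(t, fn, conditions=cond)
        res = sk.select_and_fit(trace, cond)
        assert res.method == "equal_conc"
        assert abs(res.k - k) / k < 1e-6

    def test_estimator_sklearn_contract(self, regime_a):
        est = sk.SecondOrderRateFit(in0=regime_a.in0, ai0=regime_a.ai0)
        cloned = clone(est)
        assert cloned.get_params()["in0"] == regime_a.in0
        trace, _, _ = simulate_normalized(1e4, regime_a)
        cloned.fit(trace.times, trace.fn)
        pred = cloned.predict(trace.times)
        assert np.max(np.abs(pred - trace.fn)) < 0.01


class TestDerivedSummaries:
    @staticmethod
    def _fit(k, sd=None, reps=(None,)):
        ks = tuple(k for _ in reps)
        return sk.RateFitResult(k=k, method="closed_form_eq3", r_squared=1.0,
                                n_points_used=100, success=True, replicate_ks=ks,
                                replicate_mean=k, replicate_sd=sd)

    def test_discrimination_arithmetic(self):
        res = sk.discrimination_factor(self._fit(2e4, sd=0.0), self._fit(1e3, sd=0.0))
        assert res.df == pytest.approx(20.0)
        assert res.df_sd == pytest.approx(0.0)
        assert not res.is_bound

    def test_identical_rates_give_unity(self):
        res = sk.discrimination_factor(self._fit(5e3), self._fit(5e3))
        assert res.df == pytest.approx(1.0)

    def test_unresolvable_mismatch_reported_as_bound(self):
        failed = sk.RateFitResult(k=float("nan"), method="linearized_eq2",
                                  r_squared=0.0, n_points_used=10, success=False)
        res = sk.discrimination_factor(self._fit(2e4), failed, k_floor=10.0)
        assert res.is_bound and res.df == pytest.approx(2e3)
        assert str(res).startswith("DF > ")

    def test_error_propagation_first_order(self):
        m = self._fit(2e4, sd=2e3)
        mm = self._fit(1e3, sd=50.0)
        res = sk.discrimination_factor(m, mm)
        expected = 20.0 * np.sqrt((2e3 / 2e4) ** 2 + (50 / 1e3) ** 2)
        assert res.df_sd == pytest.approx(expected)

    def test_df_round_trip_on_simulated_pair(self, regime_a):
        """A 29.4-fold rate contrast (toehold-mismatch setting) survives
        the simulate -> normalize -> fit -> ratio pipeline within 15%."""
        ratio_true = 29.4
        match = replicate_fit(2e4, regime_a, seed=21)
        mism = replicate_fit(2e4 / ratio_true, regime_a, seed=22)
        res = sk.discrimination_factor(match, mism)
        assert not res.is_bound
        assert abs(res.df - ratio_true) / ratio_true < 0.15

    def test_rate_ratio_arithmetic(self):
        res = sk.rate_ratio(self._fit(2.5e4), self._fit(1e4))
        assert res.ratio == pytest.approx(2.5)
        assert sk.rate_ratio(self._fit(1e4), self._fit(1e4)).ratio == pytest.approx(1.0)

    def test_rate_ratio_round_trip(self, regime_b):
        num = replicate_fit(2e4, regime_b, seed=31)
        den = replicate_fit(1e4, regime_b, seed=32)
        res = sk.rate_ratio(num, den)
        assert abs(res.ratio - 2.0) / 2.0 < 0.15

    def test_toehold_regression_exact(self):
        lengths = np.array([2, 4, 6, 8, 10])
        ks = 10.0 ** (2.0 + 0.4 * lengths)
        series = sk.fit_toehold_dependence(lengths, ks)
        assert series.slope == pytest.approx(0.4, abs=1e-12)
        assert series.intercept == pytest.approx(2.0, abs=1e-12)
        assert series.fold_per_nt == pytest.approx(10 ** 0.4)
        assert series.r_squared == pytest.approx(1.0)

    def test_toehold_regression_flat(self):
        series = sk.fit_toehold_dependence([2, 4, 6], [1e4, 1e4, 1e4])
        assert series.slope == pytest.approx(0.0, abs=1e-12)

    def test_toehold_regression_rejects_bad_input(self):
        with pytest.raises(ValueError, match="non-positive"):
            sk.fit_toehold_dependence([2, 4, 6], [1e4, -1.0, 1e4])
        with pytest.raises(ValueError, match="distinct"):
            sk.fit_toehold_dependence([2, 2, 6], [1e4, 1e4, 1e4])
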