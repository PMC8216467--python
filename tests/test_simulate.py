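"""Synthetic-data generator: mass-action kinetics, controls, two-state melting."""

import numpy as np
import pytest

import strandkinetics as sk
from strandkinetics.traces import ReactionConditions

from conftest import simulate_normalized


class TestDisplacementWells:
    @pytest.mark.parametrize("k,k_rep", [(1e3, 1e6), (1e5, 1e8), (1e5, 1e5)])
    def test_mass_conservation(self, regime_a, k, k_rep):
        """Gate + free incumbent + triggered reporter always sum to ai0."""
        spec = sk.TraceSimulationSpec(k_displacement=k, k_reporter=k_rep,
                                      conditions=regime_a, duration=2000.0,
                                      sampling_interval=5.0, noise_sd=0.0)
        _, ai, out, f = sk.integrate_displacement(spec)
        total = ai + out + f
        assert np.all(np.abs(total - regime_a.ai0) <= 1e-9 * regime_a.ai0)

    def test_complete_displacement_endpoint(self, regime_a):
        """Excess input + instant reporter drives normalized signal to 1."""
        spec = sk.TraceSimulationSpec(k_displacement=1e5, k_reporter=1e9,
                                      conditions=regime_a, duration=2e4,
                                      sampling_interval=50.0, noise_sd=0.0)
        wells = sk.simulate_displacement_wells(spec)
        fn_end = ((wells["reaction"].values[-1] - spec.baseline)
                  / (spec.gain * regime_a.ai0))
        assert abs(fn_end - 1.0) < 1e-3

    def test_no_input_stays_at_baseline(self, regime_a):
        """Without input the reaction well is indistinguishable from the negative."""
        cond = ReactionConditions(in0=0.0, ai0=regime_a.ai0, r0=regime_a.r0)
        spec = sk.TraceSimulationSpec(k_displacement=1e5, conditions=cond,
                                      duration=1000.0, sampling_interval=10.0,
                                      noise_sd=0.0)
        wells = sk.simulate_displacement_wells(spec)
        np.testing.assert_array_equal(wells["reaction"].values,
                                      wells["negative"].values)
        assert np.all(wells["negative"].values == spec.baseline)

    def test_seeded_runs_bit_reproducible(self, regime_a):
        spec = sk.TraceSimulationSpec(k_displacement=1e4, conditions=regime_a,
                                      duration=1000.0, sampling_interval=10.0,
                                      noise_sd=0.01, seed=42)
        w1 = sk.simulate_displacement_wells(spec)
        w2 = sk.simulate_displacement_wells(spec)
        for role in w1:
            np.testing.assert_array_equal(w1[role].values, w2[role].values)
        w3 = sk.simulate_displacement_wells(
            sk.TraceSimulationSpec(k_displacement=1e4, conditions=regime_a,
                                   duration=1000.0, sampling_interval=10.0,
                                   noise_sd=0.01, seed=43))
        assert not np.array_equal(w1["reaction"].values, w3["reaction"].values)

    def test_noise_independent_across_wells(self, regime_a):
        spec = sk.TraceSimulationSpec(k_displacement=1e4, conditions=regime_a,
                                      duration=1000.0, sampling_interval=10.0,
                                      noise_sd=0.01, seed=7)
        w = sk.simulate_displacement_wells(spec)
        assert not np.array_equal(w["negative"].values, w["background"].values)

    def test_fast_reporter_matches_single_step_law(self, regime_a):
        """With the reporter >=1000x faster, the trace follows the one-step
        closed form within 1% of ai0 — the premise of single-step fitting."""
        trace, _, _ = simulate_normalized(1e4, regime_a, k_reporter=1e7)
        expected = sk.closed_form_conversion(trace.times, 1e4,
                                             regime_a.in0, regime_a.ai0)
        assert np.max(np.abs(trace.fn - expected)) < 0.01

    def test_slow_reporter_lags_single_step_law(self, regime_a):
        """A reporter comparable to displacement delays the signal, biasing
        the apparent rate downward."""
        trace, _, _ = simulate_normalized(1e4, regime_a, k_reporter=1e4)
        expected = sk.closed_form_conversion(trace.times, 1e4,
                                             regime_a.in0, regime_a.ai0)
        assert np.all(trace.fn <= expected + 1e-9)
        assert np.max(expected - trace.fn) > 0.05

    def test_invalid_specs_rejected(self, regime_a):
        with pytest.raises(ValueError, match="reporter"):
            sk.TraceSimulationSpec(
                k_displacement=1e4,
                conditions=ReactionConditions(in0=1.5e-7, ai0=1e-7, r0=5e-8),
                duration=100.0, sampling_interval=1.0)
        with pytest.raises(ValueError, match="noise_sd"):
            sk.TraceSimulationSpec(k_displacement=1e4, conditions=regime_a,
                                   duration=100.0, sampling_interval=1.0,
                                   noise_sd=-0.1)


class TestEquilibriumFractionBound:
    def test_saturation_limits(self):
        assert sk.equilibrium_fraction_bound(-60, -0.160, 2e-6, 0.0) > 0.999
        assert sk.equilibrium_fraction_bound(-60, -0.160, 2e-6, 95.0) < 1e-3

    def test_monotone_decreasing_in_temperature(self):
        temps = np.linspace(5, 90, 60)
        theta = [sk.equilibrium_fraction_bound(-60, -0.160, 2e-6, t) for t in temps]
        assert np.all(np.diff(theta) < 0)

    def test_midpoint_matches_vant_hoff_closed_form(self):
        """Bisection on theta = 1/2 agrees with the closed-form Tm (n = 2)
        to 0.01 K: the generator and regression share one model."""
        t_half = sk.two_state_tm_bisection(-60, -0.160, 2e-6)
        t_closed = sk.tm_two_state(-60, -0.160, 2e-6)
        assert abs(t_half - t_closed) < 0.01
        # frozen oracle value: 317.75 K
        assert abs((t_half + 273.15) - 317.748) < 0.01

    def test_rejects_endothermic(self):
        with pytest.raises(ValueError):
            sk.equilibrium_fraction_bound(+10, -0.1, 1e-6, 37.0)


class TestMeltWells:
    def test_total_quench_no_drift_gives_one_minus_theta(self):
        spec = sk.MeltSimulationSpec(dH=-60, dS=-0.160, ct_values=(2e-6,),
                                     quench_efficiency=1.0, drift_slope=0.0,
                                     noise_sd=0.0)
        curve = sk.simulate_melt_wells(spec)[2e-6]
        f_corr = sk.correct_melt(curve).f_corr
        theta = np.array([sk.equilibrium_fraction_bound(-60, -0.160, 2e-6, t)
                          for t in curve.temps])
        np.testing.assert_allclose(f_corr, 1 - theta, atol=1e-10)

    def test_ratio_correction_cancels_drift(self):
        """The corrected profile is identical with and without a free-dye
        temperature drift: the positive-control division removes it."""
        kw = dict(dH=-60, dS=-0.160, ct_values=(2e-6,), noise_sd=0.0)
        flat = sk.correct_melt(sk.simulate_melt_wells(
            sk.MeltSimulationSpec(drift_slope=0.0, **kw))[2e-6]).f_corr
        drift = sk.correct_melt(sk.simulate_melt_wells(
            sk.MeltSimulationSpec(drift_slope=0.02, **kw))[2e-6]).f_corr
        np.testing.assert_allclose(drift, flat, atol=1e-10)

    def test_tm_increases_with_concentration(self):
        """Bimolecular transitions shift up with total strand concentration."""
        spec = sk.MeltSimulationSpec(dH=-60, dS=-0.160, noise_sd=0.0)
        curves = sk.simulate_melt_wells(spec)
        tms = [sk.estimate_tm(sk.correct_melt(curves[ct]), smooth=False).tm
               for ct in sorted(curves)]
        assert np.all(np.diff(tms) > 0)

    def test_warns_when_transition_not_bracketed(self):
        with pytest.warns(UserWarning, match="not bracketed"):
            sk.simulate_melt_wells(
                sk.MeltSimulationSpec(dH=-60, dS=-0.160, ct_values=(2e-6,),
                                      t_max=30.0, noise_sd=0.0))

    def test_seeded_melts_reproducible(self):
        spec = sk.MeltSimulationSpec(dH=-60, dS=-0.160, ct_values=(1e-6, 2e-6),
                                     noise_sd=0.01, seed=5)
        c1 = sk.simulate_melt_wells(spec)
        c2 = sk.simulate_melt_wells(spec)
        for ct in c1:
            np.testing.assert_array_equal(c1[ct].f_melt, c2[ct].f_melt)
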