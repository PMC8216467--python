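"""Synthetic plate-reader data with the statistical structure the analysis assumes.

Two generators are provided:

* :func:`simulate_displacement_wells` integrates the mass-action ODEs for
  the two coupled bimolecular steps of the indirect-reporter design —
  displacement of the incumbent from the PNA-DNA gate by the input
  (rate constant ``k_displacement``) followed by triggering of the
  quenched reporter by the released incumbent (``k_reporter``) — and
  renders the four wells of one experiment (reaction, pre-activated,
  negative, background) with instrument baseline, gain, and additive
  Gaussian read noise.

* :func:`simulate_melt_wells` renders fluorescence melting curves for a
  two-state bimolecular association A + B <=> AB at a ladder of total
  strand concentrations, including the free-dye positive control with a
  linear temperature drift and an empty-well background, so that the
  ratio correction applied downstream cancels the drift by construction.

Noise is added to fluorescence only, never to the chemical state, so
mass conservation holds exactly in every trajectory. All randomness is
seeded; child streams are spawned per well so wells are independent but
the whole set is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .melt import MeltCurve, tm_two_state
from .traces import FluorescenceTrace, ReactionConditions
from .units import R_KCAL, celsius_to_kelvin, nm_to_molar

__all__ = [
    "TraceSimulationSpec",
    "MeltSimulationSpec",
    "regime_a",
    "regime_b",
    "simulate_displacement_wells",
    "integrate_displacement",
    "integrate_single_step",
    "equilibrium_fraction_bound",
    "two_state_tm_bisection",
    "simulate_melt_wells",
]

#: Default reporter-step rate constant (per-molar per-second). The
#: reporter step is not characterized experimentally; this value is a
#: placeholder meaning "fast relative to displacement" and should be
#: >= 1000x k_displacement for the single-step fitting assumption to
#: hold (see methods note).
DEFAULT_K_REPORTER = 1e6

# Absolute tolerance (relative to ai0) below which transiently negative
# concentrations from the integrator are clipped to zero; larger
# negative excursions indicate invalid parameters and raise.
_NEGATIVE_CLIP_REL = 1e-6


def regime_a() -> ReactionConditions:
    """High-concentration regime: 150 nM input, 100 nM gate, 300 nM reporter, 37 C."""
    return ReactionConditions(
        in0=nm_to_molar(150.0), ai0=nm_to_molar(100.0), r0=nm_to_molar(300.0),
        temperature=37.0,
    )


def regime_b() -> ReactionConditions:
    """Low-concentration regime: 30 nM input, 20 nM gate, 60 nM reporter, 37 C."""
    return ReactionConditions(
        in0=nm_to_molar(30.0), ai0=nm_to_molar(20.0), r0=nm_to_molar(60.0),
        temperature=37.0,
    )


@dataclass(frozen=True)
class TraceSimulationSpec:
    """Parameters for one simulated displacement experiment (four wells).

    Attributes
    ----------
    k_displacement : float
        Second-order rate constant of the input + gate step, /M/s.
    k_reporter : float
        Second-order rate constant of the incumbent + reporter step, /M/s.
    conditions : ReactionConditions
        Initial concentrations (molar) and temperature (C).
    duration, sampling_interval : float
        Observation window and read period, seconds.
    noise_sd : float
        SD of additive Gaussian noise in normalized fluorescence units
        (i.e. as a fraction of the pre-activated amplitude gain*ai0).
    baseline : float
        Background fluorescence level, arbitrary units.
    gain : float
        Fluorescence units per molar of free fluorophore strand.
    seed : int
        Seed for the per-well noise streams.
    """

    k_displacement: float
    conditions: ReactionConditions
    duration: float
    sampling_interval: float
    k_reporter: float = DEFAULT_K_REPORTER
    noise_sd: float = 0.01
    baseline: float = 100.0
    gain: float = 1e9
    seed: int = 0

    def __post_init__(self):
        c = self.conditions
        if self.k_displacement <= 0 or self.k_reporter <= 0:
            raise ValueError("rate constants must be > 0")
        if c.r0 < c.ai0:
            raise ValueError(
                f"reporter must be in excess of the gate (r0={c.r0} < ai0={c.ai0})"
            )
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sampling_interval))
        return np.arange(n + 1) * self.sampling_interval


def integrate_displacement(spec: TraceSimulationSpec, rtol: float = 1e-8):
    """Integrate the two-step mass-action ODEs for the reaction well.

    State is ([Ai], [OUT], [F]) with [IN] and [R] recovered from the
    conservation laws [IN] = in0 - (ai0 - [Ai]) and [R] = r0 - [F]:

        d[Ai]/dt  = -k [IN][Ai]
        d[OUT]/dt = +k [IN][Ai] - k_rep [OUT][R]
        d[F]/dt   = +k_rep [OUT][R]

    Returns ``(times, ai, out, f)`` on the spec's sampling grid.
    """
    c = spec.conditions
    k, krep = spec.k_displacement, spec.k_reporter
    in0, ai0, r0 = c.in0, c.ai0, c.r0
    t_grid = spec.time_grid

    def rhs(t, y):
        ai, out, f = y
        inp = in0 - (ai0 - ai)
        r = r0 - f
        v1 = k * inp * ai
        v2 = krep * out * r
        return (-v1, v1 - v2, v2)

    # LSODA switches to a stiff (BDF) integrator automatically: with the
    # reporter step orders of magnitude faster than displacement the
    # coupled system is stiff, and an explicit method would grind.
    sol = solve_ivp(
        rhs, (0.0, t_grid[-1]), (ai0, 0.0, 0.0), t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=ai0 * 1e-12,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(
            f"displacement integration failed for spec {spec!r}: {sol.message}"
        )
    y = sol.y
    tol = _NEGATIVE_CLIP_REL * ai0
    if np.any(y < -tol):
        raise RuntimeError(
            f"integration produced negative concentrations beyond tolerance for {spec!r}"
        )
    y = np.clip(y, 0.0, None)
    return t_grid, y[0], y[1], y[2]


def integrate_single_step(k: float, in0: float, ai0: float, times: np.ndarray,
                          rtol: float = 1e-10) -> np.ndarray:
    """Runge-Kutta oracle for the single bimolecular step, d[OUT]/dt = k[IN][Ai].

    Returns [OUT](t) in molar on ``times`` (which must start at 0).
    Serves as the independent numerical check of the closed-form
    integrated rate law used by the fitters.
    """
    times = np.asarray(times, dtype=float)

    def rhs(t, y):
        out = y[0]
        return (k * (in0 - out) * (ai0 - out),)

    sol = solve_ivp(
        rhs, (0.0, times[-1]), (0.0,), t_eval=times,
        method="RK45", rtol=rtol, atol=min(in0 if in0 > 0 else ai0, ai0) * 1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"single-step integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, min(in0, ai0))


def simulate_displacement_wells(spec: TraceSimulationSpec) -> dict[str, FluorescenceTrace]:
    """Simulate the four wells of one displacement experiment.

    Returns a dict keyed by role: ``reaction`` follows the two-step ODE;
    ``pre_activated`` has the reporter fully triggered ([F] = ai0)
    throughout; ``negative`` has no input and stays at baseline;
    ``background`` is the bare baseline. All share the time grid; noise
    is independent across wells and seeded from ``spec.seed``.
    """
    t_grid, _, _, f_conc = integrate_displacement(spec)
    amp = spec.gain * spec.conditions.ai0  # pre-activated amplitude
    sd = spec.noise_sd * amp

    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rngs = {role: np.random.default_rng(s)
            for role, s in zip(("reaction", "pre_activated", "negative", "background"),
                               streams)}

    def well(role, signal):
        noise = rngs[role].normal(0.0, sd, size=t_grid.size) if sd > 0 else 0.0
        return FluorescenceTrace(t_grid, signal + noise, role=role, label=role)

    base = np.full(t_grid.size, spec.baseline)
    return {
        "reaction": well("reaction", spec.baseline + spec.gain * f_conc),
        "pre_activated": well("pre_activated", spec.baseline + amp * np.ones(t_grid.size)),
        "negative": well("negative", base),
        "background": well("background", base),
    }


# ---------------------------------------------------------------------------
# Two-state bimolecular melting


def equilibrium_fraction_bound(dH: float, dS: float, ct: float, temperature: float) -> float:
    """Equilibrium fraction of strands bound for A + B <=> AB at temperature (C).

    Both (non-identical) strands are present at ``ct / 2`` molar. With
    K(T) = exp(-dG(T)/RT) and dG(T) = dH - T*dS (kcal units), the bound
    fraction theta solves the mass-action quadratic

        K = x / (a - x)^2,   a = ct / 2,  theta = x / a,

    taken with the stable root so theta lies in [0, 1]. Monotonically
    decreasing in temperature for an exothermic association.
    """
    if ct <= 0:
        raise ValueError("ct must be > 0")
    if dH >= 0:
        raise ValueError("dH must be < 0 for an association reaction")
    t_k = celsius_to_kelvin(temperature)
    dg = dH - t_k * dS
    logk = -dg / (R_KCAL * t_k)
    # theta = 1 + 1/(2aK) - sqrt((1 + 1/(2aK))^2 - 1): cancellation-free
    # form of the quadratic root, stable for both huge and tiny K.
    a = ct / 2.0
    with np.errstate(over="ignore"):
        inv2ak = np.exp(-logk) / (2.0 * a)
    b = 1.0 + inv2ak
    theta = b - np.sqrt(b * b - 1.0)
    theta = float(np.clip(theta, 0.0, 1.0))
    assert 0.0 <= theta <= 1.0
    return theta


def two_state_tm_bisection(dH: float, dS: float, ct: float,
                           lo: float = -100.0, hi: float = 300.0,
                           xtol: float = 1e-10) -> float:
    """Temperature (C) where the bound fraction equals 1/2, found by bisection.

    Independent of the closed-form melting-temperature expression (see
    :func:`strandkinetics.melt.tm_two_state`); the two agree to ~1e-8 K
    and are cross-checked in the test suite.
    """
    return brentq(
        lambda t: equilibrium_fraction_bound(dH, dS, ct, t) - 0.5, lo, hi, xtol=xtol
    )


@dataclass(frozen=True)
class MeltSimulationSpec:
    """Parameters for a simulated fluorescence melt ladder.

    Attributes
    ----------
    dH, dS : float
        Association enthalpy (kcal/mol) and entropy (kcal/(mol K)); both
        negative for favorable binding.
    ct_values : tuple of float
        Total combined strand concentrations, molar.
    t_min, t_max, t_step : float
        Temperature grid in C (inclusive of t_min; 2 C steps by default,
        matching the instrument protocol).
    quench_efficiency : float
        Fraction in [0, 1] of free-dye fluorescence lost upon duplex
        formation.
    drift_slope : float
        Fractional change of free-dye fluorescence per C (dyes typically
        dim slightly on heating, hence the small negative default).
    noise_sd : float
        Gaussian noise SD as a fraction of the free-dye amplitude.
    amplitude, baseline : float
        Free-dye signal above background at t_min, and the constant
        background level, arbitrary units.
    seed : int
        Seed for the per-well noise streams.
    """

    dH: float
    dS: float
    ct_values: tuple = (0.5e-6, 1e-6, 2e-6, 3e-6, 4e-6, 6e-6)
    t_min: float = 10.0
    t_max: float = 70.0
    t_step: float = 2.0
    quench_efficiency: float = 0.9
    drift_slope: float = -0.004
    noise_sd: float = 0.01
    amplitude: float = 1000.0
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (self.dH < 0 and self.dS < 0):
            raise ValueError("dH and dS must both be < 0 for association")
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        if any(ct <= 0 for ct in self.ct_values):
            raise ValueError("all ct_values must be > 0")
        if not 0.0 <= self.quench_efficiency <= 1.0:
            raise ValueError("quench_efficiency must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def temp_grid(self) -> np.ndarray:
        n = int(np.floor((self.t_max - self.t_min) / self.t_step + 1e-9))
        return self.t_min + np.arange(n + 1) * self.t_step


def simulate_melt_wells(spec: MeltSimulationSpec) -> dict[float, MeltCurve]:
    """Simulate melt, positive-control and background wells for each ct.

    The positive control is the free-dye signal with its linear
    temperature drift; the melt well is that signal attenuated by
    ``1 - quench_efficiency * theta(T)``; the background is the constant
    baseline. The ratio correction (f_melt - f_bkgnd)/(f_pos - f_bkgnd)
    applied downstream therefore recovers 1 - q*theta(T) exactly in the
    noiseless limit, cancelling the drift by construction.
    """
    temps = spec.temp_grid
    tm_max = tm_two_state(spec.dH, spec.dS, max(spec.ct_values))
    if tm_max > spec.t_max:
        warnings.warn(
            f"Tm for the largest ct ({tm_max:.1f} C) exceeds t_max ({spec.t_max} C); "
            "the transition midpoint is not bracketed",
            stacklevel=2,
        )

    root = np.random.SeedSequence(spec.seed)
    curves: dict[float, MeltCurve] = {}
    for ct, seq in zip(spec.ct_values, root.spawn(len(spec.ct_values))):
        theta = np.array([
            equilibrium_fraction_bound(spec.dH, spec.dS, ct, t) for t in temps
        ])
        dye = spec.amplitude * (1.0 + spec.drift_slope * (temps - spec.t_min))
        sd = spec.noise_sd * spec.amplitude
        rngs = [np.random.default_rng(s) for s in seq.spawn(3)]

        def noisy(signal, rng):
            if sd > 0:
                return signal + rng.normal(0.0, sd, size=temps.size)
            return signal.copy()

        f_pos = noisy(spec.baseline + dye, rngs[0])
        f_melt = noisy(spec.baseline + dye * (1.0 - spec.quench_efficiency * theta), rngs[1])
        f_bkgnd = noisy(np.full(temps.size, spec.baseline), rngs[2])
        curves[ct] = MeltCurve(temps=temps, f_melt=f_melt, f_pos=f_pos,
                               f_bkgnd=f_bkgnd, ct=ct)
    return curves
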