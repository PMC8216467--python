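"""Fluorescence melting analysis and van't Hoff thermodynamics.

Workflow: each melt well is ratio-corrected against its free-dye
positive control and the empty-well background, giving a dimensionless
profile F_corr(T) that rises from (1 - quench) to 1 as the duplex melts.
The melting temperature is the zero crossing of the second derivative of
that profile (its inflection). Repeating at a ladder of total strand
concentrations Ct and regressing 1/Tm on ln Ct gives the association
enthalpy and entropy through the bimolecular van't Hoff relation

    1/Tm = (n-1) R / dH * ln Ct + [dS - (n-1) R ln(2n)] / dH

with molecularity n = 2 for two non-self-complementary strands (the
familiar 1/Tm = (R/dH) ln(Ct/4) + dS/dH form). dG at a reference
temperature follows as dH - T_ref * dS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .units import R_KCAL, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "MeltCurve",
    "CorrectedMeltProfile",
    "TmEstimate",
    "VantHoffFit",
    "correct_melt",
    "estimate_tm",
    "fit_vant_hoff",
    "delta_g",
    "tm_two_state",
    "TmEstimator",
    "VantHoffRegression",
]


@dataclass(frozen=True)
class MeltCurve:
    """Raw melt data for one total concentration: three aligned channels.

    ``f_melt`` is the melting well (dye strand + quencher duplex),
    ``f_pos`` the free-dye positive control, ``f_bkgnd`` the empty-well
    background, all on the shared strictly-increasing temperature grid
    ``temps`` (C). ``ct`` is the combined strand concentration (molar).
    """

    temps: np.ndarray
    f_melt: np.ndarray
    f_pos: np.ndarray
    f_bkgnd: np.ndarray
    ct: float

    def __post_init__(self):
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "temps", temps)
        for name in ("f_melt", "f_pos", "f_bkgnd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size != temps.size:
                raise ValueError(f"{name} length {arr.size} != temps length {temps.size}")
        if not np.all(np.diff(temps) > 0):
            raise ValueError("temps must be strictly increasing")
        if self.ct <= 0:
            raise ValueError(f"ct must be > 0, got {self.ct}")


@dataclass(frozen=True)
class CorrectedMeltProfile:
    """Background- and drift-corrected melt profile, nominally in [0, 1]."""

    temps: np.ndarray
    f_corr: np.ndarray
    ct: float
    n_interpolated: int = 0


@dataclass(frozen=True)
class TmEstimate:
    """Melting temperature from the second-derivative zero crossing."""

    tm: float  # C
    ct: float  # molar
    method: str = "second_derivative"
    curvature_diagnostics: dict = field(default_factory=dict)

    @property
    def tm_kelvin(self) -> float:
        return celsius_to_kelvin(self.tm)


@dataclass(frozen=True)
class VantHoffFit:
    """Association thermodynamics from the 1/Tm vs ln Ct regression."""

    dH: float            # kcal/mol
    dS: float            # kcal/(mol K)
    dG_at: float         # kcal/mol at t_ref
    t_ref: float         # K
    n: int
    r_squared: float
    dH_sd: float
    dS_sd: float
    slope: float
    intercept: float
    n_points: int


def correct_melt(curve: MeltCurve, denom_floor: float | None = None,
                 max_flagged_frac: float = 0.10) -> CorrectedMeltProfile:
    """Ratio-correct a melt well for background and temperature drift.

    f_corr(T) = (f_melt - f_bkgnd) / (f_pos - f_bkgnd) pointwise. The
    division by the positive control cancels any multiplicative
    temperature dependence of the free dye. Points where the denominator
    falls below ``denom_floor`` (default: 1% of the median denominator)
    are flagged and linearly interpolated over; more than
    ``max_flagged_frac`` flagged points is an error.
    """
    num = curve.f_melt - curve.f_bkgnd
    den = curve.f_pos - curve.f_bkgnd
    if denom_floor is None:
        denom_floor = 0.01 * float(np.median(np.abs(den)))
    bad = np.abs(den) < denom_floor
    if bad.mean() > max_flagged_frac:
        raise ValueError(
            f"{int(bad.sum())}/{bad.size} points have positive-control signal below "
            f"the floor {denom_floor:.3g}; correction unreliable"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_corr = num / den
    if bad.any():
        good = ~bad
        f_corr[bad] = np.interp(curve.temps[bad], curve.temps[good], f_corr[good])
    return CorrectedMeltProfile(temps=curve.temps, f_corr=f_corr, ct=curve.ct,
                                n_interpolated=int(bad.sum()))


class TmEstimator(BaseEstimator):
    """Melting temperature by the second-derivative zero-crossing rule.

    First and second derivatives of the corrected profile are
    approximated by central finite differences (optionally after a
    3-point moving-average smoothing, recommended for noisy data). The
    reported Tm is the linearly interpolated zero crossing of the second
    derivative nearest the maximum of the first derivative — i.e. the
    inflection of the transition.

    Parameters
    ----------
    smooth : bool
        Apply the moving-average pre-smoothing. Default True; turn off
        for noiseless synthetic curves.
    smooth_window : int
        Odd window length for the moving average.

    Attributes
    ----------
    tm_ : float
        Estimated melting temperature, C.
    d1_, d2_ : ndarray
        First/second finite-difference derivatives on the grid.
    candidates_ : list of float
        All second-derivative sign-change temperatures found.
    """

    def __init__(self, smooth: bool = True, smooth_window: int = 3):
        self.smooth = smooth
        self.smooth_window = smooth_window

    def fit(self, temps, f_corr=None):
        if f_corr is None:  # allow fit(profile)
            temps, f_corr = temps.temps, temps.f_corr
        temps = np.asarray(temps, dtype=float).ravel()
        f = np.asarray(f_corr, dtype=float).ravel()
        if temps.size < 7:
            raise ValueError("need at least 7 points to estimate Tm")
        span = f.max() - f.min()
        mid = f.min() + 0.5 * span
        if not (f[0] < mid < f[-1] or f[-1] < mid < f[0]):
            raise ValueError("transition not captured: profile does not cross its midrange")
        if self.smooth:
            w = int(self.smooth_window)
            if w % 2 == 0 or w < 3:
                raise ValueError("smooth_window must be odd and >= 3")
            kernel = np.ones(w) / w
            pad = w // 2
            fpad = np.concatenate([f[:1].repeat(pad), f, f[-1:].repeat(pad)])
            f = np.convolve(fpad, kernel, mode="valid")
        d1 = np.gradient(f, temps)
        d2 = np.gradient(d1, temps)

        sign = np.sign(d2)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        if idx.size == 0:
            raise ValueError("transition not captured: second derivative has no zero crossing")
        crossings = temps[idx] - d2[idx] * (temps[idx + 1] - temps[idx]) / (d2[idx + 1] - d2[idx])
        t_peak = temps[int(np.argmax(d1))]
        order = np.argsort(np.abs(crossings - t_peak))
        if idx.size > 1:
            warnings.warn(
                f"multiple second-derivative zero crossings at {np.sort(crossings)}; "
                f"choosing the one nearest the first-derivative maximum ({t_peak} C)",
                stacklevel=2,
            )
        self.candidates_ = [float(c) for c in crossings[order]]
        self.tm_ = self.candidates_[0]
        self.d1_, self.d2_ = d1, d2
        i = int(idx[order[0]])
        self.diagnostics_ = {
            "d1_at_crossing": float(d1[i]),
            "d2_bracket": (float(d2[i]), float(d2[i + 1])),
            "t_peak_d1": float(t_peak),
        }
        return self


def estimate_tm(profile: CorrectedMeltProfile, smooth: bool = False,
                smooth_window: int = 3) -> TmEstimate:
    """Estimate Tm of a corrected profile; see :class:`TmEstimator`."""
    est = TmEstimator(smooth=smooth, smooth_window=smooth_window).fit(profile)
    return TmEstimate(tm=est.tm_, ct=profile.ct,
                      curvature_diagnostics=est.diagnostics_)


class VantHoffRegression(RegressorMixin, BaseEstimator):
    """Association thermodynamics from the concentration dependence of Tm.

    Ordinary least squares of 1/Tm (K^-1) on ln Ct, inverted through the
    bimolecular van't Hoff relation:

        dH = (n - 1) R / slope
        dS = intercept * dH + (n - 1) R ln(2n)

    with R = 1.987e-3 kcal/(mol K). Uncertainties on dH and dS follow by
    first-order propagation of the regression covariance.

    Parameters
    ----------
    n : int
        Molecularity of the binding reaction (2 for two strands).
    t_ref : float
        Reference temperature (K) at which dG is reported; default
        310.15 K (37 C, the reaction temperature).

    Attributes
    ----------
    dH_, dS_, dG_ref_ : float
        Fitted enthalpy (kcal/mol), entropy (kcal/(mol K)) and derived
        free energy at ``t_ref`` (kcal/mol).
    slope_, intercept_, r_squared_ : float
        The underlying regression line.
    dH_sd_, dS_sd_ : float
        Propagated standard errors.
    """

    def __init__(self, n: int = 2, t_ref: float = 310.15):
        self.n = n
        self.t_ref = t_ref

    def fit(self, ct, tm_kelvin):
        ct = np.asarray(ct, dtype=float).ravel()
        tm_k = np.asarray(tm_kelvin, dtype=float).ravel()
        if ct.size != tm_k.size:
            raise ValueError("ct and tm must have the same length")
        if ct.size < 3:
            raise ValueError(f"need >= 3 (Tm, Ct) pairs, got {ct.size}")
        if np.unique(ct).size < 2:
            raise ValueError("no spread in ct values; regression is degenerate")
        x = np.log(ct)
        y = 1.0 / tm_k
        (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
        if slope >= 0:
            warnings.warn(
                "non-negative 1/Tm vs ln Ct slope implies dH >= 0; "
                "unexpected for an exothermic association", stacklevel=2,
            )
        resid = y - (slope * x + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0

        nr = (self.n - 1) * R_KCAL
        dH = nr / slope
        dS = intercept * dH + nr * np.log(2 * self.n)
        # first-order propagation through dH(s), dS(s, i)
        ddh_ds = -nr / slope ** 2
        dds_ds = intercept * ddh_ds
        dds_di = dH
        var_s, var_i = cov[0, 0], cov[1, 1]
        cov_si = cov[0, 1]
        dH_sd = abs(ddh_ds) * np.sqrt(var_s)
        dS_var = dds_ds ** 2 * var_s + dds_di ** 2 * var_i + 2 * dds_ds * dds_di * cov_si
        dS_sd = np.sqrt(max(dS_var, 0.0))

        self.slope_, self.intercept_ = float(slope), float(intercept)
        self.r_squared_ = float(np.clip(r2, 0.0, 1.0))
        self.dH_, self.dS_ = float(dH), float(dS)
        self.dG_ref_ = float(dH - self.t_ref * dS)
        self.dH_sd_, self.dS_sd_ = float(dH_sd), float(dS_sd)
        self.n_points_ = int(ct.size)
        return self

    def predict(self, ct):
        """Predicted Tm (K) at total concentrations ``ct`` (molar)."""
        ct = np.asarray(ct, dtype=float)
        return 1.0 / (self.slope_ * np.log(ct) + self.intercept_)


def fit_vant_hoff(tms, n: int = 2, t_ref: float = 310.15,
                  average_replicates: bool = True) -> VantHoffFit:
    """Fit association thermodynamics to a collection of Tm estimates.

    ``tms`` is a sequence of :class:`TmEstimate` (or ``(tm_C, ct)``
    pairs). Replicate Tm values at the same ct are averaged before the
    regression by default, matching the protocol of averaging over
    repeated melts; pass ``average_replicates=False`` to regress on the
    raw per-replicate points.
    """
    pairs = []
    for t in tms:
        if isinstance(t, TmEstimate):
            pairs.append((t.ct, t.tm_kelvin))
        else:
            tm_c, ct = t
            pairs.append((ct, celsius_to_kelvin(tm_c)))
    cts = np.array([p[0] for p in pairs])
    tm_k = np.array([p[1] for p in pairs])
    if average_replicates:
        uniq = np.unique(cts)
        tm_k = np.array([tm_k[cts == c].mean() for c in uniq])
        cts = uniq
    est = VantHoffRegression(n=n, t_ref=t_ref).fit(cts, tm_k)
    return VantHoffFit(
        dH=est.dH_, dS=est.dS_, dG_at=est.dG_ref_, t_ref=t_ref, n=n,
        r_squared=est.r_squared_, dH_sd=est.dH_sd_, dS_sd=est.dS_sd_,
        slope=est.slope_, intercept=est.intercept_, n_points=est.n_points_,
    )


def delta_g(dH: float, dS: float, temperature: float) -> float:
    """Standard free energy dH - T*dS (kcal/mol) at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return dH - temperature * dS


def tm_two_state(dH: float, dS: float, ct: float, n: int = 2) -> float:
    """Closed-form melting temperature (C) for the two-state bimolecular model.

    Inverts the van't Hoff line at the theta = 1/2 point:
    Tm = dH / [ (n-1) R ln Ct + dS - (n-1) R ln(2n) ].
    """
    nr = (n - 1) * R_KCAL
    tm_k = dH / (nr * np.log(ct) + dS - nr * np.log(2 * n))
    return float(kelvin_to_celsius(tm_k))
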