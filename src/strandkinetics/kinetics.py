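"""Normalization and second-order rate-constant estimation for strand displacement.

The displacement step input + gate -> output is treated as a single
irreversible bimolecular reaction. With unequal initial concentrations
[IN]0 != [Ai]0 the integrated rate law has two equivalent forms used for
fitting:

* linearized: ln[ (([Ai]0 - [OUT]) [IN]0) / (([IN]0 - [OUT]) [Ai]0) ]
  is linear in t with slope ([Ai]0 - [IN]0) k — preferred for slow
  reactions observed far from completion;

* closed form: [OUT]_n(t) = [IN]0 (1 - e^u) / ([IN]0 - [Ai]0 e^u) with
  u = k t ([Ai]0 - [IN]0) — fitted by nonlinear least squares for fast
  reactions that approach completion.

Raw fluorescence is first normalized against time-matched pre-activated
and negative controls, F_n = (F - F0) / (Fc - F0), which makes fitted
rate constants invariant to instrument gain. Derived summaries
(mismatch discrimination factors, toehold-length regression, rate
ratios) are thin computations on replicate-averaged rate constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .traces import FluorescenceTrace, NormalizedTrace, ReactionConditions

__all__ = [
    "RateFitResult",
    "DiscriminationResult",
    "RatioResult",
    "ToeholdSeries",
    "closed_form_conversion",
    "eq2_lhs",
    "normalize_trace",
    "fit_rate_linearized",
    "fit_rate_closed_form",
    "select_and_fit",
    "fit_replicates",
    "discrimination_factor",
    "rate_ratio",
    "fit_toehold_dependence",
    "FluorescenceNormalizer",
    "SecondOrderRateFit",
    "ToeholdLengthRegression",
]

#: Exclude points with normalized fluorescence above this from linearized
#: fits: near completion the log term sits on a singularity and amplifies
#: noise without bound.
DEFAULT_FN_CAP = 0.95

#: Regime-selection threshold on the final normalized fluorescence:
#: below it the reaction is treated as slow (linearized fit), above as
#: fast (closed-form fit).
DEFAULT_COMPLETION_THRESHOLD = 0.5

#: Smallest rate constant (/M/s) considered resolvable over a typical
#: observation window; slower fits are reported as bounds, not numbers.
DEFAULT_K_FLOOR = 10.0

_EQUAL_CONC_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Integrated rate laws


def closed_form_conversion(t, k, in0, ai0):
    """Normalized displaced incumbent [OUT]/[Ai]0 under second-order kinetics.

    Evaluates the closed-form solution of d[OUT]/dt = k([IN]0 - [OUT])
    ([Ai]0 - [OUT]), normalized by the limiting gate concentration. For
    in0 == ai0 (within rounding) the equal-concentration law
    [OUT]_n = c k t / (1 + c k t) is used. Overflow-safe for large
    |k t (ai0 - in0)|.
    """
    t = np.asarray(t, dtype=float)
    if in0 < 0 or ai0 <= 0:
        raise ValueError("need in0 >= 0 and ai0 > 0")
    if in0 == 0:
        return np.zeros_like(t)
    if abs(in0 - ai0) <= _EQUAL_CONC_RTOL * max(in0, ai0):
        x = in0 * k * t
        return x / (1.0 + x)
    u = k * t * (ai0 - in0)
    # Multiply through by e^-u where u > 0 so the exponential never overflows.
    with np.errstate(over="ignore"):
        pos = u > 0
        eu = np.exp(np.where(pos, -u, u))
        num = np.where(pos, eu - 1.0, 1.0 - eu) * in0
        den = np.where(pos, in0 * eu - ai0, in0 - ai0 * eu)
    out_n = num / den
    return np.clip(out_n, 0.0, min(in0, ai0) / ai0)


def eq2_lhs(out, in0: float, ai0: float):
    """Left-hand side of the linearized second-order law.

    ln[ ((ai0 - out) in0) / ((in0 - out) ai0) ], computed as
    log1p(-out/ai0) - log1p(-out/in0) for accuracy near out = 0 where
    the direct quotient loses precision. Equals (ai0 - in0) k t along a
    second-order trajectory. Requires 0 <= out < min(in0, ai0); callers
    exclude singular points rather than clamping them.
    """
    out = np.asarray(out, dtype=float)
    if in0 <= 0 or ai0 <= 0:
        raise ValueError("need in0 > 0 and ai0 > 0 for the linearized law")
    if np.any(out >= min(in0, ai0)):
        raise ValueError("eq2_lhs requires out < min(in0, ai0); exclude singular points")
    # Slightly negative out (read noise around zero conversion) is
    # admitted: the log arguments stay positive and excluding one noise
    # tail would bias the slope. Large negatives are still nonsense.
    if np.any(out < -0.5 * min(in0, ai0)):
        raise ValueError("out is far below zero; not a noise perturbation")
    return np.log1p(-out / ai0) - np.log1p(-out / in0)


# ---------------------------------------------------------------------------
# Normalization


class FluorescenceNormalizer(TransformerMixin, BaseEstimator):
    """Normalize raw fluorescence with time-matched controls.

    ``fit`` stores the pre-activated (Fc) and negative (F0) control
    traces; ``transform`` maps a raw reaction trace to
    F_n(t) = (F - F0(t)) / (Fc(t) - F0(t)). Points where the control
    difference drops below ``floor_frac`` of its median are flagged in
    the output mask and excluded from downstream fits.

    Parameters
    ----------
    floor_frac : float
        Fraction of the median control difference below which a point is
        flagged.
    time_atol : float
        Absolute tolerance (s) for matching control time grids.
    """

    def __init__(self, floor_frac: float = 0.1, time_atol: float = 1e-6):
        self.floor_frac = floor_frac
        self.time_atol = time_atol

    def fit(self, pre_activated: FluorescenceTrace, negative: FluorescenceTrace):
        if not np.allclose(pre_activated.times, negative.times, atol=self.time_atol, rtol=0):
            raise ValueError("pre_activated and negative control time grids differ")
        self.times_ = pre_activated.times
        self.fc_ = pre_activated.values
        self.f0_ = negative.values
        den = self.fc_ - self.f0_
        self.floor_ = self.floor_frac * float(np.median(np.abs(den)))
        self.valid_ = np.abs(den) >= self.floor_
        if not self.valid_.any():
            raise ValueError("control difference Fc - F0 is below the floor everywhere")
        return self

    def transform(self, trace: FluorescenceTrace) -> np.ndarray:
        if trace.times.size != self.times_.size or not np.allclose(
            trace.times, self.times_, atol=self.time_atol, rtol=0
        ):
            raise ValueError(
                f"trace {trace.label!r} time grid does not match the fitted controls"
            )
        den = self.fc_ - self.f0_
        fn = np.empty_like(den)
        fn[self.valid_] = (trace.values[self.valid_] - self.f0_[self.valid_]) / den[self.valid_]
        fn[~self.valid_] = np.nan
        return fn


def normalize_trace(
    reaction: FluorescenceTrace,
    pre_activated: FluorescenceTrace,
    negative: FluorescenceTrace,
    conditions: ReactionConditions | None = None,
    floor_frac: float = 0.1,
) -> NormalizedTrace:
    """Normalize a reaction trace against its two controls.

    Returns a :class:`NormalizedTrace` whose ``mask`` excludes points
    with a degenerate control difference.
    """
    norm = FluorescenceNormalizer(floor_frac=floor_frac).fit(pre_activated, negative)
    fn = norm.transform(reaction)
    return NormalizedTrace(times=reaction.times, fn=np.nan_to_num(fn, nan=0.0),
                           conditions=conditions, label=reaction.label,
                           mask=norm.valid_)


# ---------------------------------------------------------------------------
# Rate fitting


@dataclass(frozen=True)
class RateFitResult:
    """Fitted second-order rate constant with diagnostics.

    ``method`` is one of ``linearized_eq2``, ``closed_form_eq3``,
    ``equal_conc``. ``replicate_mean``/``replicate_sd`` summarize
    independent replicate fits (sd only when >= 2 replicates succeeded);
    for a single fit the mean equals ``k``.
    """

    k: float
    method: str
    r_squared: float
    n_points_used: int
    success: bool
    intercept: float = float("nan")
    residual_summary: dict = field(default_factory=dict)
    replicate_ks: tuple = ()
    replicate_mean: float = float("nan")
    replicate_sd: float | None = None
    deviation_flag: bool = False
    label: str = ""


#: Points with normalized fluorescence below this are treated as noise
#: outliers rather than near-zero conversion and excluded; slightly
#: negative values are retained so symmetric read noise around zero does
#: not get one tail truncated (which would bias the fitted slope).
DEFAULT_FN_FLOOR = -0.05


def _usable_points(trace: NormalizedTrace, cond: ReactionConditions, fn_cap: float,
                   fn_floor: float = DEFAULT_FN_FLOOR):
    """Mask of points eligible for a linearized fit (finite, in (floor, cap], non-singular)."""
    fn = trace.fn
    mask = trace.mask & np.isfinite(fn) & (fn >= fn_floor) & (fn <= fn_cap)
    out = fn * cond.ai0
    lim = min(cond.in0, cond.ai0) if cond.in0 > 0 else cond.ai0
    mask &= out < lim * (1.0 - 1e-12)
    return mask


def _r_squared(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


class SecondOrderRateFit(RegressorMixin, BaseEstimator):
    """Second-order displacement rate constant, fitted from a normalized trace.

    Parameters
    ----------
    in0, ai0 : float
        Initial input and gate concentrations, molar.
    method : str
        ``"auto"`` routes by the final normalized fluorescence
        (< ``completion_threshold`` -> linearized, else closed form);
        ``"linearized"``, ``"closed_form"`` or ``"equal_conc"`` force a
        route. ``in0 == ai0`` always uses the equal-concentration law.
    completion_threshold : float
        Auto-routing threshold on the final fn.
    fn_cap : float
        Linearized fits exclude points with fn above this cap (log
        singularity at completion).
    r2_flag_threshold : float
        Fits with r^2 below this are flagged as deviating from
        second-order kinetics (they remain reported as second-order).

    Attributes
    ----------
    k_ : float
        Fitted rate constant, /M/s (nan on failure).
    method_ : str
        The route actually used.
    success_, r_squared_, intercept_, n_points_used_ : fit diagnostics.
    """

    def __init__(self, in0: float, ai0: float, method: str = "auto",
                 completion_threshold: float = DEFAULT_COMPLETION_THRESHOLD,
                 fn_cap: float = DEFAULT_FN_CAP,
                 r2_flag_threshold: float = 0.9):
        self.in0 = in0
        self.ai0 = ai0
        self.method = method
        self.completion_threshold = completion_threshold
        self.fn_cap = fn_cap
        self.r2_flag_threshold = r2_flag_threshold

    # -- internal routes ----------------------------------------------------

    def _cond(self) -> ReactionConditions:
        return ReactionConditions(in0=self.in0, ai0=self.ai0, r0=0.0)

    def _equal_conc(self, t, fn, trace_mask):
        """Integrated law for in0 == ai0: 1/(ai0 - out) - 1/ai0 = k t."""
        c0 = self.ai0
        out = np.clip(fn, 0.0, None) * c0
        mask = trace_mask & np.isfinite(fn) & (fn >= 0) & (fn <= self.fn_cap)
        mask &= out < c0 * (1 - 1e-12)
        n = int(mask.sum())
        if n < 4:
            return dict(k=np.nan, success=False, r2=0.0, n=n, intercept=np.nan)
        y = 1.0 / (c0 - out[mask]) - 1.0 / c0
        slope, intercept = np.polyfit(t[mask], y, 1)
        r2 = _r_squared(y, slope * t[mask] + intercept)
        return dict(k=float(slope), success=slope > 0, r2=r2, n=n,
                    intercept=float(intercept))

    def _linearized(self, t, fn, trace_mask):
        cond = self._cond()
        mask = _usable_points(
            NormalizedTrace(t, fn, conditions=cond, mask=trace_mask), cond, self.fn_cap
        )
        n = int(mask.sum())
        if n < 4:
            raise ValueError(f"only {n} usable points after exclusions; need >= 4")
        out = fn[mask] * self.ai0
        y = eq2_lhs(out, self.in0, self.ai0)
        slope, intercept = np.polyfit(t[mask], y, 1)
        k = float(slope / (self.ai0 - self.in0))
        r2 = _r_squared(y, slope * t[mask] + intercept)
        return dict(k=k, success=k > 0, r2=r2, n=n, intercept=float(intercept))

    def _closed_form(self, t, fn, trace_mask):
        mask = trace_mask & np.isfinite(fn)
        n = int(mask.sum())
        if n < 4:
            raise ValueError(f"only {n} usable points; need >= 4")
        tt, yy = t[mask], fn[mask]

        def residuals(log10k):
            return closed_form_conversion(tt, 10.0 ** log10k[0], self.in0, self.ai0) - yy

        def sse(x):
            r = residuals([x])
            return float(r @ r)

        # Initial guess from a linearized fit on the early-time window,
        # backed by log-spaced candidate starts (10^1 .. 10^7).
        guesses = []
        try:
            early = yy < 0.5
            if early.sum() >= 4 and abs(self.in0 - self.ai0) > 0:
                g = self._linearized(tt[early], yy[early], np.ones(int(early.sum()), bool))
                if g["success"]:
                    guesses.append(float(np.log10(g["k"])))
        except (ValueError, np.linalg.LinAlgError):
            pass
        guesses.extend(np.arange(1.0, 7.25, 0.25))
        x0 = min(guesses, key=sse)
        # Bounded refinement: the candidate grid brackets the optimum to
        # within its spacing, so a +-2-decade box cannot exclude it while
        # preventing runaway into the saturated (zero-gradient) region.
        sol = least_squares(residuals, x0=[x0], bounds=([x0 - 2.0], [x0 + 2.0]),
                            method="trf")
        if not np.isfinite(sol.cost) or sol.cost > sse(x0) + 1e-12:
            return dict(k=np.nan, success=False, r2=0.0, n=n, intercept=np.nan)
        k = float(10.0 ** sol.x[0])
        yhat = closed_form_conversion(tt, k, self.in0, self.ai0)
        return dict(k=k, success=bool(sol.success), r2=_r_squared(yy, yhat), n=n,
                    intercept=float("nan"))

    # -- public API ---------------------------------------------------------

    def fit(self, X, y=None, mask=None):
        """Fit to times ``X`` (s) and normalized fluorescence ``y``."""
        t = np.asarray(X, dtype=float).ravel()
        fn = np.asarray(y, dtype=float).ravel()
        if t.size != fn.size:
            raise ValueError("times and fn must have the same length")
        trace_mask = np.ones(t.size, bool) if mask is None else np.asarray(mask, bool)

        equal = abs(self.in0 - self.ai0) <= _EQUAL_CONC_RTOL * max(self.in0, self.ai0)
        method = self.method
        if equal:
            method = "equal_conc"
        elif method == "auto":
            tail = fn[trace_mask][-3:]
            method = ("linearized" if float(np.mean(tail)) < self.completion_threshold
                      else "closed_form")
        if method == "equal_conc" and not equal:
            raise ValueError("equal_conc route requires in0 == ai0")

        route = {"linearized": self._linearized, "closed_form": self._closed_form,
                 "equal_conc": self._equal_conc}[method]
        res = route(t, fn, trace_mask)
        self.method_ = {"linearized": "linearized_eq2", "closed_form": "closed_form_eq3",
                        "equal_conc": "equal_conc"}[method]
        self.k_ = res["k"] if res["success"] else float("nan")
        self.k_raw_ = res["k"]
        self.success_ = bool(res["success"]) and np.isfinite(res["k"])
        self.r_squared_ = res["r2"]
        self.intercept_ = res["intercept"]
        self.n_points_used_ = res["n"]
        self.deviation_flag_ = self.success_ and res["r2"] < self.r2_flag_threshold
        return self

    def predict(self, X):
        """Predicted normalized fluorescence at times ``X``."""
        if not getattr(self, "success_", False):
            raise RuntimeError("cannot predict from a failed fit")
        t = np.asarray(X, dtype=float).ravel()
        return closed_form_conversion(t, self.k_, self.in0, self.ai0)

    def result(self, label: str = "") -> RateFitResult:
        """Package the fitted attributes as a :class:`RateFitResult`."""
        return RateFitResult(
            k=self.k_, method=self.method_, r_squared=self.r_squared_,
            n_points_used=self.n_points_used_, success=self.success_,
            intercept=self.intercept_,
            residual_summary={"r_squared": self.r_squared_},
            replicate_ks=(self.k_,) if self.success_ else (),
            replicate_mean=self.k_, replicate_sd=None,
            deviation_flag=self.deviation_flag_, label=label,
        )


def _fit_with_method(trace: NormalizedTrace, cond: ReactionConditions,
                     method: str, **kwargs) -> RateFitResult:
    est = SecondOrderRateFit(in0=cond.in0, ai0=cond.ai0, method=method, **kwargs)
    est.fit(trace.times, trace.fn, mask=trace.mask)
    return est.result(label=trace.label)


def fit_rate_linearized(trace: NormalizedTrace, cond: ReactionConditions,
                        **kwargs) -> RateFitResult:
    """Slow-reaction route: OLS of the linearized law; k from the slope."""
    return _fit_with_method(trace, cond, "linearized", **kwargs)


def fit_rate_closed_form(trace: NormalizedTrace, cond: ReactionConditions,
                         **kwargs) -> RateFitResult:
    """Fast-reaction route: nonlinear least squares of the closed form."""
    return _fit_with_method(trace, cond, "closed_form", **kwargs)


def select_and_fit(trace: NormalizedTrace, cond: ReactionConditions,
                   completion_threshold: float = DEFAULT_COMPLETION_THRESHOLD,
                   **kwargs) -> RateFitResult:
    """Route by final conversion: slow -> linearized, fast -> closed form."""
    return _fit_with_method(trace, cond, "auto",
                            completion_threshold=completion_threshold, **kwargs)


def fit_replicates(traces, cond: ReactionConditions, method: str = "auto",
                   label: str = "", **kwargs) -> RateFitResult:
    """Fit each replicate independently and summarize as mean +- sd.

    Replicates are never pooled into one global fit; the replicate sd is
    the reported measure of error. The representative single-fit
    diagnostics are those of the first successful replicate.
    """
    fits = [_fit_with_method(tr, cond, method, **kwargs) for tr in traces]
    ks = [f.k for f in fits if f.success]
    if not ks:
        rep = fits[0]
        return RateFitResult(
            k=float("nan"), method=rep.method, r_squared=0.0,
            n_points_used=rep.n_points_used, success=False, label=label,
            residual_summary={"n_replicates": len(fits), "n_failed": len(fits)},
        )
    mean = float(np.mean(ks))
    sd = float(np.std(ks, ddof=1)) if len(ks) >= 2 else None
    first = next(f for f in fits if f.success)
    return RateFitResult(
        k=mean, method=first.method, r_squared=first.r_squared,
        n_points_used=first.n_points_used, success=True,
        intercept=first.intercept,
        residual_summary={"n_replicates": len(fits), "n_failed": len(fits) - len(ks),
                          "per_replicate_r2": [f.r_squared for f in fits if f.success]},
        replicate_ks=tuple(ks), replicate_mean=mean, replicate_sd=sd,
        deviation_flag=any(f.deviation_flag for f in fits), label=label,
    )


# ---------------------------------------------------------------------------
# Derived summaries


@dataclass(frozen=True)
class DiscriminationResult:
    """Mismatch discrimination factor DF = k_match / k_mismatch.

    When the mismatched reaction is unresolvable (failed fit or k below
    the floor), ``is_bound`` is set and ``df`` is the lower bound
    k_match / k_floor, displayed as "DF > X".
    """

    df: float
    df_sd: float | None
    k_match: RateFitResult
    k_mismatch: RateFitResult
    is_bound: bool = False

    def __str__(self) -> str:
        return f"DF > {self.df:.3g}" if self.is_bound else f"DF = {self.df:.3g}"


@dataclass(frozen=True)
class RatioResult:
    """Generic ratio of two fitted rate constants with propagated sd."""

    ratio: float
    ratio_sd: float | None
    numerator: RateFitResult
    denominator: RateFitResult
    is_bound: bool = False


def _ratio_core(num: RateFitResult, den: RateFitResult, k_floor: float):
    if not num.success or not np.isfinite(num.replicate_mean) or num.replicate_mean <= 0:
        raise ValueError(f"numerator fit {num.label!r} failed; no ratio defined")
    if not den.success or den.replicate_mean < k_floor:
        return num.replicate_mean / k_floor, None, True
    r = num.replicate_mean / den.replicate_mean
    sd = None
    if num.replicate_sd is not None and den.replicate_sd is not None:
        sd = r * np.sqrt((num.replicate_sd / num.replicate_mean) ** 2
                         + (den.replicate_sd / den.replicate_mean) ** 2)
    return r, sd, False


def discrimination_factor(matched: RateFitResult, mismatched: RateFitResult,
                          k_floor: float = DEFAULT_K_FLOOR) -> DiscriminationResult:
    """DF = k_match / k_mismatch with first-order error propagation."""
    df, sd, bound = _ratio_core(matched, mismatched, k_floor)
    return DiscriminationResult(df=float(df), df_sd=sd, k_match=matched,
                                k_mismatch=mismatched, is_bound=bound)


def rate_ratio(numerator: RateFitResult, denominator: RateFitResult,
               k_floor: float = DEFAULT_K_FLOOR) -> RatioResult:
    """Ratio of two rate constants (e.g. k_RNA/k_DNA, k_short/k_long)."""
    r, sd, bound = _ratio_core(numerator, denominator, k_floor)
    return RatioResult(ratio=float(r), ratio_sd=sd, numerator=numerator,
                       denominator=denominator, is_bound=bound)


@dataclass(frozen=True)
class ToeholdSeries:
    """Exponential toehold-length dependence: log10(k) linear in length."""

    lengths: tuple
    ks: tuple
    slope: float
    intercept: float
    fold_per_nt: float
    r_squared: float


class ToeholdLengthRegression(RegressorMixin, BaseEstimator):
    """OLS of log10(rate constant) on toehold length (nucleotides).

    Attributes ``slope_`` (decades per nt), ``intercept_``,
    ``fold_per_nt_`` (= 10**slope) and ``r_squared_``.
    """

    def fit(self, lengths, ks):
        lengths = np.asarray(lengths, dtype=float).ravel()
        ks = np.asarray(ks, dtype=float).ravel()
        if lengths.size != ks.size:
            raise ValueError("lengths and ks must have the same length")
        if np.unique(lengths).size != lengths.size:
            raise ValueError("toehold lengths must be distinct")
        if lengths.size < 3:
            raise ValueError("need >= 3 distinct lengths")
        bad = np.nonzero(~(ks > 0))[0]
        if bad.size:
            raise ValueError(f"non-positive rate constant at lengths {lengths[bad]}")
        y = np.log10(ks)
        slope, intercept = np.polyfit(lengths, y, 1)
        self.slope_, self.intercept_ = float(slope), float(intercept)
        self.fold_per_nt_ = float(10.0 ** slope)
        self.r_squared_ = _r_squared(y, slope * lengths + intercept)
        return self

    def predict(self, lengths):
        lengths = np.asarray(lengths, dtype=float)
        return 10.0 ** (self.slope_ * lengths + self.intercept_)


def fit_toehold_dependence(lengths, ks) -> ToeholdSeries:
    """Semilog regression of rate constant on toehold length."""
    est = ToeholdLengthRegression().fit(lengths, ks)
    return ToeholdSeries(
        lengths=tuple(float(x) for x in np.ravel(lengths)),
        ks=tuple(float(x) for x in np.ravel(ks)),
        slope=est.slope_, intercept=est.intercept_,
        fold_per_nt=est.fold_per_nt_, r_squared=est.r_squared_,
    )
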