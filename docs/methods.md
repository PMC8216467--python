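# Methods

## Reaction model

Strand displacement from a PNA–DNA heteroduplex is modeled as two
coupled irreversible bimolecular steps under mass action:

    IN + Ai  →  OUT + waste        (rate constant k)
    OUT + R  →  F + quencher       (rate constant k_rep)

with states ([Ai], [OUT], [F]) and the conservation laws
[IN] = [IN]₀ − ([Ai]₀ − [Ai]) and [R] = [R]₀ − [F]. The fluorescent
species is the released reporter strand F, so the observable is
baseline + gain·[F] plus read noise. [Ai]₀ is limiting throughout
(standard 1.5:1 input:gate, 3:1 reporter:gate stoichiometry), so full
conversion corresponds to [F] = [Ai]₀ and the normalized signal runs
from 0 to 1.

**Fitting assumption.** All fitting treats the cascade as the single
step IN + Ai → OUT, i.e. assumes the reporter relays the released
incumbent instantaneously. The generator quantifies when this holds:
with k_rep/k ≥ 10³ the simulated trace matches the one-step closed form
within 1 % of [Ai]₀ at all times, and the residual effect on fitted k
is ≈ 0.04 %; with k_rep ≈ k the trace lags the closed form and the
apparent rate is biased low by tens of percent. The reporter rate
constant is not experimentally characterized; its default (10⁶ M⁻¹s⁻¹)
is a placeholder meaning "fast relative to displacement", and synthetic
fixtures scale it to max(10³·k, 10⁶) to stay in the valid regime.

## Integrated rate laws and fitting routes

For [IN]₀ ≠ [Ai]₀ the one-step law integrates to the linear form

    ln[ (([Ai]₀ − [OUT])[IN]₀) / (([IN]₀ − [OUT])[Ai]₀) ] = ([Ai]₀ − [IN]₀) k t

and the equivalent explicit solution

    [OUT]_n(t) = [IN]₀ (1 − e^u) / ([IN]₀ − [Ai]₀ e^u),   u = k t ([Ai]₀ − [IN]₀).

Slow reactions (final normalized fluorescence below the configurable
`completion_threshold`, default 0.5) are fit by ordinary least squares
of the log term against time, k = slope/([Ai]₀ − [IN]₀), with an
unconstrained intercept reported as a lag/mixing diagnostic. Fast
reactions are fit by nonlinear least squares of the closed form in
log₁₀ k, initialized from an early-time linearized fit with log-spaced
fallback starts (10¹–10⁷ M⁻¹s⁻¹) and a bounded refinement that cannot
escape into the saturated, gradient-free region. The two routes agree
within 0.1 % on noiseless data wherever both converge, and the
substitution identity (closed form into log term) holds to 10⁻¹⁰
relative — the routes are mutually consistent by construction.

Numerical choices:

* The log term is evaluated as log1p(−out/[Ai]₀) − log1p(−out/[IN]₀),
  which is cancellation-free near zero conversion.
* Points with F_n > `fn_cap` (default 0.95) are excluded from
  linearized fits: the log term is singular at completion and amplifies
  noise without bound there.
* Points with slightly negative F_n (≥ −0.05) are retained: the log
  arguments remain positive, and discarding one tail of symmetric read
  noise around zero conversion would bias the slope (measurably, ~3 %
  at k = 10² M⁻¹s⁻¹ with 1 % noise). Strongly negative values are
  excluded as outliers.
* The degenerate case [IN]₀ = [Ai]₀ (never used by the standard
  designs, which fix 1.5:1) falls back to the equal-concentration law
  1/([Ai]₀ − [OUT]) − 1/[Ai]₀ = k t rather than dividing by zero.
* A fit with r² below 0.9 is flagged as deviating from second-order
  kinetics but still reported as second-order, keeping the rate table
  uniform; negative fitted slopes are reported as failed fits, never
  clamped.

Replicates are always fitted independently and summarized as
mean ± sd (sd requires ≥ 2 successful replicates); there is no pooled
global fit.

## Derived quantities

Discrimination factors DF = k_match/k_mismatch and generic rate ratios
carry first-order propagated uncertainties,
sd(r) = r·√((sd₁/k₁)² + (sd₂/k₂)²). When the denominator fit fails or
falls below the resolvability floor (default 10 M⁻¹s⁻¹, roughly the
smallest rate producing measurable conversion over a 10⁴ s window at
these concentrations), the ratio is reported as a lower bound
("DF > X") computed against the floor, never as a number. The
toehold-length dependence is an ordinary least-squares line through
log₁₀ k versus toehold length; its slope (decades per nucleotide) and
10^slope (fold change per nucleotide) summarize the exponential rate
tuning.

## Two-state melting and van't Hoff analysis

Toehold association is modeled as A + B ⇌ AB between two non-identical
strands each at C_t/2, with K(T) = exp(−ΔG°(T)/RT), ΔG°(T) = ΔH° − TΔS°
(kcal units, R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹). The bound fraction θ(T)
solves the mass-action quadratic, evaluated in a cancellation-free form
valid from K → 0 to K → ∞. Melt wells are simulated as the free-dye
signal attenuated by (1 − q·θ(T)) where q is the quench efficiency;
the positive control carries the same linear temperature drift of the
free dye, so the ratio correction

    F_corr = (F_melt − F_bkgnd) / (F_pos − F_bkgnd)

cancels the drift identically. Equilibration at each temperature step
is assumed complete; only equilibrium θ(T) is simulated.

Tm is extracted as the linearly interpolated zero crossing of the
second central finite difference of F_corr(T), choosing — when noise
produces several crossings — the one nearest the maximum of the first
derivative (the transition's inflection region). A 3-point
moving-average pre-smoothing is applied by default for measured/noisy
curves and disabled for noiseless synthetic curves.

The concentration dependence of Tm across the ladder
C_t ∈ {0.5, 1, 2, 3, 4, 6} µM (10→70 °C in 2 °C steps) is regressed as
1/Tm on ln C_t and inverted through

    ΔH° = (n−1)R/slope,   ΔS° = intercept·ΔH° + (n−1)R·ln(2n),   n = 2,

with ln 2n read as ln(2n) = ln 4 — the standard non-self-complementary
form 1/Tm = (R/ΔH°)ln(C_t/4) + ΔS°/ΔH°. This reading is verified
internally: the generator's θ = ½ temperatures fall on exactly this
line (residual < 10⁻¹⁶ K⁻¹ across the six concentrations). ΔG° is
reported at 310.15 K (37 °C, the reaction temperature) by default.
Replicate Tm values at the same concentration are averaged before the
regression; per-replicate regression is available via a flag. Single
curve baseline-fitting van't Hoff analysis and heat-capacity (ΔCp)
corrections are deliberately out of scope.

**Known systematic: inflection vs midpoint.** The second-derivative Tm
is the curve's inflection, which for an asymmetric two-state
bimolecular transition sits above the θ = ½ temperature — by +1.40 °C
(continuous limit) for ΔH° = −60 kcal/mol, ΔS° = −0.160 kcal/(mol·K),
C_t = 2 µM; the discrete estimator lands at +1.2–1.3 °C on the 2 °C
grid. Because the offset is nearly constant across the concentration
ladder it cancels almost entirely in the van't Hoff slope: the
noiseless pipeline recovers ΔH° to ~0.3 % and ΔS° to ~0.8 %. Users
comparing per-concentration Tm values against midpoint-defined
predictions should expect this offset.

## Synthetic-data generator and what passing tests show

The generator emulates: mass-action kinetics of the two-step cascade at
the two standard concentration regimes (150/100/300 nM and 30/20/60 nM
input/gate/reporter, 37 °C); a pre-activated control simulated as
instantaneously complete (its brief equilibration transient is not
modeled); a no-input negative control and an empty-well background;
two-state bimolecular melt ladders with free-dye drift; and additive
i.i.d. Gaussian read noise applied to fluorescence only (default sd
1 % of the pre-activated amplitude), never to the chemical state, so
mass conservation is exact in every trajectory. Noise streams are
spawned per well from a single seed; runs are bit-reproducible.

It does **not** emulate: sequence-dependent energetics (no
nearest-neighbor model, no base-pair-resolution branch migration, no
secondary-structure prediction — homo- vs heterochiral configurations
and RNA vs DNA inputs differ only through the supplied k, ΔH°, ΔS°);
pipetting/mixing dead time; photobleaching or drift in the kinetic
traces; correlated or multiplicative noise; surface losses (the carrier
oligonucleotide is assumed fully effective); or slow melt
equilibration. Passing round-trip tests therefore demonstrate that the
estimators are unbiased and correctly calibrated for data that obey the
stated model at realistic noise levels — not that real traces are free
of the unmodeled effects; the r² deviation flag and intercept
diagnostic exist to surface such effects on measured data.

Default simulation sizes used by the test suite and acceptance script:
~400 time points per trace with the observation window scaled to ~20
pseudo-first-order timescales (clamped to 600–10⁴ s), 3 replicates per
condition, 20 seed repetitions for coverage statistics, and the 6-point
melt ladder — small enough to run the whole suite in seconds while
leaving each fit strongly over-determined.

## ODE integration

The reporter-coupled system is integrated with LSODA (relative
tolerance 10⁻⁸, absolute tolerance 10⁻¹²·[Ai]₀): with k_rep up to 10³×
the displacement rate the system is stiff and an explicit method would
need prohibitively small steps. The independent single-step oracle used
for verifying the closed form is explicit RK45 at relative tolerance
10⁻¹⁰; the two agree with the closed form to ≤ 10⁻¹⁰ relative across
k ∈ 10²–10⁶ M⁻¹s⁻¹ and both concentration regimes. Transient
integrator excursions below zero are clipped only within 10⁻⁶·[Ai]₀;
anything larger raises.

## Pipeline conventions

Manifests and configs are YAML; all tabular artifacts are CSV with
documented headers. Concentrations are nM (kinetics) and µM (melts) at
the file interface and molar internally; temperatures °C at the
interface, K inside thermodynamic formulas. Reports contain no
timestamps, sort their keys and fix row order, so identical inputs,
seed and config produce byte-identical outputs; a provenance block
records the manifest/config hash, seed and package version. Validation
failures are reported en masse before any fitting, and an individual
failed well never aborts sibling conditions.

The fixture scenarios encode the standard experimental designs with
ground truth recorded in a sidecar: a 0–10 nt toehold ladder
(log₁₀ k = 1.5 + 0.35·length), a mismatch panel with rate contrasts
{5.8, 20.8, 29.4, 36.1} plus one unresolvable mismatch, incumbent-
toehold (toehold-exchange) slowdowns of 30× (homochiral) vs 2.5×
(heterochiral) at the 8-bp incumbent toehold, RNA/DNA input
accelerations, and a strong/weak melt ladder pair (ΔH° = −65 vs −57
kcal/mol, ΔS° = −0.175 vs −0.1565 kcal/(mol·K)) whose Tm separation at
2 µM is ≈ 11 °C. The melt-pair values are synthetic, plausible
parameters — stand-ins chosen for a clear strong/weak contrast, not
measured constants.
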