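# strandkinetics

Analysis toolkit for the kinetics and thermodynamics of toehold-mediated
strand displacement from PNA–DNA heteroduplexes — the reaction at the
heart of "heterochiral" DNA nanotechnology, where an achiral peptide
nucleic acid (PNA) strand lets a native d-DNA/RNA input release an
incumbent strand of either handedness from an inversion gate.

The package turns raw plate-reader fluorescence into second-order rate
constants and derived design quantities, and fluorescence melt ladders
into toehold-binding thermodynamics:

* **Normalization.** Each reaction trace is referenced to time-matched
  controls, F_n = (F − F₀)/(F_c − F₀), where F_c is a pre-activated
  reporter (maximal signal) and F₀ a no-input well (quenched baseline).
  This makes every downstream fit invariant to instrument gain.
* **Rate fitting.** Displacement of the gate Ai by input IN is treated
  as a single irreversible bimolecular step. Slow reactions are fit via
  the linearized integrated law

  ln[ (([Ai]₀ − [OUT])[IN]₀) / (([IN]₀ − [OUT])[Ai]₀) ] = ([Ai]₀ − [IN]₀)·k·t,

  fast reactions by nonlinear least squares of the equivalent closed
  form [OUT]_n(t) = [IN]₀(1 − e^u)/([IN]₀ − [Ai]₀e^u), u = kt([Ai]₀ − [IN]₀).
  Routing is automatic on the final conversion; replicates are fitted
  independently and summarized as mean ± sd.
* **Derived summaries.** Mismatch discrimination factors
  DF = k_match/k_mismatch (with a "DF > X" bound when the mismatched
  reaction is unresolvable), semilog toehold-length regression
  (log₁₀ k linear in toehold length), and generic rate ratios
  (k_RNA/k_DNA, k_short/k_long) with first-order error propagation.
* **Melting thermodynamics.** Melt wells are ratio-corrected,
  F_corr = (F_melt − F_bkgnd)/(F_pos − F_bkgnd); Tm is the zero crossing
  of the second derivative of F_corr(T); and regression of 1/Tm on
  ln C_t across a concentration ladder yields ΔH°, ΔS° and ΔG°(37 °C)
  through the bimolecular van't Hoff relation
  1/Tm = (n−1)R/ΔH°·ln C_t + [ΔS° − (n−1)R ln 2n]/ΔH° with n = 2.
* **Synthetic data.** A seeded generator produces the four-well trace
  sets (mass-action ODEs for the displacement + reporter cascade) and
  two-state melt ladders with instrument baseline, gain, drift and read
  noise, so every stage is testable end-to-end without instrument data.

The fitting operations are scikit-learn-style estimators
(`SecondOrderRateFit`, `ToeholdLengthRegression`, `TmEstimator`,
`VantHoffRegression`) with module-level convenience functions.

## Worked example

Generate a synthetic mismatch panel (matched input plus toehold and
branch-migration mismatches, three replicates each at 150/100/300 nM
input/gate/reporter with 1 % read noise) and analyze it:

```python
import strandkinetics as sk

sk.make_fixtures("mismatch_panel", seed=1, out_dir="demo")
report = sk.run_all("demo/manifest.yaml", out_dir="demo/report")
print(report.tables["discrimination"][["label", "df", "df_sd", "is_bound", "display"]]
      .to_string(index=False))
```

```
      label          df    df_sd  is_bound    display
  MM_A_homo    5.819161 0.052214     False  DF = 5.82
  MM_B_homo   20.822340 0.167982     False  DF = 20.8
MM_A_hetero   29.277534 0.177489     False  DF = 29.3
MM_B_hetero   36.003413 0.285664     False    DF = 36
MM_C_hetero 1996.283417      NaN      True DF > 2e+03
```

The generator encoded matched/mismatched rate contrasts of 5.8, 20.8,
29.4 and 36.1; the pipeline recovers each within a few percent, and the
deliberately unresolvable mismatch (k far below the 10 M⁻¹s⁻¹
resolvability floor) is reported as a lower bound rather than a number —
the convention used for fully inhibitory mismatches.

The same workflow is available from the shell:

```bash
strandkinetics simulate mismatch_panel --seed 1 --out demo
strandkinetics fit-kinetics demo/manifest.yaml --out demo/report
strandkinetics simulate melt_ladder --seed 1 --out melts
strandkinetics fit-melt melts/manifest.yaml --out melts/report
```

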