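# Methods

## Network reduction

The 3-D CSF circulation is reduced to a two-node hydraulic network:
a ventricular node (volume `V_V`, pressure `P_V`), a cerebral-aqueduct
element, and a subarachnoid-space (SAS) node (pressure `P_S`).  The
reduction rests on two observations that the cohort data themselves
support: the SAS volume differs by less than ~2.4% between groups, so
the SAS can be treated as (nearly) rigid, while the ventricular system
differs by a factor ~13.9, so the compliant physics belongs at the
ventricle.  The governing equations are

* ventricle mass balance: `dV_V/dt = Q_in − Q_aq − Q_leak`
* aqueduct momentum:      `L dQ_aq/dt + R Q_aq = P_V − P_S`
* SAS balance:            `C_S dP_S/dt = Q_aq + Q_leak − ΣQ_out`

with `R = 8μl/(πa⁴)` (Poiseuille) and `L = ρl/(πa²)`.  In FSI mode
`P_V` follows the viscoelastic cavity law below; in CFD (rigid) mode
`dV_V/dt = 0` and `P_V` becomes an algebraic unknown.  Outlets are a
constant-pressure resistance (schemes A/B) or prescribed waveforms
(scheme C).

## Constitutive model

Brain tissue is linear viscoelastic with Prony relaxation
`Gr(t) = G₀(1 − Σ gₖ(1 − e^{−t/τₖ}))`, `G₀ = E/2(1+ν)`.  The printed
material data give a single relaxation amplitude (0.285) and three
relaxation times; following the convention of the material-data source
the amplitude applies to each branch, so `Σgₖ = 0.855` and
`Gr(∞) = 0.145 G₀ ≈ 31.4 Pa`.  This is configurable per branch.

The ventricular compartment is mapped to a pressurized spherical
cavity in an unbounded medium, `ΔV/V₀ = 3Δp/(4G)`, extended to
viscoelasticity by the correspondence principle:

```
P_tm(t) = 4/(3V₀) ∫₀ᵗ Gr(t−s) (dV/ds) ds
```

The hereditary integral is evaluated by one internal variable per
Prony branch with the exact exponential update for piecewise-linear
volume histories — unconditionally stable, O(1) memory, and within
0.02% (L2) of the continuous solution at dt = 0.01 s.  No finite-shell
or skull-confinement correction is applied; see Limitations.

A Darcy pathway through the parenchyma (conductance `kA/L`,
permeability 4.08e-12 m⁴/(N·s)) can be switched on in parallel with
the aqueduct; it is **off by default** because the network topology
gives no quantified trans-parenchymal route.  The Prony compliance and
the Darcy leak are treated as parallel mechanisms.

## Boundary-condition schemes

* Scheme A's sinusoidal pressure `80 + 160 sin(2πt)` Pa is applied as
  *gauge* pressure riding on the subject's baseline `P₀`, feeding the
  ventricle through a production resistance `R_prod` (default
  1e9 Pa·s/m³).  A pressure BC needs a flow law to enter a network
  model, and in the original pressure-gradient-only setting the
  absolute level of this function is arbitrary; anchoring it to the
  node baseline yields a physiological mean inflow
  (~0.5 ml/min with the default resistances).
* Schemes B/C superpose the constant production rate 0.35 ml/min with
  a normalized pulsatile shape (zero cycle mean, unit peak).  The
  pulsatile amplitude is a subject-level parameter; nothing in the
  printed record fixes it, so the synthetic generator calibrates it
  against a stroke-volume target (below).
* Scheme C's outlets reuse the inlet waveform scaled by the mean-flow
  fractions 0.18/0.35 and 0.17/0.35, so instantaneous and mean mass
  balance track the inlet by construction.
* The cardiac period defaults to 1 s (implied by the dimensionally
  bare `sin(2πt)`); all waveforms are defined on normalized phase.

## Numerical scheme and defaults

Backward (implicit) Euler, dt = 0.01 s, five cardiac cycles; the last
cycle (samples in `[4T, 5T)`, half-open) is reported.  The network is
linear, so each step is a single 3×3 solve; the matrix is constant and
prefactored, and one iterative-refinement pass keeps the discrete mass
balance at ~1e-11 of peak flow.  The initial state is the quasi-steady
operating point (mean flow through the resistive chain), and the
cavity's reference volume is taken as the imaged geometry *at that
operating point* — i.e., the tissue is equilibrated to its baseline
load.  Without this choice the 410-s Prony branch superimposes a slow
creep transient that has nothing to do with the cardiac-cycle
dynamics.  With it, cycles 4 and 5 agree to ≲0.4% on default
configurations (measured over node pressures, aqueduct flow, and
ventricular volume; prescribed inlet and slaved outlet series carry no
independent state and are excluded).

Other defaults: SAS compliance `C_S = 1e-9 m³/Pa` (a small bookkeeping
compliance that lets prescribed-flow imbalance integrate to a bounded
pressure oscillation — a modelling device, not a measured quantity);
outlet resistance 8e9 Pa·s/m³ (≈1 mmHg per ml/min, chosen so that the
mean operating pressure sits tens of Pa above baseline, the scale of
the reported group values); aqueduct length 15 mm; aqueduct radius
1.0 mm (healthy) / 1.5 mm (patient), unconstrained by the printed
record; outlet baselines 500 / 2700 Pa (healthy / patient).
Scheme C with `C_S = 0` is rejected: the pressure level would be
undefined.

Degenerate inputs: zero inflow with zero amplitude reproduces the
baseline state exactly; non-finite states abort with the step index;
`dt` must divide the period.

## Metrics

Stroke volume is computed from the areas above (`A⁺`) and below (`A⁻`)
the flow-rate axis with trapezoidal quadrature split exactly at linear
zero crossings.  Two conventions are reported: `difference = A⁺ − A⁻`
(the net volume per cycle, which telescopes to mean·T and is pinned to
the production rate) and `oscillatory = (A⁺ + A⁻)/2` (the shuttled
volume).  The literal net-difference reading cannot differ ~7.9-fold
between groups at a fixed production rate, so the oscillatory
convention is the default for group-ratio analyses; both numbers are
always available.  Peak phases are argmax/argmin over the last cycle
with ties broken earliest.  Peak aqueduct velocity converts element
flow to centreline velocity either parabolically (`2Q/(πa²)`) or by
reconstructing the Womersley profile from the flow's Fourier
harmonics.

## Statistics

Descriptives use the sample SD (n−1), `CV = 100·SD/mean`, and t-based
95% CIs (`mean ± t₀.₉₇₅,ₙ₋₁·SE` — the t quantile, not the normal
approximation, is what reproduces the printed intervals).  Pearson r
carries the two-sided p from the t transform.  Shapiro–Wilk gates the
parametric tests; ANOVA + Tukey HSD (α = 0.05) and pooled-variance
Student's t (with a two-sided variance-equality F test reported as a
gate, never as an automatic switch) complete the layer.  scipy.stats
and statsmodels provide the standard machinery.

### Claim arithmetic and rounding

All claim checks round half-up at the printed precision with a
tolerance of one unit in the last printed digit.  Volume claims use
the printed (1-decimal) group means — the ventricular ratio is
281.6/20.3 = 13.87 → 13.9, whereas unrounded means give 13.84 → 13.8,
which shows the source's own arithmetic was on printed means.
Pressure ratios and ICP agreement use the per-subject rows, with
group-mean comparison for the ICP claims (simulated means over 11
patients vs the measured mean over the 10 instrumented patients; the
per-patient reading does not reproduce the printed percentages).  The
scheme-A ICP figure (recomputed 36.15%) sits exactly on a rounding
boundary and is flagged `borderline`.

### Documented source discrepancies

* The measured-ICP 95% CI is typeset in the source table with both
  bounds equal to the mean (2638.5/2638.5), which is impossible for
  SD > 0; the correct n = 10 interval is (2553.5, 2723.5).  The
  fixture stores the printed cells verbatim with a `ci_misprint` flag;
  the regression check skips the two flagged cells and asserts the
  correctly recomputed interval instead.
* The printed Pearson coefficients (0.47, 0.66, 0.81 for schemes
  A/B/C) are **not derivable from the printed per-subject rows**,
  which are stated to be their raw data: recomputation gives 0.31,
  0.33, 0.73, and no alternative reading (dropping the 11th patient,
  rank correlation, other variable pairings, pooling groups)
  reproduces the printed triple.  The claims report carries these
  three claims with an `irreproducible` flag, excluded from the
  reproduction gate; the derived *reduction* claims (42.0% and 18.5%)
  are the source's own arithmetic on its printed coefficients and do
  reproduce.  One acceptance test asserts the printed 0.81 as stated
  and is expected to fail, documenting the discrepancy rather than
  hiding it.

## Synthetic cohort

The generator emulates exactly the statistical structure the pipeline
consumes: truncated-normal (±3 SD, re-draw) compartment volumes at the
cohort tables' group (mean, SD) anchors; baseline pressures 500 /
2700 Pa; measured ICP for patients at (2638.5, 118.8) Pa; a
cosine-series waveform whose harmonics all peak at 17.5% of the cycle
(the observed timing of peak aqueductal velocity) with seeded
amplitude perturbations; and an oscillatory stroke-volume target of
0.04 ml/cycle (healthy — the scale MRI studies report) and 7.9× that
(0.316 ml) for patients.  Only the ratio is anchored by the study
record; the absolute levels are conventions.  Each subject's amplitude
is calibrated with one pilot run of the scheme-C FSI solver and a
linear rescale (the oscillatory response is linear in the amplitude);
the achieved stroke volumes land within ~2% of target and the default
cohort's group ratio within [7.0, 8.8].

What the generator does **not** emulate: MRI acquisition noise,
subject-specific waveform morphology beyond the harmonic family,
within-subject correlation between volumes and pressures, or any 3-D
geometric variability.  Tests that pass on synthetic cohorts therefore
validate the pipeline's plumbing and statistical behaviour, not the
physiological fidelity of any individual subject.

## Known limitations

* The unbounded-medium spherical-cavity compliance ignores skull
  confinement and therefore overestimates ventricular compliance,
  especially for ventriculomegalic patients; under scheme B this makes
  the compliant ventricle absorb most of the prescribed inlet
  pulsation.  Scheme C, whose prescribed outlets anchor the flow, is
  the default for stroke-volume work for exactly this reason.
* Absolute simulated pressures under flow-type inlets depend on the
  baseline-pressure parameter and the bookkeeping compliance `C_S`;
  only pressure *changes* are physical.
* The per-subject aqueduct geometry is not in the printed record, so
  absolute Reynolds numbers are order-of-magnitude only; group
  *differences* in the claims layer come from the printed group means.
* Mesh-convergence data are shipped as a reference fixture only; no
  3-D meshing is performed.
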