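# csfbc

Reduced-order simulation and statistical analysis of cerebrospinal-fluid
(CSF) dynamics in hydrocephalus under three alternative inlet/outlet
boundary-condition (BC) schemes.

## The problem

In computational models of hydrocephalus, the choice of inlet/outlet
boundary conditions dominates the predicted CSF pressures, while
flow-derived quantities (aqueductal stroke volume, Reynolds number,
peak velocity) are comparatively insensitive to it.  `csfbc` packages a
desk-scale version of that comparison for three canonical schemes:

* **Scheme A** — sinusoidal inlet pressure `80 + 160 sin(2πt)` Pa
  (gauge), constant outlet pressure (500 Pa healthy, 2700 Pa patient);
* **Scheme B** — pulsatile inlet flow with cycle mean 0.35 ml/min
  (the physiological CSF production rate), same constant-pressure
  outlet;
* **Scheme C** — the same pulsatile inlet flow with pulsatile *outlet*
  flows of means 0.18 ml/min (sagittal sinus) and 0.17 ml/min (spinal
  canal), so mean mass balance holds by construction.

The package is aimed at researchers who want a transparent, fully
testable counterpart to heavyweight 3-D fluid–structure-interaction
(FSI) solvers: every governing element has a closed-form oracle, and
the complete cohort statistics layer reproduces the published summary
tables and derived claims bit-for-bit from bundled per-subject data
(8 healthy subjects, 11 hydrocephalus patients).

## The model

The CSF pathway is reduced to a two-node hydraulic network,

```
inlet → [ventricle] → aqueduct (R, L) → [SAS] → outlets
```

with Poiseuille resistance `R = 8μl/(πa⁴)` and inertance
`L = ρl/(πa²)` for the cerebral aqueduct (CSF: ρ = 998.2 kg/m³,
μ = 0.001 Pa·s, Newtonian).  In **FSI mode** the ventricular wall
carries the poro-viscoelastic compliance of brain tissue: a
pressurized spherical cavity (`ΔV/V₀ = 3Δp/4G`) whose shear modulus
relaxes along a three-branch Prony series

```
Gr(t) = G₀ (1 − Σₖ gₖ (1 − e^{−t/τₖ})),   G₀ = E / 2(1+ν)
```

with E = 584.4 Pa, ν = 0.35, gₖ = 0.285, τ = (3.1, 27, 410) s, so
Gr(∞) = 0.145 G₀.  The hereditary integral is evaluated by an exact
per-branch exponential-integrator recursion.  In **CFD mode** the
walls are rigid.  Time stepping is backward Euler (dt = 0.01 s, five
1-s cardiac cycles; the last cycle is reported).  The classical
Womersley solution for oscillatory tube flow is included as an
independent analytic oracle.

Hydrodynamic metrics: aqueductal stroke volume from the positive and
negative areas of the flow-rate diagram (both the net-difference and
the oscillatory convention), `Re = ρuD/μ`, peak values with their
phase in the cardiac cycle, and rigid-vs-compliant run comparison.
The statistics layer provides descriptives (mean, SD, SE, CV%,
t-based 95% CI), Shapiro–Wilk, one-way ANOVA + Tukey HSD,
pooled-variance Student's t with a variance-equality gate, Pearson
correlation, and a claims report that recomputes every derived
in-text number from the bundled tables.

A seeded synthetic-cohort generator draws subjects whose compartment
volumes match the bundled tables' group summaries and calibrates each
subject's waveform amplitude so the oscillatory aqueductal stroke
volume hits its group target (patient/healthy ratio ≈ 7.9).

## Worked example

```python
from csfbc import (CohortSpec, FluidProperties, generate_cohort, subject_network,
                   simulate, summarize, load_cohort_fixture, descriptives, claims_report)

cohort = generate_cohort(CohortSpec(seed=42, n_healthy=1, n_patients=1))
patient = cohort[-1]
result = simulate(subject_network(patient, scheme="C", mode="FSI"))
h = summarize(result, a=patient.aqueduct_radius, fluid=FluidProperties())
print(f"oscillatory stroke volume: {h.stroke_volume_oscillatory_ml:.3f} ml")
print(f"peak SAS pressure: {h.peak_pressure_Pa:.1f} Pa at {h.peak_pressure_phase:.0%} of the cycle")
print(f"peak aqueduct velocity: {100*h.peak_velocity_m_s:.1f} cm/s (Re_max = {h.reynolds_max:.0f}, laminar={h.laminar})")

t2, t3 = load_cohort_fixture("healthy"), load_cohort_fixture("patient")
d = descriptives(t2.values("max_pressure_SAS_BC_A_Pa"))
print(f"healthy SAS, scheme A: mean {d.mean:.1f} Pa, CI ({d.ci_lower:.1f}, {d.ci_upper:.1f})")
c = claims_report(t2, t3)["ventricular_volume_ratio"]
print(f"ventricular volume ratio: {c.computed_rounded} (printed {c.printed}, passed={c.passed})")
```

prints

```
oscillatory stroke volume: 0.316 ml
peak SAS pressure: 2738.5 Pa at 33% of the cycle
peak aqueduct velocity: 52.4 cm/s (Re_max = 1566, laminar=True)
healthy SAS, scheme A: mean 650.0 Pa, CI (597.7, 702.3)
ventricular volume ratio: 13.9 (printed 13.9, passed=True)
```

The synthetic patient's stroke volume lands on its calibrated 0.316 ml
target; its peak SAS pressure sits a few tens of Pa above the 2700 Pa
patient baseline (flow–flow BCs pin the pressure level near baseline);
the flow stays laminar; and the cohort-table statistics reproduce the
printed summary cells exactly.

There is also a CLI:

```sh
csfbc reproduce --out report.json            # claims report, exit 0 iff all pass
csfbc stats --fixtures --out cells.json      # cell-by-cell table regression
csfbc synth --seed 42 --out cohort/          # synthetic cohort
csfbc simulate --config run.yaml --out result.json
csfbc metrics --result result.json --out metrics.csv --radius-mm 1.5
csfbc pipeline --seed 42 --out artifacts/    # synth → simulate → metrics → stats
```

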