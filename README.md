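# evquant

Quantification of extracellular-vesicle (EV) subtypes from dSTORM
single-molecule localisation data.

Chip-based super-resolution imaging of immunocaptured EVs produces, per
field of view (FOV), a table of emitter localisations in three channels: a
pan-EV membrane stain, the CD9/CD63/CD81 tetraspanin trio (TT), and a cargo
marker of interest (e.g. pan-citrullination or citrullinated histone H3).
`evquant` turns those tables into biology: which particles are EVs, what
co-labelling subtype each belongs to, whether a lane contains real signal
over its empty-lane control, how strongly two conditions differ in cargo
labelling, and whether their size distributions differ.

Because raw localisation data from such experiments is rarely deposited,
the package ships a first-class synthetic-data generator that emulates the
statistical structure the analysis assumes (rim-labelled discs, lognormal
diameters with a ~137 nm mode, 15–20 nm localisation precision, Bernoulli
marker carriage, uniform background), with full ground truth for
parameter-recovery testing.

## The analysis

- **Particle detection and sizing.** Membrane-channel localisations are
  clustered with DBSCAN (the cargo channel never defines particles); each
  cluster's pan-EV localisations give a convex-hull area *A* and the
  equivalent circular diameter *d* = 2√(*A*/π).
- **Precision size-bias model.** A rim-labelled vesicle of true radius *R*
  imaged at localisation precision σ has RMS radial spread √(*R*² + σ²), so
  the apparent diameter is *d*<sub>obs</sub> = 2√(*R*² + σ²): a bias of
  8–14 nm for 50 nm EVs falling to ~3–5 nm at 150 nm.
- **EV calling.** Particles are kept when *d* < 500 nm and an EV marker
  count exceeds 5 (strict); cargo positivity needs a count above 2. Retained
  particles are partitioned into
  {panEV-only, TT-only, panEV+TT} × {cargo+, cargo−}.
- **Detection gate.** Per-FOV EV counts are compared with the empty-lane
  control by a one-sided two-sample Kolmogorov–Smirnov test
  (D⁺ = max<sub>t</sub>[F<sub>ctrl</sub>(t) − F<sub>sample</sub>(t)]); the
  p-value is an exact permutation enumeration at the 6–12 FOVs typical of a
  lane, and the lane is analysed only when p < 0.01.
- **Bayesian proportion comparison.** Cargo-positive/negative counts update
  a uniform Beta(1, 1) prior. Lanes are compared by the Monte Carlo
  distribution of *p*₁ − *p*₂ (200 000 draws; mean and 95% credible
  interval) and by quadrature of
  P(*p*₁ > *p*₂) = ∫₀¹ pdf₁(x)·CDF₂(x) dx, with a two-sided summary
  p_same = 2·min(P, 1 − P); zero-event lanes and a no-signal null
  (α = 0, β = β₁) are handled exactly.
- **Size-distribution comparison.** Two-sided two-sample KS test, followed
  by a bootstrap estimate of the median difference (10 000 replicates, 95%
  percentile interval); per-group profiles are reported as the median with
  central 67% and 95% empirical intervals.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_bayes_comparison.py` (120/400 cargo-positive particles
in a permeabilised lane vs 30/380 non-permeabilised) prints:

```
posterior means: perm 0.301, non-perm 0.081
difference p1-p2: +0.220 (95% CrI +0.168 to +0.272)
P(p1 > p2) = 1.000000, p_same = 0.00e+00
-> most cargo is intraluminal: permeabilisation exposes far more label
```

The difference estimate says permeabilisation raises the labelled fraction
by ~22 percentage points; the exceedance probability makes the direction
essentially certain.

A full run (`python examples/06_full_pipeline.py`, or
`evquant run --config run.yaml --out-dir out/` from the shell) simulates
two lanes plus an empty-lane control, gates them, and compares them:

```
status: ok  (excluded: none)
gate perm: D+=1.00 p=1.08e-03 -> pass
gate nonperm: D+=1.00 p=1.08e-03 -> pass
perm vs nonperm: diff +0.318 [+0.242, +0.393], P(p1>p2)=1.0000, p_same=6.66e-16
nonperm vs null: P(p1>null)=1.0000
sizes nonperm: median 183 nm, n=239
sizes perm: median 180 nm, n=226
size diff perm-nonperm: -3.1 nm [-14.8, +10.3] (KS p=0.96)
```

The two lanes differ sharply in cargo labelling (simulated truth: 0.4 vs
0.1) but share one size distribution, and the bootstrap interval for the
median difference correctly straddles zero.

## Layout

```
src/evquant/        library (synthetic data, clustering, calling, gate,
                    Bayesian comparison, size statistics, pipeline, CLI)
examples/           one narrative script per capability
tests/              pytest suite, including acceptance-level checks
docs/methods.md     models, assumptions, parameter choices, limitations
```
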