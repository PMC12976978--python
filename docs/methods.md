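# Methods

This note documents the models implemented in `evquant`, the parameter
choices that matter, and the places where the design was genuinely open.

## Synthetic localisation data

The generator emulates a chip lane imaged by dSTORM. Each field of view
(FOV) is a square of side `fov_size` (default 30 µm, a typical imaging
region); the number of EVs per FOV is Poisson with mean `mean_evs_per_fov`
(default 60, giving a surface density well below one particle per µm² so
particles rarely touch). Neither quantity is constrained by published
experiments, so both are explicit free parameters.

**Diameters** follow a lognormal law parameterised by its log-mean and
log-sd. The defaults (5.112887, 0.439211) were solved once so that the
distribution's mode is 137 nm and its standard deviation 84.4 nm, matching
nanoparticle-tracking profiles of cancer-cell EV preparations, and then
frozen. The implied median is ~166 nm with a tail reaching past 450 nm.

**Labelling.** Pan-EV and TT labels sit on the vesicle rim (membrane);
cargo labels are uniform over the disc interior. Per-channel localisation
counts are Poisson with means `rate_panEV` = 40, `rate_TT` = 25,
`rate_cargo` = 25 per labelled vesicle — tens of localisations per vesicle,
as expected when each fluorophore blinks repeatedly. TT and cargo carriage
are per-EV Bernoulli draws (`p_TT_positive`, `p_cargo_positive`);
permeabilised versus non-permeabilised conditions are represented purely by
different `p_cargo_positive` values, since the geometry of intraluminal
access is not otherwise quantified.

**Capture.** Tetraspanin capture retains TT-positive vesicles with
`p_capture_TT` (default 0.8) and TT-negative ones with a 10× smaller
non-specific probability, which is why TT-captured lanes still contain
pan-EV-only particles; phosphatidylserine capture retains all vesicles with
`p_capture_PS` (default 0.6) independently of tetraspanin status. Epitope
masking is not modelled by default; `tt_attenuation` exposes a
multiplicative hook.

**Noise convention.** `sigma_loc` (default 17.5 nm, the midpoint of the
15–20 nm precision range) is the *total* 2-D RMS localisation error: each
axis receives Gaussian jitter with sd `sigma_loc/√2`. Under this convention
the RMS radial spread of a rim at radius R is exactly √(R² + σ²), which is
the broadening assumed by the observed-diameter model below. Quoting the
per-axis sd instead would make the model's σ mean something different from
the generator's σ.

**Background** is a uniform spatial Poisson process per channel
(default 0.5 µm⁻²). Frames are assigned round-robin per channel; no drift
or blinking kinetics are simulated, and no z coordinate exists.

What the generator deliberately does *not* emulate: camera-frame rendering
and PSF fitting, emitter re-blinking correlations (every localisation is
independent), drift, chromatic offsets between channels, aggregates or
non-vesicular particles, and spatial inhomogeneity of capture. Tests that
pass on this generator therefore validate the *statistical machinery* —
clustering behaviour, filter logic, calibration of the inference — not the
robustness of the pipeline to optical artefacts in real recordings.

## Particle detection and sizing

Candidate particles are DBSCAN clusters (Euclidean, 2-D) over the union of
the pan-EV and TT channels; cargo localisations never participate in
cluster formation because the cargo channel is the measurand. Defaults:
`min_samples` = 3 and `eps` = 100 nm. The eps value is set by two
constraints: it must exceed the largest plausible gap between successive
rim localisations of a large vesicle (a 400–500 nm vesicle with ~50 rim
localisations has Poisson gaps that regularly exceed 50 nm, and a smaller
eps fragments single vesicles into several particles, inflating particle
counts by ~25% and diluting per-particle cargo proportions), and it must
stay far below the typical inter-particle spacing (>1 µm at the modelled
densities), which keeps merging negligible. Clusters are ordered by
centroid for determinism.

Each cluster is sized from the convex hull of its *pan-EV* members only:
area A, equivalent circular diameter d = 2√(A/π). Degenerate hulls
(coincident or collinear points, A = 0) fall back to the maximum pairwise
distance, and a cluster with no pan-EV member is sized from all EV-marker
members and flagged. The convex hull was chosen over an alpha hull because
it is parameter-free and deterministic; circularity (4πA/perimeter²) is
computed and carried along but no threshold is applied to it.

Localisations of every channel are then credited to particles by proximity:
a point is credited when within `assign_radius` (default 30 nm, roughly
1.5–2× the localisation precision) of any member point, nearest member
winning and exact ties resolved toward the lower cluster index. For large
vesicles the disc centre lies beyond 30 nm of any rim point, so a fraction
of interior cargo goes uncredited; at the default cargo rate this does not
affect positivity calls (which need only 3 credited localisations), but it
is the reason quantitative per-particle cargo *counts* should not be read
as absolute label numbers.

## The precision size-bias model

A rim-labelled vesicle of true radius R imaged with precision σ yields
localisations whose RMS distance from the centre is √(R² + σ²); the model
therefore predicts an observed diameter d_obs = 2√(R² + σ²) and a
systematic bias d_obs − 2R: 14 nm (σ = 20) or 8 nm (σ = 15) for a 50 nm
vesicle, shrinking to ~5 nm (σ = 20) or ~3 nm (σ = 15) at 150 nm.

A known limitation, documented rather than hidden: the *hull-based
estimator does not converge to this prediction*. The convex hull tracks the
extreme points of the noise distribution, so its expected support radius
grows like R + cσ√(ln n) with the number of localisations n. At n ≥ 50 the
mean hull diameter exceeds 2√(R² + σ²) by ~15–40% (worst for small R); the
two agree only around n ≈ 10–20, where the finite-sample hull deficit
happens to cancel the extreme-value overshoot. The RMS radius of the
clustered localisations, by contrast, matches √(R² + σ²) to within a
percent, and the test suite verifies exactly that closure. Comparative
size analyses between conditions acquired identically remain meaningful
because the inflation applies equally to all groups; absolute hull
diameters should be interpreted cautiously.

## EV calling

Filters follow the vendor-recommended particle criteria with strict
inequalities: diameter < 500 nm; an EV-characterisation channel (pan-EV or
TT, each judged independently, not summed) must exceed 5 labels for the
particle to be retained and for that channel to be called positive; the
cargo channel is positive above 2 labels. Cargo alone never defines a
particle. Retained particles are partitioned into the six subtypes
{panEV-only, TT-only, panEV+TT} × {cargo+, cargo−}; particles with a
degenerate (zero) diameter pass the one-sided diameter filter literally but
carry a flag and can be excluded with a toggle. Tabulation keeps all-zero
rows for empty FOVs so zero-event cases flow into the Bayesian stage.

## Detection gate

The gate asks whether a lane's per-FOV EV counts are stochastically greater
than the empty-lane control's, using
D⁺ = max_t [F_ctrl(t) − F_sample(t)] on right-continuous empirical CDFs
(ties in count data are handled naturally by this definition). Because
asymptotic KS p-values are unreliable at 6–12 observations, the p-value is
computed by full enumeration of all C(n₁+n₂, n₂) group assignments whenever
n₁+n₂ ≤ 16 (at most 12 870 assignments), and by the one-sided asymptotic
formula exp(−2D²n₁n₂/(n₁+n₂)) otherwise; the report records which method
produced the number. The gate passes strictly when p < 0.01. A consequence
worth knowing: with 3 vs 3 FOVs the smallest achievable exact p is 1/20, so
small designs can never pass — 6 vs 6 reaches 1/924 under complete
separation. Under the null the exact test is conservative (measured type-I
rate ~0.3% at the 1% threshold). No multiplicity correction is applied
across conditions.

## Bayesian proportion comparison

Counts are binomial with a uniform Beta(1, 1) prior throughout, so a lane
with s cargo-positive and f cargo-negative particles has posterior
Beta(s+1, f+1) — proper even at s = 0, which is the zero-event case the
machinery must handle. Posterior mean and variance use the closed forms
α/(α+β) and αβ/((α+β)²(α+β+1)). Real-valued pseudo-counts (e.g. means over
FOVs) are accepted.

Two lanes are compared by (i) the Monte Carlo difference distribution —
200 000 independent draws from each posterior, reporting the mean and the
2.5th/97.5th percentile credible interval (linear-interpolation quantiles;
the seed is a required, logged argument) — and (ii) the exceedance
P(p₁ > p₂) = ∫₀¹ pdf₁(x)·CDF₂(x) dx, evaluated by adaptive quadrature to
~1e-10 absolute tolerance with the posterior means supplied as break
points so sharply concentrated integrands are not missed. The two-sided
summary p_same = 2·min(P, 1−P) is this package's definition of a
significance-like number for "no difference"; it is labelled as such in all
outputs. The null comparison rebuilds the no-signal posterior from counts
(0, f₁), i.e. Beta(1, f₁+1), and runs the identical machinery. Which counts
feed a comparison is the caller's choice; the pipeline defaults to pooled
particle counts per condition rather than per-chip means, because pooling
keeps the binomial model exact.

## Size statistics

Distributions are compared with the standard two-sided two-sample KS test;
a `significant` flag records p < 0.05, after which the magnitude estimate
is the difference in medians with a 95% percentile bootstrap interval
(10 000 replicates, each group resampled with replacement at its own size,
deterministic given the required seed). The bootstrap always runs on
request — the interval is informative even when the KS test is not
significant. Per-group profiles report the median with central 67% and 95%
empirical intervals of the diameters themselves; the 67% interval is a
spread descriptor of the size distribution, deliberately distinct from the
bootstrap confidence interval of the median difference. All quantiles use
linear interpolation between order statistics.

## Pipeline and reproducibility

One condition = one lane (capture mode × permeabilisation × cargo marker).
A run validates its configuration exhaustively (never fail-fast), processes
every lane and the negative control identically, gates each lane, excludes
failing lanes from all comparisons (a `--force-gate` flag overrides this
for debugging), and writes particle tables, subtype tallies, gate,
comparison and size reports plus a manifest (config echo, SHA-256 of the
config, seed, package versions). Every stochastic stage receives an integer
seed below 2³¹ derived deterministically from the run seed by hashing the
stage label, so reruns are byte-identical and any single stage can be
reproduced in isolation.

## Problem sizes used in the test suite

The acceptance-level tests run at deliberately moderate scale chosen as the
package's own verification conditions: 50 random posterior pairs against
200 000-draw Monte Carlo and 2 000-replicate coverage for the Bayesian
engine; 2 000 null replicates at 6 vs 6 FOVs for the gate; 150 vesicles per
radius for the geometry loop; 20 seeded two-lane runs at 8 FOVs × ~100 EVs
for end-to-end recovery; and 300 simulations × 10 000 bootstrap replicates
for interval coverage. The full suite completes in about a minute on one
core.

## Known limitations

- Hull-based absolute diameters are inflated for well-sampled clusters (see
  above); only comparative size statements are calibrated.
- Localisation counts treat every blink as independent; real emitters
  re-blink, so label counts are not molecule counts and the positivity
  thresholds should be read as operational, not stoichiometric.
- The crediting radius truncates interior cargo for vesicles much larger
  than ~200 nm; positivity calls are robust to this, raw cargo counts are
  not.
- The synthetic generator's idealisations (no drift, no artefacts, disc
  geometry) mean green tests bound the statistical behaviour of the
  pipeline, not its performance on adversarial real-world data.
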