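# Methods

This note documents the models, defaults and numerical choices behind
`rotadapt`, and what its synthetic experiments do and do not show about real
reaching data.

## The synthetic experiment generator

### Design

The default design has four phases — 80 baseline trials with veridical
endpoint feedback, 240 rotation trials with the cursor rotated 30° clockwise,
40 aftereffect trials without feedback (participants instructed to drop any
strategy), and 40 washout trials with veridical feedback restored — 400
trials in total.  Eight targets lie 8 cm from the origin.  The sources this
paradigm descends from are ambiguous about target spacing (eight "equally
spaced" targets versus 22.5° separation); we place the 8 targets 45° apart,
and `n_targets` is configurable for other layouts.  Targets follow a
pseudorandom cycle structure: each target appears once per cycle, in a fresh
random order, before any repeats.

All angles are in degrees, counterclockwise positive, reported relative to
the target (target at 0°).  A clockwise cursor rotation displaces the cursor
to −30° relative to the hand, so compensation drives the hand direction
toward +30°.  Geometry is in screen centimetres throughout (8 cm target
distance); tablet units are never used.

### Behaviour model

Each simulated subject is a single-rate state-space learner with an explicit
strategy on top.  On trial *t* with feedback present, the implicit state
updates as

    x_{t+1} = a·x_t + b·e_t,        e_t = rot_t − (x_t + expl_t)

where `rot_t` is the active rotation (30 during the rotation phase, 0
otherwise) and `expl_t = g·(rot_t − x_t)` is the explicit component
(a fraction *g* of the remaining planned error strategically re-aimed).
During the aftereffect phase the explicit component is forced to zero
(instructed strategy removal) and the state decays as
`x_{t+1} = r_ae·x_t`.  The produced hand direction is

    hand_t = bias + x_t + expl_t + Normal(0, σ_trial)

The learning error `e_t` is the cursor error of the *planned* movement:
trial noise and the static perceptual bias do not enter the update.  This
keeps the small counterclockwise baseline offset stable across baseline and
washout — as observed empirically in this paradigm — and makes the
noise-free learning curve exactly equal to the iterated recursion, which the
tests exploit as an oracle.  Whether a ~20° adaptation asymptote (below the
full 30°) reflects capped explicit compensation or incomplete implicit
learning is not settled; the generator exposes both interpretations through
`explicit_gain`.

### Default calibration

Chosen once to reproduce the magnitudes typical of endpoint-feedback
rotation studies, and used by all default-condition tests:

| parameter | mean | between-subject SD | role |
|---|---|---|---|
| retention `a` | 0.98 | 0 | implicit state retention per trial |
| learning rate `b` | 0.025 | 0.005 | error sensitivity |
| explicit gain `g` | 0.65 | 0.05 | strategic share of remaining error |
| baseline bias | −2° | 1.3° | static perceptual offset |
| trial noise SD | 5° | 0.8° | motor noise per reach |
| aftereffect retention | 0.998 | 0.002 | no-feedback state decay |

These give an implicit asymptote `x* = c·30/(1−a+c)` with `c = b(1−g)` of
≈ 9.1°, a measured adaptation asymptote (bias + x* + explicit) of ≈ 20.7°,
and subject-level early-aftereffect means approximately Normal(7°, SD 2°)
(the bias and learning-rate variability combine to the 2° between-subject
SD of epoch means).  The group-level effect of feedback duration defaults to
zero — the null structure of interest; `duration_effect_deg` shifts a
group's implicit asymptote exactly, by solving for the learning rate that
moves `x*` by the requested amount.

### Trajectories

Reaches are minimum-jerk profiles, 8.4 cm amplitude, duration ~ N(430, 40) ms,
preceded by an origin hold of ~N(600, 120) ms, sampled at 200 Hz; the
closed-form speed `30·A·τ²(1−τ)²/T` gives the kinematics module an analytic
oracle.  A configurable 1% of trials is corrupted — a reach stopping at
7.0 cm, or a sharp mid-movement radial dip — so the exclusion logic is
exercised at the empirically reported ~1% rate.

### What the generator does not emulate

Real kinematic idiosyncrasies (curved paths, online corrections, target-
specific biases), any effect of feedback duration on proprioception or
explicit re-aiming, reward sounds, and feedback-delay manipulations.
Passing tests therefore show that the analysis chain recovers known
structure of this class of generative processes at realistic noise levels —
not that it is robust to every failure mode of real data.

## Kinematics

Speeds come from central finite differences of position (optional boxcar
position smoothing, off by default — empirical reports are typically silent
on smoothing).  Onset is the first sample at ≥ 10% of the trial's peak
speed; end is the first post-peak sample below that threshold.  The movement
direction is taken where the path crosses the target radius, using linear
interpolation between the straddling samples so the result is sampling-rate
independent; at 200 Hz the interpolation error against the commanded
direction is < 0.1°.  Angles are normalised to (−180°, 180°].

Exclusions follow two rules: radial distance not strictly increasing after
first exceeding 0.4 cm, and maximum radial distance below 7.6 cm.  Radial
decreases ≤ 0.01 cm are tolerated as jitter (configurable; 0 restores the
literal rule).  Trials slower than the 500 ms movement-time criterion are
flagged but *not* excluded — the exclusion set is exactly the two rules
above.  Excluded trials keep their epoch label and are dropped from model
input; adaptation epochs with exclusions are left short rather than
re-binned.

Epochs: baseline and aftereffect split at their midpoints, adaptation binned
into consecutive 8-trial epochs, washout one epoch — 35 epoch types under
the default design (40, 40, 8×30, 20, 20, 40 trials).

## The hierarchical model

Movement direction `y` of subject *s* (group *g*) in epoch *e*:

    y ~ Normal(μ_{s,e}, σ_s)
    μ_{s,e} = β₀ + α_e + γ_g + δ_{e,g} + u_s + v_{s,e}

Priors: `δ_{e,g} | λ_{e,g} ~ Normal(0, σ_δ²/λ)` with `λ ~ Gamma(ν/2, ν/2)` —
the scale-mixture representation of a Student-t(ν, 0, σ_δ) prior, letting
individual epoch×group cells escape shrinkage (the robustness that makes the
interaction coefficients informative); `u_s ~ Normal(0, σ_u²)` and
`v_{s,e} ~ Normal(0, σ_v²)` hierarchically (subject effects regress toward
the mean; `v` can be disabled for speed); `1/σ_s² ~ Gamma(a_τ, b_τ)` with a
lognormal hyperprior on the shape and a gamma hyperprior on the rate; broad
Normal(0, 50²) priors on β₀, α, γ and heavy-tailed inverse-gamma(0.5, 0.5)
priors on the squared scales.  The degrees of freedom are sampled with a
shifted-exponential prior (lower bound 2, prior mean 30), standard
robust-ANOVA practice; a fixed-ν mode (ν = 4) is available.  `scale_factor`
multiplies every prior range; doubling it changes posterior cell means by
< 0.1° on the default dataset (verified by test), which is the robustness
property the broad-prior choice is meant to deliver.

### Sampling

All location and scale parameters are conditionally conjugate, so the
sampler is a vectorised Gibbs sweep over per-(subject, epoch) sufficient
statistics, with two Metropolis-within-Gibbs steps (log-scale random walks
for ν and a_τ).  Additive models of this kind have likelihood-flat ridges
between fixed and random effects; the sweep therefore includes translation
moves — exact Gibbs draws along the one-parameter directions γ_g ↔ {u_s},
δ_{e,g} ↔ {v_{s,e}} and u_s ↔ {v_{s,·}} — which leave the likelihood
invariant and sample the ridge position from its conditional.  With these
moves the derived cell means reach effective sample sizes near the number of
draws; the weakly identified hyperparameters (ν, a_τ, b_τ) mix more slowly,
which does not affect the reported quantities.

Parameters are sampled unconstrained; stored coefficients are recentred per
draw to the sum-to-zero parameterisation, and the derived cell means
`m_{e,g} = β₀ + α_e + γ_g + δ_{e,g}` are invariant to the recentring.
Defaults are 4 chains, 1000 burn-in, 10,000 draws per chain; the reported
analyses in the test suite and acceptance script use 2–4 chains × 2500–5000
draws, which the cell-mean effective sample sizes comfortably support.  The
subject×epoch terms `v` are not stored draw-by-draw (only their scale), to
bound memory; `store_subject_means=True` stores the per-draw subject-epoch
means instead when needed.

Convergence is gated at split R-hat ≤ 1.01 for the reported cell means plus
a per-chain mean-agreement check (an automated, stricter stand-in for visual
chain inspection); the report lists R-hat and bulk ESS for every stored
parameter, and a single chain yields an explicit "undefined" flag rather
than a silent pass.  Correctness of the kernel is verified distributionally:
a term-by-term log-density oracle, a conjugate normal-means toy with
analytic posterior, duplicated-group symmetry, vanishing shrinkage at large
n, and 95% HDI coverage ≈ 95% over 50 replicate fits on data drawn from the
model itself.

## HDI and ROPE

The HDI is the shortest contiguous interval containing ⌈mass·n⌉ sorted
draws; ties in the window scan break to the lowest starting index, making
the result deterministic.  ROPE assessment (default −3° to +3°) reports two
quantities that the literature uses interchangeably but that differ:
the fraction of posterior *mass* inside the ROPE and the fraction of HDI
*length* inside it.  The mass fraction is the primary decision statistic;
the decision is `equivalent` only when the entire HDI lies inside the ROPE,
`not_equivalent` only when it lies entirely outside.  Summary tables label
the interval extent `hdi_width` explicitly because "mean ± x" conventions in
this literature report x as the full 95% HDI width, not an SD or SE.

## Sample-size procedure

The criterial-precision rule stops data collection when HDI widths fall
below preset criteria: 2.0° for each group's early-aftereffect mean and 2.5°
for each pairwise difference, assessed at the 90th percentile
(nearest-rank, deterministic on 10 replicates) of replicate datasets at each
candidate n ∈ {10, 15, 20, 25, 30}.  Datasets come either from the posterior
predictive distribution of a previous fit (the sequential procedure proper:
new subjects receive fresh hierarchical effects and precisions drawn from a
joint posterior draw) or from the generator (no prior fit needed; the
default for testing).  Refits use reduced sampler settings (2 × 2500 draws)
by default; a config switch restores full fidelity.  Non-convergent refits
are excluded with a logged count.  Under the default calibration the
expected group-mean width is ≈ 3.92·√(σ_b² + σ_w²/20)/√n ≈ 1.8° at n = 25;
hierarchical shrinkage makes fitted widths somewhat narrower (≈ 1.4–1.6°),
never wider, and difference widths exceed group widths by ≈ √2.  The
combined stopping rule (both criteria, default policy) recommends n = 25
per group under the default calibration; the mean-only criterion is reached
at n = 20 because of that shrinkage.

## Problem sizes used in tests

The test suite and acceptance script size their simulations for desk-scale
runs: the precision and recovery checks fit 25 subjects/group with 2 chains
× 2500 draws (the reported widths are posterior properties, not sampler
settings); the coverage calibration uses 50 replicates of a 3-group ×
6-subject × 5-epoch model at 2 × 800 draws; sample-size sweeps in tests use
reduced candidate lists, replicate counts and epoch subsets.  The acceptance
script fits the full 35-epoch, 75-subject model at 4 chains × 5000 draws.

## Known limitations

- The generator's subject-epoch structure is milder than real data's, so
  fitted HDI widths run ~15% below the independence closed form; real-data
  widths would sit closer to it.
- The Student-t interaction prior is exchangeable across all 105 cells; no
  structure (e.g. smoothness across adaptation bins) is imposed.
- No model comparison, no explicit/implicit decomposition model, no
  trial-level autoregressive errors, and no frequentist equivalence tests.
- The exact prior constants of the original JAGS implementations of this
  model family are not public in the papers themselves; the defaults here
  are broad by construction and validated by the prior-doubling invariance
  rather than by matching any particular file.
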