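# Methods

## The model

Each trial of a two-alternative motion-direction discrimination is modeled as
a Wiener diffusion: evidence starts at a fraction *z* of the boundary
separation *a*, accumulates with drift *v* and unit diffusion coefficient,
and the first boundary reached determines the response; response time is the
first-passage time plus a non-decision time *t0*. The package uses accuracy
coding: the upper boundary is the correct response, so *v* > 0 favors a
correct choice and *z* is a start-point bias toward correct. Drift rate is a
per-subject linear function of median-centered coherence (median 6.4% in the
reference design; a log-coherence link is available as a configuration
switch). The boundary is parameterized on the log scale, bias on the logit
scale, and *t0* = 0.001 s + offset with the offset strictly positive.

The defective first-passage density at the lower boundary is evaluated with
the standard dual series — the small-time image expansion and the large-time
Fourier sine expansion — choosing per evaluation whichever needs fewer terms
at truncation error 1e-7; the upper boundary follows from the reflection
identity f_upper(t; v, z) = f_lower(t; −v, 1−z). The defective CDF is the
term-wise integral of the large-time series with an adaptive term count and
an unreachable-region guard; choice probability and mean decision time use
the classical closed forms with series expansions near zero drift (switch at
|va| < 1e-8 and |v| < 1e-6). Exact sampling inverts the CDF on a dense
quadratically-spaced grid with two Newton polish steps; an independent
Euler–Maruyama simulator (with the Brownian-bridge mid-step crossing
correction, so its boundary-detection bias is O(dt) rather than O(sqrt dt))
exists purely as a cross-check and is never used by the likelihood path.

## Learning dynamics

A time-varying parameter follows

    param(n) = asymptote + (start − asymptote) · 2^((1 − n) / (2 + 2^rate)),

with *n* a 1-based trial index, so trial 1 returns the start exactly and the
time-to-half-of-change is T50 = 2 + 2^rate (always above 2 trials, which
keeps very fast trajectories identifiable). Four forms are supported:
constant; continuous (cumulative trial index); day-resetting (within-day
index, same curve every day); and flexible (within-day index, day-specific
starts and asymptotes, one shared rate per parameter per subject). The six
candidate models A–F pair these forms for drift rate and boundary:
constant/constant, continuous/continuous, continuous/day-resetting,
continuous/flexible, flexible/continuous, flexible/flexible. Both the drift
intercept and the drift~coherence slope follow the drift-rate form and share
its rate; the boundary trajectory evolves on the log scale (positivity by
construction; the nonlinear combination scale is a package choice, stated
here because only the link scale of the parameter itself is pinned down by
the estimation convention). Bias and non-decision time are constant in time
within subject. Nesting is exact: start = asymptote reduces any form to
constant, and tying per-day values reduces flexible to day-resetting.

## Priors

Drift-scale coefficients: student-t(3, 1, 10). Log-boundary coefficients:
normal(−0.6, 1.3). Logit bias: normal(0, 1). Non-decision offset:
exponential with mean 0.15 s. Rate parameters: normal with SD 1 centered on
the binary log of 25% of the relevant maximum trial number (the within-day
trial count for within-day forms, the total trial count for cumulative
forms), placing ±2 SD between the full timescale and 1/16 of it. The
drift~coherence slope has no pinned-down prior in the estimation convention
we mirror (its default there is improper-flat, unusable for initialization
or marginal likelihoods), so the package uses a weakly-informative
student-t(3, 0, 2.5); this matters only for initialization draws and the
Bayesian backend.

## Fitting

The default backend is per-participant maximum likelihood in an
unconstrained space (logit bias, log-scale boundary coefficients, rates raw,
and the non-decision offset through a scaled sigmoid enforcing
0.001 < t0 < min retained RT − 1e-4, since the likelihood is −inf beyond the
smallest RT). Multistart L-BFGS-B: candidates are an EZ-style moment-matching
heuristic, an optional warm start (e.g. a richer model initialized from the
constant model's fit via the exact nesting embedding), and seeded draws from
scale-shrunk priors (shrink 0.25 — raw draws from a scale-10 student-t are
useless starting points); the best `n_restarts` candidates by initial
objective are polished. Gradients are forward differences evaluated as one
batched likelihood call, which is what makes the dynamic models affordable.

One deliberate departure from pure ML: the rate parameters carry a Gaussian
ridge centered exactly on their priors above. Without it the likelihood has
a flat ridge — pushing T50 beyond the design length leaves the asymptote
unconstrained and estimates diverge (we observed fitted asymptotes of ~11
drift units against a truth of ~1.1). All other parameters are unpenalized,
`regularize_rates=False` restores pure ML, and reported log-likelihoods,
AIC and BIC always use the unpenalized objective at the estimate. The
logistic baseline applies the same ridge to its rates plus a weak
normal(0, 0.5) ridge on its z-scored-RT slopes, for the same reason.

The Bayesian backend samples the same transformed space (with the sigmoid
Jacobian) under the priors above using an affine-invariant ensemble sampler;
walkers serve as chains for R-hat and tail-ESS diagnostics (bar: R-hat
< 1.03), per-draw pointwise log-likelihoods are retained, and an empty table
yields a prior-only run. Hierarchy is approximated by independent
per-subject fits; the group covariate (game-player status) is carried as
additive fixed shifts in simulation and prediction, zero by default, and not
estimated in per-subject fits where it is unidentifiable.

## Model comparison

Bayesian fits are ranked by LOOIC from Pareto-smoothed importance sampling
(generalized-Pareto fit to the top 20% of importance weights per
observation; ≥100 draws required), with the SE of pairwise pointwise
differences and the "difference > 4 and larger than a couple of difference
SEs" interpretability annotation. MLE fits are ranked by AIC — the
asymptotic equivalent of leave-one-out cross-validation, hence the honest
desk-scale analogue of LOOIC — with BIC reported alongside; BIC's heavier
penalty at these sample sizes always prefers the constant model and cannot
recover dynamics.

Bayes factors come from iterative (optimal-bridge) bridge sampling with a
warped proposal: a multivariate normal moment-matched to half the posterior
draws, the other half entering the bridge. Independent subjects' log
marginal likelihoods add. Several runs (default 15) are performed and the
most equivocal base-3 log Bayes factor (closest to 0) is reported, so ±1
marks the conventional "substantial evidence" threshold; runs that fail to
stabilize are dropped, and fewer than two successes yields a ±inf sentinel
meaning the relative evidence could not be estimated. Convergence tolerance
(1e-8) and iteration cap (1000) are exposed.

## Synthetic data

The generator reproduces the reference design: per subject and day, a
balanced randomized schedule of 7 coherence levels (0.8–51.2%, 100 each on
the full 700-trial day), left/right directions 50/50. Responses are sampled
exactly from the Wiener first-passage distribution at each trial's
parameters (per-trial CDF inversion with Newton polish; the Euler simulator
is available as an independent fallback). A contaminant fraction (default
0.5%) replaces the RT with uniform(0.05, 3.0) and the response with a coin
flip, to exercise the exclusion filter.

Population defaults sit at the reference fixed-effect estimates where those
exist: drift intercept start 0.44 and change N(0.516, 0.175) between
subjects (asymptote mean ≈ 0.96), cumulative T50 of 1261 trials on the
2800-trial design, rescaled proportionally for shorter designs. Quantities
no analysis reports are package choices typical of dot-motion DDM fits:
coherence slope ~0.05–0.08 per %, log-boundary day levels declining from
~0.70 to ~0.40 (boundary ≈ 2.0 → 1.5) with within-day T50 of 150 trials on a
700-trial day, start SD 0.15, bias logit N(0, 0.2), non-decision time
~0.25 ± 0.03 s. What the generator does *not* emulate: sequential and
feedback effects, fatigue, RT drift unrelated to the diffusion parameters,
and any group difference (shifts default to zero) — so passing recovery
tests certify the machinery under the model's own assumptions, not
robustness to real-data misspecification.

## Validation experiments and problem sizes

Desk-scale analogues of the full study, sized to run in minutes on one CPU:

- Parameter recovery: 12 subjects × 4 days × 196 trials (7 × 28) under the
  winning continuous-DR/flexible-RB model at the defaults above; the fitted
  per-subject drift asymptotes correlate with truth at r ≈ 0.75–0.91
  depending on the seed (the seeded validation run gives 0.91) and group-mean
  start/asymptote sit within ~10%. Two caveats at this design length: the
  asymptote is only ~80% traversed by the final trial, and the rate ridge
  centers below the rescaled true time-to-half, producing a small downward
  bias in estimated asymptotes (~0.1 drift units) that the group-mean check
  absorbs but that caps the attainable correlation.
- Model recovery: 8 subjects × 4 days × 98 trials, 10 replicates generated
  under the constant model and 10 under the dynamic model; the criterion
  must identify the generator. Recovery experiments generate from the model
  itself (contaminant rate 0): a contaminant RT inside the retained window
  but below t0 makes the generating model's own likelihood −inf, which tests
  outlier robustness rather than the comparison machinery.
- Conjugate normal-mean toys give closed-form oracles: brute-force exact LOO
  for PSIS-LOO, and analytic marginal likelihoods for bridge sampling.
- Logistic baseline: 8 subjects × 2800 trials; threshold truth runs from
  ~12% to ~5% coherence with non-monotone day-level offsets for the flexible
  form and a 0.6 log-unit day-resetting offset for the combined form —
  effect sizes chosen so the four dynamics are identifiable from choices
  alone; trajectory recovery r ≈ 0.95 and the criterion identifies the
  generating dynamics in ≥ 70% of replicates.

## Numerical choices and degenerate inputs

Truncation: density series 1e-7; CDF tail cut 1e-12 with term cap 4000 and
an unreachable guard at 40 log-units of bridge exponent. rt ≤ t0 returns
−inf by default (optimizers must probe infeasible t0) and can raise instead.
Degenerate inputs are flagged, not silently absorbed: subjects with no
retained trials, all-identical responses, constant binned predictions
(correlation undefined → NaN with a warning), identical day-1/day-4 data
(t = 0, p = 1). Blocks for absolute fit partition retained trials in order —
every trial in exactly one 25-trial block (112 per subject on the full
design); binning is applied after RT exclusion.

## Known limitations

Per-subject fits are not a hierarchical model: between-subject shrinkage is
available only as an optional penalty, group-level SEs are not pooled, and
the rate ridge means rate estimates are MAP-flavored. The Bayesian backend's
ensemble sampler is adequate for the per-subject problem sizes used here but
is not a substitute for long NUTS runs on the full crossed design. Absolute
fit uses the unconditional mean decision time, pooling correct and error
RTs. Inter-trial parameter variability (sv, sz, st0) and time-varying bias
or non-decision time are out of scope by design.
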