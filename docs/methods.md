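# Methods

## The simulated experiment

Each synthetic participant completes two blocks of a two-interval
forced-choice (2IFC) coherent-motion task. A trial presents two brief
random-dot kinematograms (RDKs); one contains a fraction of dots
(the *coherence*) translating rightward, the other is fully random, and
the participant reports which interval held the coherent motion.

The stimulus geometry follows common online-RDK practice: a 10° square
aperture, 0.075° dots, 0.05° displacement per frame at 60 Hz (3 deg/s),
133 ms per interval (8 frames). Coherent dots translate rigidly; the
remaining dots random-walk with the same step, redrawing a uniform
direction every frame. A dot that leaves the aperture re-enters at a
uniformly random point on the opposite edge (for a corner exit, the edge
opposite the axis with the larger overshoot — a measure-zero convention).
Dot lifetime exceeds the interval, so there is no mid-trial respawn.
Initial positions are i.i.d. uniform over the aperture; the coherent
subset is drawn without replacement and round-half-up fixes its size.

*Block 1 (thresholding).* Dot numerosity is fixed at the participant's
group value (100 or 400 dots, assigned at the 118:214 ratio of the kept
reference sample) while a 1-up-2-down (Levitt) staircase adjusts
coherence: one error moves coherence up a step, two consecutive correct
responses move it down, so the tracked point satisfies p² = ½, i.e.
70.7 % correct. The staircase starts at 70 % coherence with a 10-point
step; the step becomes 5, 3, 2 and finally 1 point after the first four
reversals (the schedule slot is `min(#reversals, 4)`, and the move that
triggers a reversal already uses the new step). Coherence is clamped to
[1, 100] %. The run stops at the 12th reversal; the threshold is the mean
of the last 8 reversal levels, each recorded at the pre-move coherence.
A first move from the initial state records no reversal, and a hard cap
of 10 000 trials raises a diagnostic (reachable only for observers that
essentially never err, which also means the rule's equilibrium does not
exist). Whether reversal levels should be logged pre- or post-move is a
genuine ambiguity of such designs; pre-move is implemented and noted.

*Block 2 (constant stimuli).* Coherence is fixed at the individual
block-1 threshold while total dot numerosity sweeps the 14 quasi-log
levels 20, 29, 41, 58, 83, 118, 168, 239, 340, 485, 691, 999, 1403,
2000 — the external-noise axis — with 20 trials per level.
"Pseudorandomised" is operationalised as a seeded shuffle rejected until
no level repeats more than 3 times consecutively; target intervals are
balanced 140/140 and shuffled.

*Exclusions*, applied in order with first-match reporting: (1) threshold
above 75 % coherence; (2) fewer than 6 reversals within the final 40
staircase trials; (3) mean block-2 accuracy above 90 %. The boundary
values themselves are kept. Per-criterion and unique drop counts are both
reported, since overlapping criteria make per-criterion counts
non-additive.

## The observer

The observer is the minimal classical threshold-SR detector consistent
with the pedestal account of stochastic resonance. Each interval is
reduced to scalar motion evidence; for the target interval

    X_t ~ N(mu, sigma²),   mu = a · c · N/(N + n_sat),
                           sigma² = sigma_int² + b² · N,

and the non-target interval has the same distribution with mu = 0. The
pooling term saturates in dot numerosity N (gain `a`, half-saturation
`n_sat`); the noise term combines internal noise `sigma_int` with
correspondence noise accumulating as the sum of independent per-dot
matching errors, hence SD growing like √N (a linear-in-N variant would
only relabel the axis). Both draws pass through a hard threshold,
T(x) = x·1[x > θ]; the observer chooses the interval with the larger
rectified evidence, guessing on exact ties, and lapses (responds at
random) on a fraction `lapse` of trials.

Expected accuracy decomposes over the rectifier's regimes — only the
target crosses θ (correct), both cross (correct iff X_t > X_n), neither
crosses (coin flip) — with the middle term evaluated by adaptive
quadrature to 1e-6 absolute tolerance; a vectorised sampling twin
(`simulate_trials`) drives the behavioural simulation and agrees with the
quadrature within Monte-Carlo error.

For a sub-threshold signal (mu < θ) accuracy versus total noise SD is an
inverted U with chance at both limits. On the numerosity axis the same
mechanism makes accuracy peak at the N where total noise is near-optimal,
and because internal noise spends part of the noise budget, the optimal N
is non-increasing in `sigma_int` — *provided the signal stays
sub-threshold*. Once the pooled signal exceeds θ the detector enters a
d′-like regime in which extra dots help more than their noise costs, and
the monotone peak shift genuinely reverses; no parameterisation avoids
this, so the peak-monotonicity property is stated and tested for
sub-threshold coherences (with the defaults, pooled signal below θ across
the grid means coherence ≲ 0.14).

Defaults (evidence units are arbitrary; only ratios to θ matter):
θ = 1, a = 6, n_sat = 15 dots, b = 0.035 per √dot, lapse = 0.02.
With these values the titrated coherence thresholds land in the 15–30 %
range and the 70.7 % anchor at 100 dots sits just left of the accuracy
peak for a young observer.

## The synthetic cohort

Ages are truncated-normal on [18, 82] with the recruited-sample moments
(mean 45.92, SD 19.85); 286 participants are recruited by default and the
exclusions then act emergently (typically a handful of drops; an optional
`target_kept` mode keeps recruiting until a requested kept size).

Ageing enters through three linear maps, dominated by the first:

* `sigma_int`: 0.08 at age 18 rising by 0.01203/yr to ≈ 0.85 at 82 —
  the neural-noise account, with age an explicit proxy;
* pooling gain: −0.3 %/yr — mild age-related sensitivity loss;
* lapse: 0.02 rising by ≈ 0.001/yr to ≈ 0.08 — attentional lapses.

The gain and lapse components are deliberately small but load-bearing:
with internal noise alone, a young observer at the staircase numerosity is
noise-starved, so the first years of added internal noise *help* and the
threshold-versus-age curve dips before rising — contradicting the
age-declining sensitivity the cohort is meant to embody. The gain and
lapse maps restore strictly increasing thresholds at both 100 and 400
dots while leaving the block-2 curve shapes governed by `sigma_int`
(titration largely cancels gain, and lapse compresses curve amplitude,
which is itself the flattening signature of ageing data).

Between-participant heterogeneity is multiplicative lognormal jitter
(log-SD 0.03) on `sigma_int`, θ, gain and `b`, keeping positivity; most
systematic variance is carried by the age maps, and the staircase itself
contributes substantial realistic threshold noise (relative SD ≈ 20–30 %,
larger and upward-biased for older observers, whose psychometric
functions are shallow near the anchor).

Jitter-free ground truth under the defaults, verified analytically in the
tests: coherence thresholds strictly increase with age at both staircase
numerosities; the titrated accuracy peak is interior for the young and
non-increasing in age. The titration anchor compresses age differences —
every observer is pinned to ≈ 70.7 % at the staircase numerosity, so the
oldest observers' curves flatten and shift left but do not collapse onto
the lowest level; the leftward shift recovered by the pipeline is
correspondingly moderate (fitted peaks ≈ 185 → 160 dots from youngest to
oldest tercile on a default cohort).

## The analysis stack

*Threshold model.* OLS of ln(threshold) on scaled age × group with
sum-to-zero group coding; sequential (Type I) F-tests in the order group,
age, interaction; partial η² = SS_term/(SS_term + SS_resid); marginal
means per group at the mean age on the ln scale with exponential
back-transform. The ln transform reflects the compressive nonlinearity of
numerosity/coherence perception and stabilises residuals.

*Accuracy GLMM.* Bernoulli trials are aggregated to participant × level
binomial counts (covariates are constant within a cell), and the
log-likelihood omits binomial coefficients, so it equals the trial-level
Bernoulli log-likelihood and AICc's sample size is the trial count
(e.g. 280 × kept-n). Fixed effects: orthogonal polynomials of log dot
numerosity (degrees 1–4, Forsythe recurrence with trial-count weights,
recurrence coefficients stored for prediction-time reuse), scaled age
(or a younger/older factor split at 50, age ≥ 50 counted as older, with
sum-to-zero coding), and their interaction; one Gaussian random intercept
per participant. K counts fixed effects plus the variance component
(5, 7, 9, 11 for degrees 1–4).

The marginal likelihood is maximised over (β, log σ_u) with L-BFGS-B;
each participant's integral uses adaptive Gauss–Hermite quadrature
(default 15 nodes; 7 in the heavier simulations; 1 node = Laplace), with
the integrand re-centred at its Newton-found mode. σ_u is floored at
1e-5 (σ_u² ≈ 1e-10); because the likelihood is extremely flat near the
boundary, the optimiser's solution is compared against the σ_u → 0
profile solution (plain logistic IRLS) and the boundary candidate is
adopted when it is as good to within 1e-6, which makes boundary fits
agree with plain logistic regression to full precision. The coefficient
covariance is the inverse observed information (central-difference
Hessian over β and log σ_u) at the optimum; estimates, standard errors
and the random-intercept SD reproduce lme4's `glmer` (nAGQ = 15) to
about 1e-3 on a shared fixture.

Model selection uses AICc = −2LL + 2K + 2K(K+1)/(n−K−1) and Akaike
weights computed after subtracting the minimum. Inference on the selected
model: Type III Wald χ² per term block; Nakagawa marginal R² =
var(Xβ)/(var(Xβ) + σ_u² + π²/3); part R² by refitting without the term
(reference = full model for the interaction, interaction-free model for
main effects, so main effects are never judged in the presence of their
own interaction — the ΔR²s are not additive and are not summed).
Population-level predictions pass new numerosities through the stored
polynomial recurrence and scaling parameters with the random intercept at
zero; peak locations are grid argmaxima on 2001 log-spaced points in
[20, 2000] (ties to the smaller level), deliberately avoiding
derivative roots because the logit link makes the response-scale curve
non-polynomial. The residual diagnostic simulates replicate responses
from the fitted model (fresh random intercepts), forms randomized
quantile (PIT) residuals and KS-tests them against Uniform(0, 1).

## Numerical and design notes

* Quadrature tolerance 1e-6 for the observer; bisection tolerance 1e-4
  (on coherence) for analytic thresholds, with NaN signalling an
  unattainable 70.7 % target.
* The 1-up-2-down rule with this step schedule carries a small negative
  bias (≈ one final-step unit below the true 70.7 % point). For
  psychometric widths typical of coherence tasks (≈ 6–8 points) the bias
  is ≲ 0.02 in probability; much steeper functions would exceed it.
* GLMM fixed effects move by < 1e-3 between 7 and 25 quadrature nodes;
  nested fits have monotone log-likelihoods up to optimizer tolerance.
* Recovery experiments run at 20 seeded replicates of the default
  286-participant cohort (or 200 participants × 280 trials for direct
  parameter recovery); these sizes make AICc degree selection, the
  interaction Wald test (power ≥ 80 % with mechanisms on, size ≤ 10 %
  with mechanisms off) and the tercile peak ordering reproducible while
  the whole suite stays lightweight.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline assumes: per-trial
Bernoulli accuracy with participant-level clustering, titrated difficulty,
age-graded curve shape, staircase estimation noise, and emergent
exclusions. It does not emulate practice/fatigue or between-block drift,
response times, display-hardware variability, non-monotone or bimodal age
density, or any direct neural measurement of internal noise (age is a
proxy by construction). Passing recovery tests therefore demonstrates
that the pipeline recovers this model's structure at realistic sizes,
not that real ageing data must behave identically — in particular, real
cohorts show a stronger leftward shift (oldest observers peaking at the
lowest noise level) than the titration-anchored observer can produce.
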