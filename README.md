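# srmotion

Stochastic resonance (SR) is the counter-intuitive phenomenon in which a
*moderate* amount of noise improves the detection of a sub-threshold signal
in a nonlinear system; too little noise leaves the signal invisible, too
much drowns it, so accuracy plotted against noise is an inverted U.
`srmotion` is a simulation-plus-inference package for studying how that
inverted U changes across the adult lifespan in a coherent-motion
detection task: it simulates the full behavioural experiment — a
random-dot kinematogram (RDK) shown in a two-interval forced-choice (2IFC)
design, a 1-up-2-down staircase that titrates motion coherence to each
observer's 70.7 %-correct point, and a 280-trial sweep over 14 dot
numerosities (20 … 2000 dots, the external-noise axis) — and then analyses
the simulated data exactly the way such experiments are analysed:

* **Block 1** — linear model of ln(coherence threshold) on scaled age ×
  staircase numerosity (100 vs 400 dots), sequential F-tests, partial η²,
  back-transformed marginal means;
* **Block 2** — binomial random-intercept mixed models (GLMM, logit link,
  adaptive Gauss–Hermite quadrature) of trial accuracy on orthogonal
  polynomials of log dot numerosity (degrees 1–4), age, and their
  interaction; model selection by AICc with Akaike weights
  (w_i ∝ exp(−Δ_i/2)); Type III Wald χ² tests; Nakagawa's marginal R²
  and semipartial (part) R²; peak-location estimates of the optimal
  external-noise level; a simulation-based KS uniformity check of
  randomized quantile residuals.

The synthetic cohort gives each participant an observer whose internal
(neural) noise rises with age, so the generative ground truth — thresholds
that worsen with age, an interior accuracy peak for young observers, a
flatter curve whose optimum sits at less external noise for older ones —
is known exactly, and the statistical pipeline can be validated as a
whole: does AICc prefer the nonlinear models, is the numerosity × age
interaction detected, do the fitted peaks move left across age terciles?

The observer is a classical threshold-SR detector: each interval yields
Gaussian evidence (mean `a·c·N/(N+n_sat)` from pooling `N` dots at
coherence `c`, SD `sqrt(σ_int² + b²·N)` from internal noise plus
correspondence noise), passed through a hard threshold θ; the observer
picks the interval with more rectified evidence and guesses on ties.

## Worked example

```bash
srmotion reproduce --seed 0 --out runs/demo
```

simulates a 286-participant cohort, applies the three exclusion screens
(threshold > 75 %, fewer than 6 reversals in the last 40 staircase trials,
block-2 accuracy > 90 %), fits the four candidate GLMMs and prints the
selection table and the fitted peaks; on this seed:

```
Model           K   AICc      Delta_AICc  AICcWt
Cubic           9   90583.81  0.00        0.51
Fourth degree   11  90583.93  0.12        0.48
Quadratic       7   90594.59  10.78       0.00
Linear          5   91331.44  747.63      0.00

peaks: youngest (age 29.9): 185 dots   middle (45.6): 174   oldest (64.9): 159
```

The cubic and quartic models share essentially all the Akaike weight —
accuracy is strongly non-monotone in dot numerosity — and the optimal
numerosity declines from the youngest to the oldest tercile: observers
with more internal noise need less external noise, the leftward peak
shift. The same run reports the Type III Wald tests (numerosity
χ²(3) = 758.0, p < .001; numerosity × age χ²(3) = 8.1, p = .044), the
marginal R² (0.015) and the residual KS check (D = 0.012, p = 0.58).

The `examples/` directory holds short scripts, one per capability:
RDK frame generation, the observer's inverted U, staircase titration,
cohort simulation, and model selection with peak estimates.

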