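# Methods

## Observer model

Responses are modeled as a two-stage process. First, each available cue
yields a noisy, unbiased sensory estimate of the stimulus value *s*:

    c_i ~ Normal(s_i, σ_i²),   i = 1, 2

and, when both cues are present, the estimates are fused by the
reliability-weighted average c_c = w₁c₁ + w₂c₂ with w_i ∝ 1/σ_i², giving
fused variance σ_c² = σ₁²σ₂²/(σ₁²+σ₂²). Second, the (fused) sensory estimate
is shrunk toward the center μ of the stimulus range and perturbed by response
noise:

    r = (1 − w_p)·c + w_p·μ + ε,   ε ~ Normal(0, σ_n²)

The shrinkage weight w_p is condition-specific. Following Bayesian accounts
of the central tendency bias (the range center acts as a category prior whose
relative weight grows as sensory reliability falls), the package derives the
single-cue weights from the combined-cue weight w_pc:

    w_pi = w_pc σ_i² / (σ_c² + w_pc (σ_i² − σ_c²))

which guarantees w_pi ∈ [w_pc, 1]: shrinkage is never weaker for a noisier
estimate. The model assumes independent Gaussian cue noise, unbiased single
cues, a fixed shrinkage target μ (not a running mean of recent stimuli —
recency-based accounts exist but are not modeled), bias applied *after*
fusion (decoding-stage), and unbounded responses.

Key closed forms (best cue labeled 1, i.e. σ₁ ≤ σ₂; inputs are relabeled
internally when needed):

- combination effect: E = σ₁⁴/(σ₁²+σ₂²)
- expected behavioral variance per condition: (1−w_pi)²σ_i² + σ_n²
- bias-attenuated effect: E_b = (1−w_p1)²σ₁² − (1−w_pc)²σ_c², equal to E when
  w_pc = 0 and never larger otherwise (it can be negative).

## Precision estimators

For one observer and condition, with targets s_t and responses r_t:

- **raw**: sample variance (denominator N−1) of the errors r_t − s_t. Under
  a central bias this mostly measures the bias, not sensory noise.
- **behavioral**: variance of residuals from OLS of r on s. The regression
  absorbs the stimulus-dependent constant error, but the estimate targets
  (1−w_p)²σ² + σ_n² — an *under*-estimate of sensory variability.
- **sensory**: behavioral variance divided by the squared fitted slope β̂.
  Since β̂ estimates 1−w_p, this targets σ² + σ_n²/β², removing the
  compression the bias adds. The correction is conditional: it is applied
  only when β̂ is significantly below 1 (one-sided t test on the slope,
  n−2 df, 5% level by default), so bias-free data are returned unchanged,
  and a slope above 1 is never used.

Numerical choices: residual variance uses the residual degrees of freedom
(n−2); at the trial counts of interest (≥105) the difference from n−1 is
negligible, but n−2 is unbiased under the regression model. The conditional
test is a t test on the OLS slope because it is the minimal test consistent
with "significantly below one". A fitted slope ≤ 0 that passes the test has
no meaningful correction; the behavioral value is returned with a
`degenerate` flag and a runtime warning.

With response noise present the sensory estimator targets σ_i² + σ_n²/β_i²
rather than σ_i² exactly; the implied combination-effect estimate is
E + σ_n²(1/β₁² − 1/β_c²), which is ≥ E when the bias grows with sensory
uncertainty (β_c > β₁) and exactly E when there is no true effect (β_c = β₁).
The correction therefore recovers — and with noise can even amplify — the
detectable effect, without creating one where none exists.

## Combination test

Per-observer variability with both cues is compared to the best (lowest
variability) single cue with a one-tailed Wilcoxon signed-rank test
(alternative: combined < best single). The best cue is chosen per observer
from the data, using the same precision measure being tested. The exact null
distribution is used for n ≤ 25 with untied, non-zero differences; otherwise
the normal approximation with continuity correction (zeros dropped). Effect
size is the paired Cohen's d, mean(diff)/SD(diff), reported as 0 with a flag
when the differences have zero spread. Ties to cue 1.

## Weight estimators

On conflict trials (cues indicating different values s₁ ≠ s₂):

- **behavioral (simple)**: OLS slope of (r − s₂) on (s₁ − s₂); implicitly
  w₁ + w₂ = 1. On the balanced 72-pair design its noiseless estimand is
  (1−w_p)·w₁ + w_p/2 (derived exactly for any exchangeable design; the test
  suite confirms it against the exact OLS solution), so weights above ½ are
  underestimated whenever w_p > 0, by an amount independent of σ_n.
- **behavioral (multiple)**: OLS of r on (s₁, s₂, 1); coefficients estimate
  ((1−w_p)w₁, (1−w_p)w₂) and are not constrained to sum to one.
- **sensory**: posterior inference on
  r ~ Normal((1−w_p)(w₁s₁ + (1−w₁)s₂) + w_p·μ, σ²), which recovers w₁
  without attenuation. μ is fixed at the known range center, not estimated.

Priors are flat on natural bounded supports: w₁, w_p ~ Uniform(0,1),
σ ~ Uniform(0, range width). The sampler is a component-wise random-walk
Metropolis-within-Gibbs: 3 independent chains, 100 burn-in iterations, 1000
recorded samples per chain thinned by 5 (5000 post-burn-in iterations),
weights initialized at 0.5 and σ at 0.01. Proposal scales start from an OLS
pre-fit of the same mean model and are tuned by Robbins–Monro adaptation
toward ~44% acceptance during burn-in only, then frozen, so the recorded
chain satisfies detailed balance. The point estimate is the mean of the
per-chain posterior means; uncertainty is the pooled posterior SD. A split
potential-scale-reduction diagnostic (threshold 1.1) is computed per
parameter; non-convergence is flagged on the result rather than raised, so
grid studies can continue. Behavioral regression estimates are deliberately
not clamped to [0,1]; posterior estimates are bounded by the prior support.

## Simulators

Trial tables are tidy DataFrames (observer, condition, s₁, s₂, target,
response). Congruent designs place both cues at a common target; conflict
designs enumerate all ordered pairs of distinct grid values (72 pairs for the
9-value grid 0.4–0.6 in steps of 0.025; zero-conflict self-pairs are excluded
by default since they carry no weighting information, with a flag to restore
them). Responses are not clipped to the stimulus range: the model is
unbounded-Gaussian and clipping would distort variance recovery (an option
exists, defaulting off). One master seed spawns per-observer/per-condition
substreams, so extending a design never perturbs existing draws.

The worked-example fixtures simulate six single-cue observers on a
[−40, 40] degree range (grid step 2, the grid itself being an illustrative
choice), sensory variances {4, 16, 36} crossed with bias weights {0, 0.5},
σ_n = 0, μ = 0; at the default repetition count each observer contributes
~10⁵ trials, pinning variance estimates to a few tenths of a percent.

What the generator does *not* emulate: non-Gaussian or correlated cue noise,
constant single-cue biases, stimulus-dependent (heteroscedastic) noise,
recency effects, lapses, or response bounds. Passing tests therefore show
that the estimators invert the stated generative model, not that real data
satisfy it.

## Validation studies

**Power study.** Observers are simulated on the 36-value unit-range target
grid (0.15–0.85, step 0.02), 5 repetitions per target per condition, best-cue
noise σ₁ = 0.01. Grid axes: reliability ratio σ₂/σ₁ (20 log-spaced in
[1, 10]), bias strength w_pc (20 log-spaced in [0.01, 1]), response noise
σ_n ∈ {0, 0.005, 0.01, 0.015, 0.02}, sample size n ∈ {10, 20, 30}. Per cell,
1000 datasets are simulated; power is the fraction of 100 random size-n
subsets (drawn without replacement within a subset) in which the combination
test rejects at α = 0.05, computed for the behavioral and the sensory
measure from the same simulated data. The uncorrected measure loses all
power once w_pc exceeds ≈0.3; the corrected measure does not lose power as
the bias grows.

**Recovery study.** Conflict observers with σ₁ = 0.05, ratio axis 5
log-spaced in [1, 4.18], bias axis 10 log-spaced in [0.01, 0.7], σ_n ∈
{0.01, 0.015, 0.02}, 100 datasets per cell of 72 pairs × 10 repetitions.
Each dataset yields a behavioral and a sensory weight estimate; cells report
mean ± SD of (estimate − true w₁). The behavioral error is negative (an
underestimate) whenever w₁ > ½ and the bias is strong, and is unaffected by
σ_n; the sensory error centers on zero throughout.

Both studies are deterministic given their spec's master seed (per-cell
child streams). Full-scale grids are hours of CPU and are run via the CLI
with a config; the shipped test suite exercises reduced grids — 2×2 cells
(150 datasets, 40 resamples) in unit tests, a 4×4 grid (200 datasets, 50
resamples, n = 20, σ_n = 0.01) plus one strong-bias recovery cell
(ratio 4.18, w_pc 0.7, 20 datasets) in the end-to-end tests — sizes chosen
so the qualitative pattern is resolved at 3×-binomial-SE tolerance.

## Tolerances and degenerate inputs

Monte-Carlo assertions use 3 standard errors: SE(s²) = σ²√(2/n) for sample
variances, a delta-method SE for the slope-corrected variance (combining
residual-variance error and propagated slope error), and binomial SEs for
power fractions. Degenerate inputs fail loudly: non-positive noise SDs,
constant targets, fewer than 3 (regression) / 5 (signed-rank) observations,
conflict designs without conflict variance, and collinear predictors all
raise; missing cue values in CSVs are reported with 1-based line numbers.

## Known limitations

The sensory-precision estimate absorbs σ_n²/β² and is therefore an upper
bound on σ² when response noise is non-negligible; exact optimality tests
should account for this. The conditional correction introduces a small
selection effect near β ≈ 1 at low trial counts. The posterior fit assumes a
known μ and a single residual SD absorbing both shrunken sensory noise and
response noise; it does not separate the two. Hierarchical pooling across
observers and cue-prior designs (a cue combined with prior knowledge rather
than a second cue) are out of scope.
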