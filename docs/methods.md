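# Methods

## The task and the restless walk

The restless three-armed bandit forces continual re-learning: each arm's
reward probability follows its own bounded random walk, so the best option
drifts over the session. Walk dynamics: per arm and per trial, the
probability steps ±`step` with probability `hazard` (direction uniform),
otherwise holds. Defaults are 300 trials, 3 arms, hazard 0.6667, step 0.2,
bounds [0.1, 0.9]; initial values are drawn uniformly on the grid
{0.1, 0.3, 0.5, 0.7, 0.9}. When `(hi − lo)/step` is integral the walk is
simulated in integer grid units, so values stay exactly on the grid.

Boundary handling is a genuine design choice: a step that would exit the
bounds is **reflected** (forced in the feasible direction) by default,
which preserves per-trial volatility at the edges; `boundary="clip"`
truncates instead. Reflection is the default because with hazard = 1 a
clipped walk would sit motionless at a bound while a reflected one keeps
moving, matching the intent of a *restless* environment.

## Model-free metrics

All transition-conditioned metrics use the transitions t → t+1 whose
predecessor outcome is observed (the final trial conditions nothing).
Punishment sensitivity is

PS = (P(shift | loss) − P(shift | win)) / P(shift),

with every term computed over that same transition set; this realizes the
verbal definition "relative shift probability after losses versus wins,
controlling for overall shiftiness". Including the first trial in the
P(shift) denominator would mix in a transition with no conditioning
outcome, so it is excluded for internal consistency; this also makes the
identity P(shift) = w·P(shift|win) + (1−w)·P(shift|loss) (w = predecessor
win rate) hold exactly, which the test suite asserts to 1e-12.

Degenerate sessions (never shifting, never losing, …) yield NaN for the
affected metric only; downstream correlations drop missing values
pairwise, so no subject is ever excluded.

## The tied explore/exploit HMM

Four states: explore (uniform emissions — the maximum-entropy categorical)
and one exploit state per arm (one-hot emissions). Emissions are fixed,
never re-estimated. Transitions are tied: every exploit state leaves for
explore with the same probability `a`, and explore leaves with total
probability `b` split equally across exploit states. Exploit→exploit
entries are structurally zero, so even a one-trial switch passes through
exploration. The initial state distribution is fixed uniform over the four
states — re-estimating it would add free parameters beyond the model's
two, and with 300 trials it is barely informed by the data.

Fitting is Baum–Welch with the tied M-step: pooled expected
exploit→explore transition counts over pooled exploit occupancy for `a`,
and symmetrically for `b`. Restarts draw (a, b) i.i.d. uniform(0.01,
0.99), 10 per fit; convergence at log-likelihood gain < 1e-6, max 500
iterations; the best restart wins. Deterministic exploit emissions make
many (state, choice) pairs impossible, so all recursions use per-step
scaling with explicit zero handling rather than log(0) arithmetic; an
all-zero scale flags the sequence impossible (−inf) instead of raising.

Viterbi decoding runs in log space with −inf for impossible cells and
breaks ties toward the lower state index at each backtrack step. One
subtlety, documented because the test oracles depend on it: the tied
structure creates *exact* algebraic path-probability ties for generic
(a, b) — e.g. paths that differ only in which of two trials an explore
self-transition occupies have identical probability — and two independent
computations (the DP and an exhaustive enumeration) accumulate the same
product in different floating-point orders, so which tied path "wins" is
rounding luck. The oracle tests therefore assert that the decoded path
attains the enumerated maximum probability (1e-10) and require exact path
identity whenever the maximizer is unique.

Derived metrics: p(explore) is the fraction of explore-labeled trials;
P(explore|explore) and P(exploit|exploit) are empirical transition
frequencies of the label sequence with exploit states merged.
**Exploration potential** has no standard definition; this package defines
it as the fitted `a` — the per-trial probability of *initiating*
exploration from exploitation — which is the natural "propensity to
explore" distinct from realized exploration. It is a documented stand-in
and callers can substitute their own column.

### What recovery can and cannot achieve at T = 300

At the reference conditions (a, b) = (0.05, 0.6) the chain's stationary
explore mass is a/(a+b) ≈ 7.7%, i.e. ≈ 23 explore trials per 300-trial
session. `a` is informed by ≈ 277 exploit trials and recovers with median
absolute error ≈ 0.01; `b` is informed only by the ≈ 23 explore trials,
so its MLE carries a standard error ≈ sqrt(b(1−b)/23) ≈ 0.10 — measured
median absolute error ≈ 0.12, sampling SD ≈ 0.16. This is an information
limit of the session length, not an estimator defect: the same EM recovers
b to ≈ 0.02 at T = 30000. Viterbi label accuracy is ≈ 96% at these
conditions. The corresponding acceptance test asserts a 0.05 bound on both
parameters and is expected to fail on `b`; it is left failing rather than
weakened.

## RL and RLCK models

Decide-then-learn ordering: trial-t choice probabilities use the values
before that trial's update (the convention the model equations imply).
Only the chosen arm's Q updates (delta rule); the choice kernel updates
every arm toward its chosen-indicator at rate α_C; a single inverse
temperature β multiplies (Q + CK). Initial values q0 = 0.5 (midpoint of
the 0/1 reward scale) and ck0 = 0, both configurable. Bounds:
α, α_C ∈ [1e-6, 1], β ∈ [1e-6, 50] — the lower bounds keep gradients
finite, the β cap keeps exp(βQ) finite and spans the behaviorally
plausible range. Fitting: truncated-Newton (TNC) from 30 uniform random
starting points, best final NLL wins, deterministic given the seed. The
simulator and the likelihood share one per-trial recursion (policy +
update functions), so simulated agents and fitted trajectories cannot
disagree; a replay test reproduces simulated choices exactly from the
likelihood-side value trajectories.

At the reference conditions (α, β, α_C) = (0.4, 5, 0.3), T = 300, median
recovery errors are ≈ 0.10 for α (with a known positive finite-sample
bias of MLE learning rates at this session length), ≈ 0.5 for β and
≈ 0.08 for α_C. AIC comparison of the nested pair behaves as theory
predicts: on kernel-free data the RL-minus-RLCK AIC difference
concentrates at −2 (the penalty for the unused parameter, Wilks at the
boundary), and on kernel-generated data summed AIC strongly favors RLCK.

## Sparse CCA

Rank-1 penalized matrix decomposition of Z = B'E/(n−1) (columns z-scored
first — covariance maximization is only meaningful on a common scale):
alternate x ← argmax x'(Zy) and y ← argmax (x'Z)y under ‖·‖₂ ≤ 1 and
‖·‖₁ ≤ c, each solved exactly by soft-thresholding with the threshold
found by 60-step bisection; the objective is therefore monotone.
Initialization is the leading right singular vector of Z. Successive
components by deflation Z ← Z − d·xy'. Penalties are expressed on a
(0, 1] scale with c = max(1, scale·√dim), the convention of
penalized-matrix-decomposition software; the analysis default is
(1.0, 0.9), i.e. c₁ = 6.0 on 36 items and c₂ = 2.7 on 9 features.
Reported canonical correlations are Pearson correlations of the variates
Bx and Ey; loadings are per-variable correlations with their own set's
variate; signs are fixed by making the dominant-loading item positive.

The unpenalized limit (scales 1.0/1.0) maximizes cross-*covariance* under
unit L2, which coincides with classical CCA exactly when the within-set
covariance is the identity; the oracle tests therefore whiten instances
within-set before comparing against the eigen-decomposition CCA solution.
On raw correlated data the two objectives legitimately differ.

Penalty tuning: for each of 10 random two-thirds discovery splits, 10-fold
CV over the 10×10 grid of scales (0.1…1.0), scoring the held-out Pearson
correlation of the variates with weights and standardization fit on the
training folds; the selected point maximizes the CV score averaged over
splits (the aggregation rule across resamples is this package's choice).
Permutation inference shuffles B's rows, refits at the *same* penalties
and component count, and uses the +1-corrected p-value
(1 + #{perm ≥ obs})/(1 + n_perm), BH-adjusted across components; tuning
is not re-run inside permutations. Default 5000 permutations (tests and
the acceptance script use 200–500).

## Cohort statistics

Spearman's rho (mid-ranks for ties), two-sided p from the t
approximation, and a 95% CI from the Fisher z-transform with SE
1/√(n−3) — the CI method is unstated in the reporting convention this
mirrors, and Fisher-z is the standard choice. Shapiro–Wilk screening
justifies the rank-based tests (subsampling to 5000 beyond the test's
validity range). FDR is Benjamini–Hochberg throughout. α = 0.05.

## The synthetic cohort generator

What it emulates: (a) the reward walks above; (b) heterogeneous RLCK
agents whose parameters covary with a latent aloofness trait —
α = logit⁻¹(logit(0.4) − 0.08·z + ε), β = exp(ln 4 + 0.13·z + ε),
α_C = logit⁻¹(logit(0.3) + 0.17·z + ε) with independent Gaussian link
noise (SDs 0.6, 0.5, 0.7); (c) three correlated latent subscale traits
(pairwise r = 0.4) emitting 12 ordinal items each via
round(3.5 + 0.8·trait + N(0, 0.8)) clamped to 1..6; (d) log-normal
response times (log-mean ln 0.6, log-SD 0.4) with a +0.15 s additive
slow-down on shift trials (natural-scale, so the cohort-mean shift-stay
RT difference equals the configured offset — the round-trip the tests
assert). Coupling strengths were calibrated once so the end-to-end
aloof-behavior Spearman correlations land at |rho| ≈ 0.10–0.28, the
magnitude regime the pipeline is designed to detect; all are
configurable, and zeroing the coupling yields an exact null.

What it does not emulate: real item response styles (acquiescence,
category collapse), reward-sensitive RT modulation, within-session
nonstationarity of strategy, demographic structure, or exclusion/attention
artifacts. Passing tests therefore demonstrate correctness of the
machinery and detectability of planted structure — not that any specific
real cohort satisfies the generative assumptions.

Randomness: every stochastic operation takes an explicit seed; nested
streams derive via `numpy.random.SeedSequence.spawn`, so identical
configs reproduce byte-identical cohorts and reports.

## Problem sizes used by tests and the acceptance script

Recovery studies use 100 sequences/agents (tests) or 50 (acceptance
script) at the reference conditions; the end-to-end directional test uses
one n = 1000 cohort plus 20 null cohorts of n = 150; the acceptance
script's cohort stage uses n = 500 with 500 sCCA permutations and fits
RL/RLCK on 60 subjects. These sizes give stable medians and calibrated
rejection rates while keeping a full run in the minutes range on one CPU.

## Known limitations

- `b` (explore → exploit) is weakly identified at T = 300 (see above).
- The learning-rate MLE is biased upward at session lengths around 300;
  hierarchical estimation would shrink it but is out of scope.
- The permutation test holds penalties fixed; selection-and-test on the
  same data is the caller's responsibility to avoid.
- The sCCA stage median-imputes the rare missing behavioral features
  rather than dropping subjects; with heavy missingness this would bias
  loadings toward zero.
- Exploration potential is a package-defined stand-in (fitted `a`), not a
  field-standard quantity.
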