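# Methods

## Simulated world

Each simulation cell is defined by a truth condition, an original sample
size and a publication-bias level. A true standardized effect θ is drawn
from one of two normal distributions:

* **spurious**: θ ~ N(0, 0.02) — effects negligibly close to zero but not
  exactly zero, unrestricted in sign;
* **real**: θ ~ N(0.5, 0.15) — a medium average effect with realistic
  spread.

An original study of size n ∈ {25, 50, 75, 100} observes n iid
Normal(θ, 1) values and is summarized by a one-sided one-sample t-test
(H0: μ = 0, Ha: μ > 0). Significant originals (p < 0.05) are always
published; non-significant ones are published with probability
(100 − bias)/100 for bias ∈ {100, 75, 50, 25, 0}%. Every published
original is followed by one close replication with the same θ and twice
the sample size. Unpublished originals are retained with a flag so the
shrinking denominators can be audited, but all rates condition on
publication. Defaults are 5000 iterations per (truth, n) cell, i.e. 20,000
originals per truth condition and bias level.

Sampling is by sufficient statistics — x̄ ~ N(θ, 1/√n) and
(n−1)s² ~ χ²(n−1) — which is exactly equivalent in distribution to drawing
raw data; the test suite verifies the null p-value is uniform
(Kolmogorov–Smirnov) and that the one-sided test rejects at its nominal
rate.

Randomness: a single master seed; each (bias, truth condition, n) cell gets
an independent `numpy` `SeedSequence` substream keyed by those three
integers, so any cell can be regenerated in isolation and results do not
depend on evaluation order. Reruns are bit-identical.

## Decision rules and their statistics

Every metric reduces to a per-pair *evidence statistic* compared with a
threshold, plus sign gates (sample effects strictly positive; an exact zero
counts as failure). Statistics are computed once per pair; threshold sweeps
(alpha grid 0.0001–0.5 step 0.0001; BF grid 0.1 upward in steps of 1/25,
4998 values) are derived by sorting and binary search. The Small Telescopes
rule is a fixed single-point criterion — its internal alpha is pinned to
0.05 for both the 33%-power benchmark d₃₃(n) and the "significantly
smaller" noncentral-t test — so it contributes one point rather than a
curve. The replication Bayes factor is *not applicable* to non-significant
originals; those pairs are excluded from both numerator and denominator for
that metric (only relevant below 100% bias).

The true positive rate at a threshold is the fraction of successes among
published, applicable pairs with real-condition truth; the false positive
rate the same among spurious-condition pairs. Empty denominators raise an
error rather than report zero. Pooled rates across the four sample sizes
are exactly the published-pair-weighted average of the per-n rates (tested).

## Bayes factors

All three Bayes factors integrate noncentral-t likelihoods of observed t
statistics over the standardized effect δ:

* single-study JZS: BF₁₀ = ∫ f_nct(t; n−1, δ√n) π(δ) dδ / f_t(t; n−1);
* meta-analytic: joint likelihood of both t statistics under one common δ;
* replication BF: the original study's posterior (JZS prior × original
  likelihood, normalized numerically) serves as the prior for the
  replication; the test suite verifies it against an independently computed
  Savage–Dickey density ratio.

π(δ) is a zero-centred Cauchy with scale √2/2 (config-exposed; 1.0
available). **Default sidedness is one-sided** — the prior folded onto
δ > 0 — because the whole design is directional (one-sided tests, only
positive effects count as findings); the symmetric two-sided prior is a
config switch. This choice moves the liberal-threshold BF rates by several
percentage points, far more than the Cauchy scale does.

Numerics: integrands are evaluated in log space on a graded Simpson grid —
401 dense points across ±15 likelihood scales, geometric tails to ±45 —
centred on the likelihood peak(s); the bracket widens automatically until
the integrand has fallen at least e⁻³⁰ below its peak at both endpoints,
and raises if it cannot. Log Bayes factors are clipped at ±700 before
exponentiation. Agreement with a 200,001-point fixed-grid trapezoid oracle
is at machine precision in the tested regime (asserted at 1e−5 relative).
scipy's noncentral-t density is used near the peak, where it is accurate; a
Gaussian screen discards evaluations more than 25 likelihood scales into
the tails (where the density is ≥55 log-units below the peak and scipy's
boost backend is slow or fails), and degrees of freedom above 2000 switch
to an exact 80-node Gauss–Legendre integration over the chi scale factor.

## Sceptical p-value

With z_o, z_r the standardized-effect z values (d/se, se² = 1/n + d²/2n)
and c = se_o²/se_r² the variance ratio, the one-sided sceptical p-value
p_S = Φ(−z_S) solves the quadratic
(c−1) z_S⁴ + (z_o² + z_r²) z_S² − z_o² z_r² = 0 (positive root). This is
the *nominal* variant: no recalibration of the level. The closed form is
verified against a two-step construction oracle (root-find the sufficiently
sceptical prior variance at each level, then the prior-predictive conflict
with the replication) to 1e−6 on a 300-point grid. Pairs with z_o ≤ 0 or
z_r ≤ 0 return a value ≥ 0.5 — no one-sided replication success is
possible. A structural consequence worth knowing: z_S < z_o always, so
barely-significant originals can essentially never yield p_S < 0.025
however strong the replication; under 100% publication bias this drives the
metric's false positive rate to ~0 and its summary-threshold true positive
rate well below the significance rule's.

## Meta-analysis

Fixed-effect, inverse-variance on Cohen's d with the large-sample variance
1/n + d²/(2n) and a one-sided normal z-test. No Hedges small-sample
correction (n ≥ 25 makes it negligible) and no heterogeneity modelling —
originals and replications share their θ by construction.

## Scale choices

The acceptance script runs the full published design (5000 iterations per
cell; ≈1 minute single-core, dominated by ~19,000 replication-BF
quadratures). The test suite's end-to-end checks run a 1/5-scale design
(1000 iterations per cell) and widen every Monte-Carlo band by the
corresponding √5 through the margin formula 1.96·√(p(1−p)/n) evaluated at
the actual denominators; unit tests use a few hundred pairs. Monte-Carlo
tolerance tests are seeded and use 3σ bands.

## What the generator does and does not emulate

It emulates: truth heterogeneity, sampling noise in both mean and variance,
selection of originals on significance, and larger replications. It does
not emulate: two-sample or unequal-variance designs, hidden moderators or
any original-vs-replication heterogeneity, publication bias acting on
replications, graded (p-value-dependent) publication probabilities, or
questionable research practices inflating original effects. Passing tests
therefore show how the metrics behave under clean close replications of
biased-but-honest literatures, not under every real-world distortion.

## Known limitations

* The replication BF's informed prior is deterministic quadrature on the
  original's posterior; results match sampling-based implementations only
  up to their Monte-Carlo error.
* One-sided Bayes factors with strongly negative original effects put the
  folded prior almost entirely in a likelihood tail; values are correct but
  the quantity is not meaningful there (the decision rules gate on d_o > 0
  first).
* The sceptical p-value is implemented in its nominal one-sided form only;
  recalibrated variants (e.g. the golden level) are out of scope.
* Rates are reported with the binomial margin formula; no between-curve
  significance testing or scalar ROC summaries are provided.
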