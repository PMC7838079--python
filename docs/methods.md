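# Methods

## Data model

The unit of data is one trial: participant × dilemma × design cell ×
binary action/inaction response.  The four design cells cross norm type
(proscriptive / prescriptive) with consequence magnitude (benefits
greater / smaller than costs); `p1..p4` denote action probabilities in
the fixed cell order defined in `moralcan.data.CELL_DESIGN`, and every
module shares that convention.  The canonical file format is a
long-format CSV (one row per trial); a wide 16-column count table is
supported for export only.  Participants missing trials in any cell are
rejected by default — the CAN formulas are undefined without all four
cells — with an explicit `allow_incomplete` flag that drops and logs
them instead.

## CAN scoring

`C = (p1−p2+p3−p4)/2`, `N = (p3−p1+p4−p2)/2`, `A = (p1+p2+p3+p4)/4`,
evaluated exactly with no clamping; `C` and `N` average a
benefit-contrast and a norm-contrast over the two levels of the other
factor, `A` is the grand mean action rate.  Group summaries report mean,
SD, SE and two-tailed one-sample t tests of C and N against 0 and A
against 0.5 (df = n−1, α = 0.05 by default, no multiplicity
correction across the three tests).  Zero-variance samples are flagged
degenerate rather than producing an infinite t; for classification a
degenerate test counts as significant exactly when its mean differs from
the null value (every observation then sits away from it).

The qualitative classification applies sign-and-significance rules to
the three tests: C/N are *supporting* / *opposing* / *insensitive*, A is
*action_preference* / *inaction_preference* / *neutral*; a neutral-A
group sensitive to at least one principle is summarized as
*pure_morality*, neutral and insensitive to both as *random*, anything
else as *mixed*.  These rules are defined for group means; the package
deliberately offers no per-participant significance labels, because a
single 24-trial battery carries too little information for stable
individual inference.

## Tree models and likelihood

Three trees map latent triples onto the cells (CNI: consequences →
norms → generalized inaction; NCI: the same with norms first; DNA:
parallel norm/consequence drive D with norm dominance N and residual
action preference A).  The forward maps are exact polynomial
evaluations; closed-form inversions exist for interior parameters and
raise structured errors on the degenerate boundaries (`C = 1`, `N = 1`,
`D ∈ {0, 1}`) and on cells violating the tree's structural equality
(for CNI, `p1 − p2 = p3 − p4`).

Fitting maximizes the product-binomial likelihood of aggregated
action/inaction counts over the four cells, per group, matching the
group-level practice the batteries were designed for.  The optimizer is
L-BFGS-B with analytic gradients on logit-transformed parameters,
multi-started from a fixed 3×3×3 interior grid {0.25, 0.5, 0.75}³ plus
the closed-form inversion of the observed proportions clamped to
[0.02, 0.98]; the best likelihood wins, ties broken by the first start.
The likelihood is concave in the transformed coordinates
(C, (1−C)N, (1−C)(1−N)(1−I)), so the landscape is benign and the
multi-start is belt-and-braces rather than load-bearing.

G² = 2·Σ obs·ln(obs/exp) over action and inaction counts in every cell,
with 0·ln 0 = 0; df = 4·groups − free parameters (one group, three free
parameters → df = 1).  p-values are chi-square upper tails without
continuity correction.  Estimates within 1e−4 of a bound are listed in
`boundary_parameters`.  ΔG² constraint tests refit with one parameter
tied across groups (df = groups−1) or fixed to a value (df = groups),
warm-started from the unconstrained optimum; a ΔG² below −1e−6 after a
denser restart raises an error instead of returning a silently wrong
statistic, and smaller negatives round to zero.  Cohen's w =
√(ΔG²/total observations) is reported as a descriptive effect size for
these tests.

## Exhaustive grid reference

`g2_grid_minimum` validates the fitter by exhaustively evaluating the
deviance on a uniform step-spaced grid over the parameter cube
(step 0.001 → 1001³ points).  To keep one pass affordable it first
sweeps the 10×-coarser subgrid (whose points all lie on the fine grid)
to seed per-instance incumbents, then skips fine slices only when a
rigorous bound — each cell's binomial log-likelihood maximized over the
cell-probability interval attainable within the slice — proves no point
in the slice can beat the incumbent.  The returned minima are identical
to a plain exhaustive sweep; the heavy inner products run in float32,
keeping G² errors below ~1e−5, well inside the 1e−4 agreement the tests
require.

## Simulation

Latent parameters are drawn from a mean-calibrated logit-normal:
`expit(mu + sd·Z)` with `mu` solved (Gauss–Hermite quadrature + Brent)
so that the population mean equals the requested value.  Plain
`mu = logit(mean)` would bias sample means toward 0.5 by
`≈ ½·sd²·p(1−p)(1−2p)`, which at sd = 0.5 already exceeds Monte-Carlo
error at n = 10⁴; calibration makes "latent mean" mean what it says.
With sd = 0 every participant receives the mean exactly.  Responses are
independent Bernoulli trials per cell; the default battery is 24 trials
(6 per cell), mirroring the published study design.  A single seed
governs everything, with per-participant generators spawned from it so a
participant's data do not depend on the sample size simulated around
them.  The generator draws no item (scenario) random effects and no
response-time structure, so passing recovery tests speak to sampling
noise only, not to scenario heterogeneity in real batteries.

## Comparison harness

For two-group batteries the harness pairs, per parameter, the ΔG² test
on the group-level tree fit with the pooled-variance Student's t test on
the individual CAN scores (df = n1+n2−2; Welch behind a flag; Cohen's d
from the pooled SD), and flags whether both p-values fall on the same
side of α.  The tree's third parameter (I) is paired with the CAN A
score — their group differences probe the same contrast from the two
frameworks.  Identity checks fit the CNI tree to the pooled counts and
report `|C̄_CAN − C_CNI|`, `|N_CNI − N̄_CAN/(1−C_CNI)|` and whether
`A − 0.5` and `I − 0.5` have opposite signs; the sign check returns a
boundary verdict when either quantity is within 1e−3 of zero.  The
default discrepancy tolerance is 1e−3 on noise-free data and 0.02 on
sampled data (both configurable).  Trait analyses compute Pearson r of
the trait against each score with listwise deletion of missing traits
and a degenerate flag for zero-variance inputs.

## Problem sizes

The validation suite uses the sizes it reports: a 9×9×9 parameter grid
for the identities; 50 count tables with ≤12 trials/cell against the
0.001-step exhaustive reference; recovery at n = 200 participants × 24
trials; 1000 null replicates (two groups of 100 × 24 trials) for the
calibration of both tests, whose rejection rates are required to land in
[0.03, 0.07] at α = 0.05.  Null calibration simulates aggregated and
per-participant binomial counts directly — with homogeneous latents this
is distributionally identical to trial-level simulation and keeps a
thousand replicates cheap.

## Known limitations

* Individual CAN scores from 6 trials/cell are coarse (steps of 1/12 on
  C and N); the package reports them exactly and leaves shrinkage or
  reliability modelling to the user.
* No measurement-error index accompanies the scores; absent correlations
  with traits cannot be distinguished from attenuation.
* Only binary responses are supported, although the CAN formulas extend
  naturally to continuous action ratings.
* Exactly the three named trees are implemented; there is no
  user-defined tree DSL and no hierarchical/latent-trait MPT extension.
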