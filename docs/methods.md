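# Methods

## The triplet interference test

The building block is the triplet (x, y, z): two genes of the current
bottom layer and one candidate regulator. All correlations are Spearman
rank correlations with midrank ties. The test statistics are:

* `p1`: two-sided p-value of r_xy via the t approximation,
  t = r·sqrt((n−2)/(1−r²)) with n−2 df.
* `p2`: the same for the first-order partial correlation r_xy|z, with n−3
  df (one degree of freedom spent on the conditioning gene).
* `p3`: two-sided p-value of D = r_xy − r_xy|z. D is a smooth function of
  (r_xy, r_zy, r_zx); its variance is the delta-method quadratic form
  pdᵀ·Σ·pd, with pd the analytic gradient and Σ the asymptotic covariance
  matrix of the three sample correlations, and z1 = D/sqrt(var D) is
  referred to N(0,1).

The marginal-correlation test has no stated form in the GGM literature for
this construction; the t approximation is the conventional choice and is
well calibrated at the sample sizes used here (n ≥ 30).

### The covariance matrix Σ

With the ordering (r_xy, r_zy, r_zx), diagonal entries are
var(r) = (1−r²)²/n. Every pair of the three correlations shares one
variable; the classical (Pearson–Filon) asymptotic covariance of the two
correlations b, c sharing an index, with a the remaining correlation, is

    cov = [(2a − bc)(1 − a² − b² − c²) + 2a³] / (2n).

This form and the assignment of `a` per entry (σ12: a = r_zx, σ13:
a = r_zy, σ23: a = r_xy) were confirmed empirically against the
Monte-Carlo covariance of sample correlations over 50,000 trivariate-normal
datasets; the check is part of the acceptance suite. The oracle uses
n = 800 observations per dataset so that the O(1/n²) remainder of the
asymptotic expansion sits below Monte-Carlo resolution — at n = 200 the
remainder alone is ≈4 MC standard errors and would dominate the comparison.

These covariance formulas are product-moment asymptotics. They are applied
to rank-transformed data, as the construction prescribes; the combination
is validated by simulation (type-I calibration of p3) rather than asserted
from theory. Under a zero-difference null with a non-vanishing gradient
(e.g. ρ_xy = ρ_zy = 0, ρ_zx = 0.6, n = 200) the empirical rejection rate at
0.05 is ≈0.05 and z1 passes a KS comparison with N(0,1).

### A known degeneracy

When z is uncorrelated with *both* pair genes (ρ_zx = ρ_zy = 0), the
gradient of D vanishes identically at the true parameter and the
first-order delta method degenerates: z1 converges not to N(0,1) but to
(A−B)/(2√(A+B)) with A, B independent χ²₁ variables (standard deviation
1/2), and the test rejects at far below its nominal rate (≈5·10⁻⁴ at
α = 0.05). This only *loses power where there is nothing to detect* — the
false-positive rate remains controlled — but z1 should not be treated as a
pivotal N(0,1) quantity in that corner of the parameter space. The test
suite asserts both behaviors (calibration at non-degenerate nulls,
conservativeness at the degenerate one).

Numerical conventions: correlations with |r| ≥ 1−1e−12 are clamped in the
variance formulas (warning); a negative quadratic form from rounding is
clamped to zero (warning); D_se = 0 with D = 0 yields p3 = 1; partial
correlations overshooting [−1, 1] numerically are clipped with a warning.

## The decision table and multiple testing

Circumstances over (p1, p2) at levels (α1, α2), default 0.05 each:
1. p1 < α1, p2 ≥ α2 — interference (the regulator carries the pair's
   coordination);
2. both significant — interference iff p3 < α3;
3. p1 ≥ α1, p2 < α2 — interference (coordination emerges only given z);
4. neither — the triplet is discarded.

Comparisons are strict (`p < α`). Each interfering triplet contributes its
*operative* p-value — p1, p3, or p2 for circumstances 1, 2, 3 — to a joint
per-layer multiplicity correction (Benjamini–Hochberg default; Bonferroni
and none selectable; a `p3_only` mode corrects only circumstance-2
triplets). Interference is then re-declared as p_adjusted < α. Correction
is per layer: each layer is an independent screen. Triplet evaluation is
order-independent and canonically ordered (sorted identifiers), so reruns
are exactly reproducible.

## Layer selection

* `topk` / `percent`: regulators ranked by interference count, ties broken
  by larger summed |D| over interfered pairs, then lexicographic identifier.
* `wscca`: maximize uᵀXᵀYv − λ‖W∘v‖₁ subject to ‖u‖₂ = ‖v‖₂ = 1, with
  W_i = (max interference count) − (count of candidate i). The weighted ℓ₁
  penalty is *subtracted*: an added penalty in a maximization cannot
  produce sparsity, and the subtracted form yields the standard
  alternating solution — u ← XᵀYv/‖XᵀYv‖₂, v ← soft-threshold(YᵀXu, λW)
  then ℓ₂-normalize — whose objective is provably non-decreasing.
  Candidates at the maximal count have W_i = 0 and are never thresholded
  out. λ is chosen on a 20-point log grid spanning [1e−3, max_i
  |(YᵀXu₀)_i|/max(W_i, ε)] by k-fold cross-validation (seeded folds,
  shared across the grid) maximizing the held-out canonical correlation
  |cor(X_test u, Y_test v)|; the final fit uses λ·lam_scale, where
  lam_scale = 2 trims a layer to its most persistent regulators.
  Convergence: successive v change < 1e−6 or 500 iterations; v is
  initialized at the leading right singular vector of XᵀY with a
  deterministic sign convention.

The held-out-correlation CV criterion is a design choice; nothing in the
construction prescribes one.

## Bottom-up recursion and edges

Each round promotes the selected regulators to a new layer, removes them
from the candidate pool, and treats them as the next bottom layer with the
same significance levels. Construction stops at the requested depth, when
a round selects zero regulators ("terminated automatically"), or when the
pool empties; the stop reason is recorded. Interference is defined on
*pairs*; an edge is drawn from each selected regulator to every distinct
bottom-layer gene occurring in its interfered pairs, with the pair list and
the best adjusted p-value kept as edge evidence. Within-layer edges are not
inferred.

## The synthetic benchmark

`generate_network` plants a tiered regulator DAG: tier-1 regulators drive
2–fanout bottom (pathway) genes each, with every bottom gene covered;
higher tiers drive the tier below; decoys drive nothing. Roles are
assigned to gene identities at random per seed. `simulate_expression`
walks the DAG top-down: top-tier regulators and decoys are iid N(0,1);
every regulated gene is f(a/sd(a)) + N(0, noise_sd²), where a is the
weighted parental sum (weights ±U(0.5, 1.5) per edge) and f is tanh
(default) or the identity (`transfer="linear"`). Standardizing the
pre-activation keeps genes on a common scale before the transfer function.

Defaults mirror the reference benchmark: 200 genes (48 bottom, 26
positives in two tiers, 126 decoys), 100 samples, noise sd 0.3 — giving
regulator→target Spearman correlations around 0.9, strong but within what
co-regulated pathway genes show in real compendia. Under these conditions
one-layer construction with top-50 selection recovers a median 26/26 true
regulators over 21 seeds (`scripts/acceptance.py`).

What the generator does *not* emulate: kinetic regulation models,
TF cooperativity/combinatorial logic, cell-type mixtures, batch structure,
or correlated decoys (decoys are independent noise, so specificity here is
an upper bound on what correlated negatives would allow). Passing the
benchmark shows the statistical machinery ranks genuinely coupled
regulators above uncoupled candidates; it does not certify performance on
real compendia.

### The hierarchy-recovery benchmark

`hierarchy_benchmark` plants a 3-tier *linear* cascade (24 bottom genes,
tier sizes 11/5/2, 40 decoys) in the regime closest to the method's
premise that regulatory influence attenuates with distance: pathway genes
are tightly coupled to their direct regulators (noise sd 0.4, link ρ≈0.91)
while regulated regulators are loosely coupled to their parents
(noise sd 2.0, link ρ≈0.45) — reflecting that TF activity is substantially
post-transcriptional, so TF–TF mRNA correlations run well below
TF–structural-gene correlations. Layers are built with top-k at the true
tier sizes.

Observed behavior (and a real limitation of count-based ranking): true
tier-1 regulators are strongly enriched in the first built layer
(hypergeometric p < 3·10⁻⁴ in every seed; mean tier-1 assignment accuracy
≈0.8), but exact per-tier assignment degrades sharply above tier 1 (mean
accuracy ≈0.35 for tier 2, lower for tier 3). The cause is structural:
with strong links, an indirect regulator's larger descendant set gives it
*more* interfered pairs than any single direct regulator; with weak links,
counts are dominated by sampling noise; and circumstance 1 credits an
indirect regulator whenever a borderline partial correlation fluctuates
above α. Surveyed alternatives (uniform strong or weak links, chain-topped
hierarchies, smaller sample sizes) do not escape this trade-off. The
hierarchy built should therefore be read as "strongly enriched for true
regulators, ordered only approximately by regulatory distance".

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| alpha1/alpha2/alpha3 | 0.05 | levels for correlation / partial / difference tests |
| correction, correction_alpha | BH, 0.05 | per-layer multiplicity control of operative p-values |
| selection_mode; k / percent | wscca | layer-size rule |
| lam_scale, cv_folds | 1.0, 5 | WSCCA λ scaling and CV folds |
| max_layers | 1 | layers to build above the pathway |
| seed | 0 | drives CV folds and all simulation |
| noise_sd (generator) | 0.3 | per-gene noise sd around the transfer function |

Problem sizes used by the shipped checks — 50,000 Monte-Carlo datasets of
n = 800 for the covariance oracle, 2,000 replicates of n = 200 for
calibration, 21 seeds of the 200-gene benchmark (≈171,000 triplets per
seed), 6–8 seeds of the hierarchy cascade — were chosen so each check's
sampling error is small relative to the margins it asserts.
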