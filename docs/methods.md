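# Methods

## Model and procedure

Given *N* observations with pairwise dissimilarities and an inversion-free
linkage rule, agglomerative clustering yields a binary tree whose internal
nodes carry merge heights h and leaf counts. The distinctness of the data
subset under a node *n* is measured by its tightness,

    S(n) = (h(P(n)) - h(n)) / h(P(n)),

the height gap to the parent *relative* to the parent's height. On
inversion-free trees S ∈ [0, 1]; S(leaf) = 1 identically; S = 0 when a node
merges at its parent's height. The relative form is the point of the
statistic: a linear (absolute) height gap ranks a tight cluster at small
dissimilarity scales below an equally distinct cluster at large scales,
whereas S scores them alike, so all nodes of the tree can be examined
simultaneously rather than top-down. A children-based variant
S₂(n) = (h(n) - max(h(c₁), h(c₂))) / h(n), defined for every internal node
including the root, is provided as a documented alternative
(`statistic="children"`); its exact algebraic form is an interpretation (the
parent-free mirror of S using the taller child) and the statistic is
pluggable behind the same null machinery.

Degenerate case: when the relevant denominator is 0 (all-identical
observations collapse the whole tree to height 0), S is defined as 0 — no
branch can be distinct within identical data. This also keeps division safe.

## Null distribution and leaf-count matching

The null is sampled by randomizing the *data matrix* — never the
dissimilarities — re-growing the tree, and reading off tightness values.
Because the null distribution of S shifts toward larger values for smaller
branches, null values are matched to each observed node's leaf count *k*:

- if the null tree contains nodes with exactly *k* leaves, the *maximum* S
  among them joins the sample for *k*;
- otherwise the maximum S over all nodes at the nearest leaf count below and
  the nearest above joins the sample (one-sided at the extremes).

Taking maxima makes the sampled null stochastically dominate the tightness
of any single matched node, i.e. the test errs on the conservative side.
One randomization serves every observed leaf count at once; results are
identical to a per-node procedure because the per-*k* value depends only on
the null tree. The root of a null tree is excluded from the matching table
for the parent statistic, mirroring the observed tree. Since S = 1 for every
leaf, single leaves are never testable and *k* ≥ 2 throughout.

Randomization schemes (`scheme=`):

- `columns` (default): each variable's values are permuted independently —
  appropriate when variables are exchangeable across observations, e.g.
  per-gene permutation of expression matrices.
- `grouped`: variables are partitioned into groups (e.g. genomic cores
  grouped by chromosome) and one row permutation is applied jointly to all
  columns of a group, preserving within-group dependence exactly.
- `margins`: for strictly 0/1 matrices (e.g. mutation status), a
  checkerboard 2×2-swap Markov chain preserving all row and column sums.
  Burn-in defaults to 10× the number of ones — a common heuristic for swap
  chains, exposed as `n_swaps`, with an attempt cap so that matrices with a
  unique margin-preserving configuration terminate.
- `pool`: every entry resampled with replacement from the pooled empirical
  distribution of the matrix; intended for one-dimensional data, where
  per-column permutation cannot change the tree. Note a real limitation,
  established empirically in this package's validation: for clustered 1-D
  data the pooled bootstrap reproduces the cluster structure itself in every
  null draw, so observed branches are essentially never significant against
  it. It is retained as the specified 1-D scheme, with this caveat; see
  "Known limitations".

Reproducibility: a single user seed spawns index-addressed child streams
(`numpy.random.SeedSequence.spawn`), one per permutation, so serial and
reordered execution agree bit for bit.

## P-values, tail approximation, multiplicity

Empirical p-values use the add-one convention
p_e = (1 + #{null ≥ S_obs}) / (1 + M) over M permutations (never zero; ties
count as exceedances, the conservative direction). Every internal node
except the root is tested — N − 2 tests — and the family-wise correction is
Šidák, p = 1 − (1 − p_e)^(N−2) (Bonferroni min(1, (N−2)·p_e) behind
`correction="bonferroni"`), computed in expm1/log1p form to stay accurate
for tiny p.

The corrected threshold for α = 0.05 falls below 1/(M+1) already for modest
trees (N = 60 needs p < 8.8×10⁻⁴, unreachable with M = 1000 empirical
permutations), so by default the upper tail of each null sample is
approximated by extreme-value theory: exceedances over the 90% quantile of
the null sample (`tail_fraction=0.1`) are fitted by a generalized Pareto
distribution by maximum likelihood (location 0), and for S_obs above the
threshold

    p = (n_exc / M) · (1 − F_GPD(S_obs − threshold)),

floored at machine epsilon; below the threshold the empirical p-value is
returned unchanged. Fit quality is checked by a Kolmogorov–Smirnov test
against the fitted distribution (chosen because no Anderson–Darling variant
for the generalized Pareto is available in the numerical stack); on failure,
or with fewer than 10 exceedances, or a degenerate (constant) tail, the
threshold is raised stepwise (tail fraction halved, twice at most) before
falling back to the empirical p-value with a warning. EVT needs at least 100
null values for a stable fit and is accurate to roughly a factor of 2 at
p ~ 10⁻⁴ with a few hundred exceedances — adequate here because decisions
are made at thresholds orders of magnitude above that noise floor in
well-powered settings, and verified in the tests both against a known
generalized Pareto generator and against empirical p-values in the
[0.01, 0.2] range (agreement within ±50%).

## The most detailed significant partition

A partition of the observations is significant at threshold α when every
part is a branch and every part's parent node has at least one child with
corrected p strictly below α (leaf children never qualify). The most
detailed such partition is extracted by the recursion

    can_split(n) = has_significant_child(n)
                   or (can_split(c1) and can_split(c2))

evaluated bottom-up, followed by a descent from the root through `can_split`
nodes; the frontier is the partition. The second disjunct is legitimate
because a node both of whose children are split is not the parent of any
part, so the significance clause does not apply to it; conversely a part's
parent can only have been split via a significant child (the part itself is
unsplit), so every returned part satisfies the definition. Maximality holds
because any valid split set is contained in the `can_split` set; the test
suite confirms it by exhaustive enumeration of all branch partitions on
small trees. When the root cannot split, the trivial one-part partition is
returned flagged `is_significant=False`. Ties p = α count as not significant
(strict inequality); raising α only refines the partition.

## Evaluation against a reference labeling

The Rand index is the fraction of object pairs on which two partitions
agree. The corrected Rand index (cRI) is the Hubert–Arabie adjustment,
subtracting the hypergeometric expectation of concordance at fixed part
sizes; the degenerate case where both partitions carry no pair information
(adjustment denominator 0) scores 1 if they are identical and 0 otherwise,
so a trivial one-part partition scores 0 against any informative truth.
Because parts found on a tree are necessarily branches while true classes
need not be, the attainable ceiling is the *best branch partition* — the
branch partition maximizing cRI against the truth — found by exhaustive
enumeration when the tree has at most `enumeration_cap` branch partitions
(the count obeys C(node) = 1 + C(c₁)·C(c₂)) and otherwise by split/merge
hill climbing from several starting frontiers with random restarts, flagged
as heuristic in the output. The *relative cRI* of a computed partition is
its cRI divided by the ceiling (undefined, returned as NaN, when the ceiling
is not positive). The alternative reading of "relative" — cRI *between* the
computed and the best branch partition — can be computed directly with
`corrected_rand(computed, best)`.

## Synthetic data

`gen_mixture_1d` draws n = 280 points from the 1-D normal mixture
N(0.5, 0.4²), N(11, 1²), N(5, 2²) with weights (0.25, 0.25, 0.50). The two
outer components form tight branches under single linkage on absolute
differences; the weights are a package choice (the outer components visible
against a broad middle background) and are parameters of `MixtureSpec1D`.

`gen_simulated6` emulates a classic simulated gene-expression design: 60
observations × 600 variables, six subtypes of sizes 8, 12, 10, 15, 5, 10;
300 background genes i.i.d. N(0, 1) everywhere; six disjoint 50-gene blocks
each shifted upward by `effect_shift` (default 2.5, in background-SD units —
a package choice making the six blocks cleanly separable under both
Euclidean/complete and correlation/average clustering) for its own subtype
only. Setting `exceptional_column=7` additionally up-regulates the second
subtype's block for the eighth observation, reproducing the published
design's exceptional column; it is off by default because a correct analysis
then rightly isolates that observation as a seventh part, which is the
interesting behaviour of the stress variant, not of the baseline.

`gen_noise_matrix` (i.i.d. standard normal) and `gen_binary_matrix`
(i.i.d. Bernoulli) provide null-calibration and fixed-margin fixtures.

What the generators do *not* emulate: heavy-tailed measurement noise,
gene–gene correlation within the background, batch structure, and unequal
per-class covariances. Passing the recovery and type-I tests on these
fixtures therefore demonstrates correctness of the machinery under clean
exchangeable noise, not robustness to the full messiness of real assays.

## Problem sizes and numerical choices

Defaults: `n_perm=1000`, `alpha=0.05`, `use_evt=True`, `tail_fraction=0.1`,
Šidák correction, Euclidean/complete clustering. The validation suite runs
the six-subtype recovery at 20 seeds × 1000 permutations, type-I control at
200 noise matrices (30×100) × 1000 permutations, the null-shape trend at
500 randomizations, and the 1-D demonstration at 50 seeds × 1000
permutations — sizes chosen so the whole suite completes in a few minutes on
one CPU while keeping binomial tolerances meaningful. Ward linkage uses the
Lance–Williams update on whatever dissimilarity is supplied (so Ward with
correlation dissimilarities is allowed); heights follow the standard
agglomerative convention, and since S is scale-free within a tree, Ward
height-scaling conventions do not affect any downstream quantity. Merge
tie-breaking follows the deterministic order of the underlying agglomerative
implementation, so repeated runs are identical. Tiny negative correlations
arising from round-off are clipped to 0 on the 1 − r scale; tree validation
tolerates height noise of 10⁻¹⁰ when checking monotonicity.

## Known limitations

- **Single leaves are never significant** (S = 1 identically), so a lone
  outlier can only appear as a part when its sibling branch is tight.
- **Anti-conservatism under correlation dissimilarity on strongly clustered
  data.** The fully-permuted null destroys *all* structure, while within-class
  sub-branches of the observed tree live at a different dissimilarity scale
  with different relative-gap noise. Under (1 − Pearson)/average linkage on
  the six-subtype design at effect 2.5, genuine-noise sub-branches inside a
  class reach p below the corrected α = 0.05 threshold in a substantial
  fraction of realizations (verified by 20 000-permutation brute force, so
  this is a property of the null construction, not of the tail
  approximation), producing partitions finer than the generating truth. The
  family-wise guarantee is calibrated against the global
  no-structure null, not against the "truth plus noise" alternative.
- **The pooled 1-D scheme is structure-preserving** (see above): bootstrap
  resampling of a clustered univariate sample reproduces its gaps, so the
  1-D demonstration has essentially no power against that null.
- **EVT tail estimates are noisy at extreme depths**: roughly factor-of-2
  accuracy at p ~ 10⁻⁴ per fitted null; borderline decisions within that
  factor of the corrected threshold can go either way between seeds.
- The heuristic best-branch search is not guaranteed optimal on trees too
  large for enumeration; its output is flagged.
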