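# Methods

## Scope and model

`saltrait` analyses the macroevolution of a rare binary ecological trait
(salt tolerance, coded 1/0 at the tips of a phylogeny) at two levels:

1. **Taxonomic**: are trait-positive species spread across families as a
   single global binomial rate would predict?
2. **Phylogenetic**: within a family subtree, are the trait-positive
   tips arranged in few deep clades or many shallow ones, relative to a
   Brownian-motion threshold null?

All phylogenetic statistics operate on rooted, fully bifurcating trees
with **every branch length equal to 1**. This is a deliberate modelling
convention, not a simplification of convenience: the trees this method
targets are assembled from heterogeneous sequence data whose branch
lengths are unreliable at this scale, and the equal-length convention
makes the Brownian variance of a node proportional to its depth in edge
counts. Polytomies must be resolved (randomly, seeded) before any metric
is computed.

## Taxonomic stage

Given per-family species counts `n_i` and trait-positive counts `k_i`,
the global proportion is `p̂ = Σk_i / Σn_i`. Each family is tested
against `Binomial(n_i, p̂)` with two one-sided tails computed through the
regularised incomplete beta function (scipy), which is exact to double
precision at any `n` — no normal approximation at any size. The
classification rules are strict inequalities at α = 0.05 on each tail;
a tail probability exactly equal to α is *not* significant. No
multiple-testing correction is applied across families: the verdict
column is a descriptive screen, and both tail probabilities are always
reported so users can apply FWER/FDR control themselves.

The overall goodness-of-fit G-test uses the likelihood-ratio statistic
`G = 2 Σ O ln(O/E)` over the full families × {trait, non-trait}
contingency table, expecteds from the margins, `df = #families − 1`,
chi-square upper tail. Cells with `O = 0` contribute zero. With
heavy-tailed family sizes some expected counts are small and the
chi-square reference is mildly anticonservative; the test suite checks
the null rejection rate within a documented band (0.02–0.09 at nominal
0.05) rather than asserting exact nominal coverage.

## Phylogenetic stage

**Origin counting.** Ancestral states are reconstructed by equal-cost
minimum-change parsimony via a two-key dynamic programme: each node ×
state carries a (changes, gains) cost pair packed into one integer and
minimised lexicographically, so among all minimum-total-change
reconstructions the one with the fewest 0→1 edges is selected. The tree
is treated as hanging from a virtual state-0 ancestor; consequently a
reconstruction in which the trait is present at the root costs one
change and counts as exactly one gain (an all-positive tree has one
origin, not zero). This convention keeps the identity
`total changes = gains + losses` and matches the scientific question —
the minimum number of independent origins needed to explain the extant
tips. Ties among equally optimal reconstructions do not affect the gain
*count* (the DP minimum is unique); the reported edge set is one
deterministic optimum (first-index tie-break on the backtrack).

**NoTO** = trait-positive tips / gains, in [1, k]. Reported at full
precision internally and rounded to 1 decimal only in display output.

**SSCD**: post-order pass assigning each internal node the mean of its
two children's values, summing |left − right| over internal nodes.
Defined only on bifurcating trees; the implementation raises on
polytomies rather than silently averaging more than two children.

**Null model.** Brownian motion with root value 0 and independent
N(0, branch length) increments; with unit branches, a node's variance is
its edge-count depth. Tip values are dichotomised by rank so that
exactly `k` tips are positive in every replicate (asserted per
replicate); ties — probability zero for continuous draws — would break
by stable tip order. Because thresholding sees only ranks, the diffusion
variance is unidentifiable and fixed at 1; the test suite verifies that
rescaling the increments leaves every thresholded map bit-identical.

The p-value inequalities are intentionally asymmetric, preserving the
original test's framing: `p_noto` counts simulated NoTO **≤** observed,
`p_sscd` counts simulated SSCD **>** observed (a non-strict variant is
exposed as an option). P-values are counted proportions over `n_sims`
(default 1000), so they are multiples of `1/n_sims` and can be exactly 0
or 1; an optional conservative mode uses `(r+1)/(n+1)`. Replicate
randomness derives from a spawned child of the master seed, so results
are bit-reproducible for a given seed. In reports, `p ≤ 0.05` on either
metric is labelled a labile signal; `p ≥ 0.95` on both is *flagged* (not
tested) as conserved, since the conserved end has no conventional
threshold.

Because NoTO takes few distinct values (`k/g` for small integer `g`),
null-calibrated `p_noto` is uniform only at the atoms of its null
distribution. The calibration test therefore bounds the one-sided
(superuniformity) KS excess by Monte-Carlo error alone (0.09, the
99th-percentile one-sided bound at 500 replicates, rounded up) and the
two-sided KS distance by the largest simulated atom mass plus the same
error — both derived before running, not fitted.

## Tree preparation

Family subtrees are the clade at the MRCA of the family's tips;
non-monophyly is handled by pruning out-of-family intruder tips from
that clade, with every removed name logged (the reproducible abstraction
of what is otherwise a manual curation step). Tip-name cleaning drops
names containing an indeterminate epithet **token** — `af`, `aff`, `cf`,
`sp`, case-insensitive, optional trailing period — or a hybrid format
(the token `hybrid`, or two epithets separated by the token `x`). Token
matching, never substring matching: `Spartina` and `Sporobolus` survive.
Halophyte matching is exact after case-folding and separator
unification; infraspecific tips are *not* collapsed to species, and no
fuzzy matching is attempted — silent false positives are worse than
missed matches here. Random polytomy resolution delegates to dendropy's
seeded resolver, after which every branch length is overwritten with 1.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes,
with planted ground truth:

- **Trees**: Yule (pure-birth) topologies grown by bifurcating a
  uniformly chosen extant leaf, then all branch lengths set to 1. The
  Yule shape is a stand-in — real angiosperm trees are shaped by
  variable diversification and 20 % sampling — so passing tests
  demonstrate correctness of the statistics, not realism of tree shape.
- **Planted origins**: `m` disjoint clades covering `k` tips, each
  chosen clade's sister subtree retaining a state-0 tip. Stem separation
  alone does not guarantee exact recovery (with few state-0 tips a
  root-positive labelling can tie on total changes and win the
  fewest-gains tie-break), so every candidate placement is verified to
  reconstruct to exactly (`m` gains, 0 losses) before being returned —
  the verifying DP is itself checked against exhaustive enumeration
  elsewhere in the suite, so the check is not circular. Search is
  randomized greedy with restarts; failure raises an explicit
  infeasibility error, never a silently relaxed placement.
- **Family tables**: sizes log-normal (μ = 5.4, σ = 1.5 on the log
  scale, rounded, minimum 1), chosen so the mean family size ≈ 670
  species matches ~276,000 species over 411 families while keeping the
  heavy right tail real family-size distributions show; counts
  `Binomial(n_i, min(1, p·e_i))` with per-family enrichment factors
  `e_i` (1 = null). Default global rate 0.0103, the observed halophyte
  proportion.
- **Dirty names**: mixtures of clean binomials, indeterminate-epithet
  and hybrid formats with ground-truth keep/drop flags.

Everything flows through per-call seeded numpy generators; identical
seeds give bit-identical outputs.

## Problem sizes

The packaged survey covers the published 22 families; its arithmetic is
exact and instantaneous. Simulation-based checks use sizes chosen to
keep the full suite fast while leaving no statistical ambiguity:
parsimony oracle equivalence on exhaustive 8-tip state spaces plus 500
random ≤12-tip instances; planted-origin recovery on 500 random feasible
configurations up to 64 tips and 6 origins; null calibration with 500
observations × 200 simulations on a 24-tip tree; demonstration
geometries (conserved: one 29-tip clade on 42 tips; labile: 40 origins
on 200 tips) at the full 1000 replicates.

## Known limitations

- Parsimony counts are minima: gains erased by extinction or reversal
  are invisible, so NoTO is an upper bound on tips-per-origin.
- The binomial screen treats family sizes as known constants; they are
  published mean estimates.
- The Brownian-threshold null conditions on the tree and on `k`; it does
  not model trait-dependent diversification.
- The G-test's chi-square reference degrades when many families are
  tiny relative to `1/p̂`.
- Synthetic trees are Yule-shaped; conclusions about robustness to real
  tree imbalance or to incomplete sampling require the archived
  full-scale inputs, which are not distributed with the package.
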