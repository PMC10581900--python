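# Methods

This note documents the models, algorithms and numerical choices behind
phytodisparity, and what the synthetic study conditions do and do not show
about real data.

## Character model and imputation

Characters are unordered and evolve independently under the equal-rates
(ER) Mk process: k states, every specific change at rate *q* per Myr, so
the total leaving rate is (k−1)q. The transition probabilities have the
closed form P(same) = 1/k + (1 − 1/k)e^(−kqt), P(each other state) =
1/k − (1/k)e^(−kqt); rows sum to one for all q, t, k. The root prior is
uniform. Likelihoods use Felsenstein pruning with per-node rescaling, so
matrices of hundreds of taxa pose no underflow risk.

*Rate treatment.* The Mk family fixes the model but not the per-character
rate; we fit *q* per character per tree by bounded 1-D maximum likelihood
on log10 q ∈ [−8, 3] (Brent, xatol 1e−4). Characters with fewer than two
distinct observed states have a likelihood monotone in q → 0 and receive
a floor rate of 1e−8 per Myr, flagged `at_floor`. ER is the standard
choice for heterogeneous morphological supermatrices; asymmetric and
ordered models are out of scope.

*Stochastic mapping.* Joint node states are sampled root-down from the
pruning conditionals; observed tips are fixed with probability 1, missing
and inapplicable tips are free over the character's *observed* states
(states never observed for a character cannot be assigned meaningfully).
Within-branch histories are drawn by uniformization with total rate
μ = kq, whose jump chain is the uniform k×k matrix: the virtual-jump count
is Poisson(μt) conditioned on the endpoints (inverse-cdf sampling) and
intermediate states are i.i.d. uniform, which is exact — no rejection
loop is needed, though the count sampler guards against cdf rounding with
a hard cap at 1000 + 100·μt jumps.

*Consensus.* Per character and per tree the modal sampled state is kept
(default 1,000 maps per character per tree); the cross-tree consensus is
the modal state of the per-tree modes, ties broken to the lowest state
code with a recorded tie flag, so runs are deterministic and auditable.
Node correspondence across trees uses exact clade (tip-set) matching
against the first tree of the sample; nodes of other trees without an
identical clade contribute nothing for that tree. Inapplicable cells pass
through imputation unchanged; characters with zero scored tips stay
missing with a warning.

*Seeds.* One master seed fans out into named per-stage streams and, inside
imputation, into a deterministic stream per (tree, character) via
`numpy.random.SeedSequence` spawn keys, so any subset of the work is
reproducible in isolation.

## Distances

Gower dissimilarity: mismatches / comparable characters, any state
difference scoring 1 (unordered). A character is comparable for a pair
only when both cells are coded; under the default
`zero_mode="ignore_matching_zeros"` a shared state 0 is also excluded, so
shared absence and shared (absence-recoded) inapplicability contribute no
similarity. Whether an analysis should ignore all matching zeros or only
inapplicability-driven ones is not decidable in general, so both modes are
first-class and the tests exercise both. Pairs with an empty comparable
set are imputed to the maximum observed distance and flagged rather than
failing the run; ordination gives them zero weight. The Euclidean
alternative rescales each pair by sqrt(total/comparable) so sparsely
compared pairs are not biased small.

## Ordination

NMDS is SMACOF stress majorization with isotonic disparities: per
iteration the disparities are the weighted isotonic regression of current
configuration distances on dissimilarity order, rescaled to a fixed sum of
squares (stress-1 is scale-invariant, so without an anchor the
configuration drifts toward collapse), followed by a weighted Guttman
transform (pseudo-inverse of the weight Laplacian when flagged pairs zero
out weights). Stress-1 = sqrt(Σw(d̂−d)²/Σw d²) is recorded per iteration
and is non-increasing in practice; iteration stops when it improves by
less than 1e−7 (max 500 iterations), and the best of 20 random starts is
returned, axes standardized (centred, principal-axis rotation, signs fixed
by the first unit). Tie handling is Kruskal's primary approach by default;
a secondary (tie-averaging) mode exists because rank structure alone is
degenerate when few points produce few distinct dissimilarities (four
points at square corners rank-fit any rectangle).

PCoA double-centres the squared dissimilarities and eigendecomposes;
coordinates use positive eigenvalues only, the full spectrum including
negatives is reported uncorrected as the metricity diagnostic (no Cailliez
correction by default). An all-identical input returns all-zero
coordinates and stress 0 by definition.

## Disparity and disparity through time

Mean disparity is the mean pairwise distance within a clade; partial
disparity is Σ members' squared distance to the grand centroid / (n−1)
with n the total units embedded, so over any partition the values sum
exactly to the total sum of variances (unsquared distances are available
behind a flag but break additivity). Bootstraps resample the units of the
statistic being computed — group members — with replacement (1,000
replicates by default), holding the grand centroid fixed for partial
disparity; envelopes are the 2.5/25/75/97.5 percentiles.

DTT slices the dated tree at 0, 50, 100, … Ma plus the root age. A branch
crosses a slice when parent age > t ≥ child age (closed at the child, so
the present-day slice is exactly the extant tips and a slice at a node's
age returns that node's own coordinates). Gradual evolution interpolates
linearly between parent and child embeddings in proportion to elapsed
time; the punctuated model inherits a uniformly chosen endpoint per branch
and re-randomizes that choice in every bootstrap replicate, so model
uncertainty propagates into the envelopes. Slices with fewer than two
lineages score 0 and are flagged. Zero-length branches are permitted but
never host interpolated states (the closed-at-child rule resolves them to
the child).

## Complexity and ploidy

Complexity is the count of present-coded characters per unit; inapplicable
recodes to absent in the presence matrix, with the proportion-applicable
score (applicable / non-missing cells; a flag includes missing in the
denominator) as the robustness alternative. Node complexity uses the modal
consensus call per character; an expected-score mode sums per-character
present frequencies, giving the fractional node values that averaging over
trees and simulations produces. Ploidy events are consumed as per-branch
counts; cumulative tip counts are root-to-tip path sums, never inferred.

The headline association test is the independent-contrasts Pearson
correlation through the origin; the t-based p uses df = n_tips − 2
(= n_contrasts − 1), the exact null for isotropic contrasts. Polytomies
are folded pairwise with zero-length internal edges, so any rooted tree
yields n_tips − 1 contrasts and an equal-branch star recovers the ordinary
Pearson correlation of the raw values. A plain Spearman on tip values is
provided alongside. Contrasts with zero pooled branch length raise rather
than guess.

## Statistics

The Mantel test correlates off-diagonal upper triangles under simultaneous
row/column permutation of one matrix, one-tailed (greater) by default to
match directional hypotheses, add-one p (never 0), with an exhaustive
enumeration mode for tiny n. Reports embed coefficient, p, n, permutation
count and seed. Pearson/Spearman delegate to scipy (t approximation,
mid-ranked ties).

## Synthetic study conditions

The generator emulates a clade-structured morphological supermatrix.
Defaults, chosen once as the study conditions:

- tree: forward birth–death (birth 0.025, death 0.01 per Myr) run from two
  lineages until 64 extant lineages exist, extended to just before the
  next event (so conditioned pure-birth root ages have mean
  Σ_{k=2..n} 1/(kλ)); extinct lineages become fossil tips, thinned to 16.
  Root ages land around 250–300 Myr, a deep-time scale.
- characters: 200, state counts 2/3/4 with probability 0.7/0.2/0.1, rates
  lognormal around a median of 0.004 per Myr (morphological characters are
  conserved; this yields a few expected changes per root-to-tip path, with
  the lognormal tail providing saturated characters), eight overlapping
  trait categories; an optional rate multiplier inside one root clade
  creates two-regime structure.
- missingness: 20% i.i.d. on extant tips; fossils lose entire categories
  (default gametophytic + cellular) — block masking reproduces the real
  failure mode of fossils clustering on shared missing data, which the
  imputation stage is tested to remove.
- ploidy: Poisson events at 0.004 per Myr per branch; an optional coupling
  flips `effect × inherited events` absent characters to present per tip,
  creating a known true complexity association (the acceptance script's
  recovery experiment uses rate 0.02 and effect 4 so the signal is
  clearly detectable at 80 tips).
- tree samples: posterior spread is emulated by lognormal branch-length
  jitter (σ = 0.1) on a shared topology. This is a synthetic stand-in:
  real posterior samples vary in topology, so the clade-matching consensus
  path is exercised only partially by it.

What passing on these conditions does *not* show: characters are
independent and ER — correlated evolution, ordered states or
rate heterogeneity across branches beyond the regime multiplier are not
represented; missingness is independent of state; fossil placement is
error-free. Real-data behaviour on those axes is untested here.

## Problem sizes and runtime

The default pipeline (80 tips × 200 characters, 1,000 maps/character,
1,000 bootstrap replicates) completes in well under a minute on one CPU.
The acceptance script uses the same study conditions with 500
maps/character, 500 bootstrap replicates and 499 Mantel permutations; the
test suite scales some experiments down (e.g. 32+8 tips × 60 characters
for the imputation-monotonicity suite, a 20+5-tip pipeline for the
byte-determinism check) — sizes chosen so the whole suite runs in a couple
of minutes while keeping every property measurable.

## Known limitations

- Node consensus requires exact clade matches across the tree sample;
  heavily conflicting topologies leave some nodes supported by few trees
  (logged, and visible as sparse frequencies in the imputation report).
- NMDS stress on saturated high-dimensional simulations is substantially
  higher than on strongly clustered empirical matrices; stress, the
  Shepard data and the PCoA eigenvalue spectrum are all reported so users
  can judge dimensionality for their data.
- Undefined distance pairs are imputed to the observed maximum; with very
  sparse matrices many flagged pairs will erode the ordination even with
  zero weights.
- The punctuated DTT point estimate is itself a random draw (seeded); use
  the bootstrap envelopes, not the point curve, for inference.
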