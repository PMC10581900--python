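# phytodisparity

Quantitative morphospace analysis for discrete morphological character
matrices on dated phylogenies — the workflow used to study how phenotypic
disparity and complexity evolve across a clade such as the plant kingdom,
where living taxa are scored in detail but fossils carry large blocks of
non-random missing data.

The package is aimed at morphologists and phylogeneticists who have:

- a taxa × characters matrix of unordered discrete states (0–9), with `?`
  for unknown and `-` for inapplicable cells, optionally partitioned into
  trait categories (sporophytic, gametophytic, …);
- one or more rooted, time-calibrated trees (Newick or a NEXUS TREES
  block) linking the same taxa;
- optionally, per-branch counts of whole-genome-duplication (polyploidy)
  events.

## What it computes

**Imputation by consensus stochastic mapping.** Each character evolves
under the equal-rates Mk model (k unordered states, every change at rate
*q* per Myr; P(same) = 1/k + (1 − 1/k)·e^(−kqt)). Per character and per
tree the rate is fitted by maximum likelihood, observed tips are fixed
with probability 1, missing tips get a uniform prior over the character's
observed states, and stochastic maps (default 1,000 per character per
tree) sample joint node and tip states from the Felsenstein-pruning
conditionals. The modal state per tree, then the modal state across trees,
fills the missing cells and reconstructs every internal node, yielding a
*focal matrix* over tips and ancestors.

**Morphospace.** Gower dissimilarity over comparable characters — a
character counts for a pair only when both cells are coded and, by
default, not a matching zero, so shared absence or inapplicability adds no
similarity. Non-metric multidimensional scaling (SMACOF majorization with
isotonic disparities, Kruskal stress-1, dimensions constrained to 2) with
a PCoA/Euclidean cross-check (Mantel test on the two embeddings'
distances). A *phylomorphospace* embeds tips and reconstructed ancestors
jointly and pairs every node with its children for branch plotting, with
convex hulls per clade.

**Disparity.** Per clade: mean pairwise distance and partial disparity
(sum of squared distances to the grand centroid / (n − 1), which sums to
the total sum of variances over a partition), both with 1,000-replicate
bootstrap percentile envelopes. Disparity through time slices the dated
tree every 50 Myr; each crossing lineage contributes an interpolated
(gradual) or randomly inherited (punctuated) morphospace point and the
statistic is the sum of variances per slice.

**Complexity.** Presence/absence recode of the matrix, per-taxon presence
sums, ancestral complexity from the same consensus mapping machinery, and
the phylogenetically corrected (independent-contrasts) Pearson correlation
between complexity and cumulative polyploidy events (plus a plain
Spearman).

A synthetic-data generator produces all inputs with known truth — dated
birth–death trees with extant and fossil tips, Mk characters, i.i.d.
extant missingness, block-by-category fossil missingness, Poisson WGD
events with an optional complexity coupling — so every stage is testable
without any external dataset.

## Worked example

```python
import numpy as np
from phytodisparity import (
    SyntheticScenario, generate, impute_matrix, gower, nmds,
    groups_from_tree, mean_disparity, missingness_silhouette,
)

scenario = SyntheticScenario(n_extant=32, n_fossil=8, n_characters=120)
data = generate(scenario, seed=42)
print(f"tree: {len(data.tree.tip_labels)} tips, root age {data.tree.root_age:.1f} Ma")

focal, result = impute_matrix(data.matrix, data.trees, n_sims=500, seed=42)
recovered = np.mean([
    focal.cells[i, j] == data.truth_matrix.cells[i, j]
    for i, j in zip(*np.nonzero(data.mask))
])
print(f"imputation: {data.mask.sum()} masked cells, {100 * recovered:.1f}% recovered")
print(f"fossil missingness silhouette: "
      f"{missingness_silhouette(data.matrix, data.tree.extinct_tips):.2f} -> "
      f"{missingness_silhouette(focal, data.tree.extinct_tips):.2f}")

d = gower(focal)
morphospace = nmds(d, k=2, seed=42)
print(f"NMDS stress (k=2): {morphospace.stress:.3f}")

clades = groups_from_tree(data.tree, 0.7 * data.tree.root_age)
disparity = mean_disparity(d, clades, n_boot=1000, seed=42)
for grp, g in sorted(disparity.per_group.items()):
    if not g.flagged:
        print(f"clade {grp}: mean disparity {g.estimate:.3f} "
              f"[{g.percentiles[2.5]:.3f}, {g.percentiles[97.5]:.3f}]")
```

prints

```
tree: 40 tips, root age 299.3 Ma
imputation: 1031 masked cells, 79.2% recovered
fossil missingness silhouette: 1.00 -> 0.00
NMDS stress (k=2): 0.215
clade N19: mean disparity 0.582 [0.505, 0.584]
clade N39: mean disparity 0.291 [0.000, 0.291]
clade N5: mean disparity 0.487 [0.383, 0.497]
```

Reading the numbers: 79.2% of deliberately masked cells are recovered
(chance from state frequencies alone is ~51%); the fossil tips' silhouette
on their missingness patterns drops from 1.0 (a pure missing-data cluster)
to 0.0 after imputation; stress 0.215 says two axes summarize this noisy
120-character simulation only approximately; the bracketed values are
2.5/97.5% bootstrap percentiles of each clade's mean pairwise Gower
distance.

The same pipeline runs end to end from the shell:

```bash
phytodisparity run --seed 1 --out results/
phytodisparity generate --seed 1 --out synthetic/     # stage-by-stage
phytodisparity impute synthetic/matrix.csv synthetic/trees.nwk
```

Every run writes a `manifest.json` (master seed, named per-stage seeds,
full parameter echo, versions) sufficient to reproduce all outputs
byte for byte.

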