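"""Phenotypic complexity: presence sums, ancestral scores, ploidy correlation.

Complexity here is the count of characters coded present for a unit.
Ancestral scores reuse the consensus stochastic-mapping machinery on the
binary presence matrix: the modal node call gives an integer score, and an
expected-score mode (summed per-character present frequencies) gives the
fractional values that averaging across trees and simulations produces.

The headline association test is the phylogenetically corrected Pearson
correlation: Felsenstein's independent contrasts for both variables and the
through-origin correlation of the contrasts, alongside a plain Spearman
rank correlation on tip values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .matrix_io import MISSING, CharacterMatrix, PresenceMatrix
from .mk import ImputationResult, impute_matrix
from .stats import CorrelationReport
from .trees import Phylogeny, TreeSample

logger = logging.getLogger("phytodisparity")


@dataclass
class ComplexityProfile:
    """Presence-sum complexity per tip and reconstructed node."""

    tip_scores: dict[str, int]
    node_scores: dict[str, int] = field(default_factory=dict)
    expected_node_scores: dict[str, float] = field(default_factory=dict)
    prop_applicable: dict[str, float] = field(default_factory=dict)
    n_characters: int = 0

    def to_frame(self):
        import pandas as pd

        rows = []
        for unit, s in sorted(self.tip_scores.items()):
            rows.append({"unit": unit, "is_node": False, "score": s,
                         "score_expected": float(s),
                         "prop_applicable": self.prop_applicable.get(unit)})
        for unit, s in sorted(self.node_scores.items()):
            rows.append({"unit": unit, "is_node": True, "score": s,
                         "score_expected": self.expected_node_scores.get(unit, float(s)),
                         "prop_applicable": None})
        return pd.DataFrame(rows)


@dataclass
class PloidyAnnotation:
    """Whole-genome-duplication counts per branch and cumulatively per tip."""

    branch_counts: dict[str, int]  # keyed by child-node label
    tip_cumulative: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.branch_counts.values()):
            raise ValueError("event counts must be nonnegative")

    @classmethod
    def from_branch_counts(cls, tree: Phylogeny, counts: dict[str, int]) -> "PloidyAnnotation":
        per_node = np.zeros(tree.n_nodes, dtype=np.int64)
        for lbl, c in counts.items():
            per_node[tree.labels.index(lbl)] = int(c)
        cumulative = np.zeros(tree.n_nodes, dtype=np.int64)
        for i in range(1, tree.n_nodes):
            cumulative[i] = cumulative[tree.parent[i]] + per_node[i]
        tips = {tree.labels[i]: int(cumulative[i]) for i in tree.tip_indices}
        return cls(dict(counts), tips)

    def to_frame(self):
        import pandas as pd

        rows = [{"branch": b, "count": c} for b, c in sorted(self.branch_counts.items())]
        df = pd.DataFrame(rows)
        df["tip_cumulative"] = [self.tip_cumulative.get(b) for b in df["branch"]]
        return df


def complexity_scores(p: PresenceMatrix) -> tuple[dict[str, int], dict[str, int]]:
    """Per-taxon count of present characters, plus per-taxon missing count."""
    present = (p.cells == 1).sum(axis=1)
    missing = (p.cells == MISSING).sum(axis=1)
    return (
        {t: int(s) for t, s in zip(p.taxa, present)},
        {t: int(m) for t, m in zip(p.taxa, missing)},
    )


def _presence_as_matrix(p: PresenceMatrix) -> CharacterMatrix:
    return CharacterMatrix(list(p.taxa), list(p.characters), p.cells.copy())


def ancestral_complexity(
    p: PresenceMatrix,
    trees: TreeSample | Phylogeny,
    n_sims: int = 1000,
    seed: int | None = None,
) -> ComplexityProfile:
    """Reconstruct per-character node states and sum them into node scores.

    Missing tip cells are imputed by the same consensus machinery first, so
    tip scores come from the completed matrix.  ``expected_node_scores``
    sums each character's present-call frequency instead of the modal call.
    """
    sample = trees if isinstance(trees, TreeSample) else TreeSample([trees])
    focal, result = impute_matrix(_presence_as_matrix(p), sample, n_sims=n_sims, seed=seed)
    tip_scores = {t: int((focal.cells[i] == 1).sum()) for i, t in enumerate(focal.taxa)}
    node_scores: dict[str, int] = {}
    expected: dict[str, float] = {}
    for lbl in result.node_labels:
        total = 0
        exp = 0.0
        for char in focal.characters:
            key = (lbl, char)
            if key in result.consensus:
                total += int(result.consensus[key] == 1)
                exp += result.frequencies[key].get(1, 0.0)
        node_scores[lbl] = total
        expected[lbl] = exp
    return ComplexityProfile(
        tip_scores, node_scores, expected, n_characters=p.n_characters
    )


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts
# ---------------------------------------------------------------------------

def independent_contrasts(tree: Phylogeny, values: dict[str, float]) -> np.ndarray:
    """Felsenstein's standardized contrasts for one trait.

    Polytomies are folded pairwise with zero-length internal edges, giving
    n_tips - 1 contrasts on any rooted tree.  Contrast order is a
    deterministic function of the tree, so contrasts of two traits on the
    same tree pair up correctly.
    """
    missing = [t for t in tree.tip_labels if t not in values]
    if missing:
        raise ValueError(f"tips without trait values: {missing[:5]}")
    x = np.zeros(tree.n_nodes)
    v = np.zeros(tree.n_nodes)
    for i in tree.tip_indices:
        x[i] = float(values[tree.labels[i]])
    contrasts: list[float] = []
    for i in tree.postorder():
        if tree.is_tip[i]:
            v[i] = float(tree.blen[i])
            continue
        kids = tree.children[i]
        cx, cv = x[kids[0]], v[kids[0]]
        for c in kids[1:]:
            denom = cv + v[c]
            if denom <= 0:
                raise ValueError(
                    f"zero-variance contrast at node {tree.labels[i]!r} "
                    "(zero-length branches)"
                )
            contrasts.append((cx - x[c]) / np.sqrt(denom))
            cx = (cx * v[c] + x[c] * cv) / denom
            cv = cv * v[c] / denom
        x[i] = cx
        v[i] = cv + float(tree.blen[i])
    return np.asarray(contrasts)


def pic_pearson(tree: Phylogeny, xvals: dict[str, float], yvals: dict[str, float]) -> CorrelationReport:
    """Through-origin Pearson correlation of independent contrasts.

    p is two-sided from t = r * sqrt(df / (1 - r^2)) with df = n_tips - 2;
    a through-origin fit on the n_tips - 1 contrasts spends one df, which
    is exact for isotropic null contrasts.
    """
    u = independent_contrasts(tree, xvals)
    w = independent_contrasts(tree, yvals)
    su, sw = (u**2).sum(), (w**2).sum()
    if su == 0 or sw == 0:
        raise ValueError("zero-variance contrasts")
    r = float((u * w).sum() / np.sqrt(su * sw))
    n = len(u)
    df = n - 1
    if abs(r) >= 1.0:
        p = 0.0 if df > 0 else 1.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationReport("pic_pearson", r, max(p, np.finfo(float).tiny), n)


def ploidy_complexity_correlation(
    c: ComplexityProfile | dict[str, float],
    ploidy: PloidyAnnotation,
    tree: Phylogeny,
    method: str = "pic_pearson",
) -> CorrelationReport:
    """Correlate tip complexity with cumulative WGD counts.

    ``pic_pearson`` (headline) corrects for phylogeny via independent
    contrasts; ``spearman`` ranks the raw tip values.
    """
    scores = c.tip_scores if isinstance(c, ComplexityProfile) else c
    missing = [t for t in tree.tip_labels if t not in scores or t not in ploidy.tip_cumulative]
    if missing:
        raise ValueError(f"tips lacking complexity or ploidy values: {missing[:5]}")
    if method == "pic_pearson":
        return pic_pearson(
            tree,
            {t: float(scores[t]) for t in tree.tip_labels},
            {t: float(ploidy.tip_cumulative[t]) for t in tree.tip_labels},
        )
    if method == "spearman":
        x = np.array([scores[t] for t in tree.tip_labels], dtype=float)
        y = np.array([ploidy.tip_cumulative[t] for t in tree.tip_labels], dtype=float)
        from .stats import correlate

        return correlate(x, y, "spearman")
    raise ValueError(f"unknown method {method!r}")
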