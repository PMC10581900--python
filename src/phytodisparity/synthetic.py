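"""Synthetic trees, character matrices, missingness and ploidy with known
truth, emulating a clade-structured morphological supermatrix: a dated
birth-death tree with extant and fossil tips, a few hundred unordered
multistate characters evolved under the ER Mk process, random missingness on
extant tips, block-by-category ("fossil-like") missingness on extinct tips,
and Poisson-placed genome-duplication events on branches.

The block fossil masking reproduces the failure mode real fossil data show —
fossils clustering together on shared missing data — so the imputation stage
can be tested for removing it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .matrix_io import MISSING, CharacterMatrix, PresenceMatrix
from .complexity import PloidyAnnotation
from .trees import Phylogeny, TreeSample

logger = logging.getLogger("phytodisparity")

CATEGORY_NAMES = (
    "sporophytic",
    "gametophytic",
    "branching_appendages",
    "reproductive",
    "vegetative",
    "cellular",
    "developmental",
    "life_cycle",
)


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    Defaults give ~80 tips x 200 characters: a dated birth-death tree with
    64 extant and 16 fossil tips, mostly binary characters at morphological
    (slow) rates, 20% i.i.d. missingness on extant tips and whole-category
    missing blocks on fossils.
    """

    n_extant: int = 64
    n_fossil: int = 16
    birth_rate: float = 0.025  # per Myr
    death_rate: float = 0.01
    n_characters: int = 200
    state_counts: tuple[int, ...] = (2, 3, 4)
    state_count_probs: tuple[float, ...] = (0.7, 0.2, 0.1)
    rate_median: float = 0.004  # ER Mk q, changes per Myr per state pair
    rate_sigma: float = 0.5  # lognormal spread of per-character rates
    regime_multiplier: float = 1.0  # Mk rate multiplier inside one root clade
    extant_missing_fraction: float = 0.2
    fossil_missing_categories: tuple[str, ...] = ("gametophytic", "cellular")
    second_category_prob: float = 0.15  # categories overlap, as real trait sets do
    ploidy_rate: float = 0.004  # WGD events per Myr per branch
    ploidy_effect: float = 0.0  # absent->present flips per inherited event
    n_trees: int = 1  # tree-sample size (branch-length jittered copies)
    tree_jitter_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.extant_missing_fraction <= 1:
            raise ValueError("missing fraction must be in [0, 1]")
        for r in (self.birth_rate, self.death_rate, self.ploidy_rate):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        unknown = set(self.fossil_missing_categories) - set(CATEGORY_NAMES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticScenario":
        data = json.loads(Path(path).read_text())
        for key in ("state_counts", "state_count_probs", "fossil_missing_categories"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    scenario: SyntheticScenario, seed: int | None = None, max_retries: int = 200
) -> Phylogeny:
    """Forward birth-death tree conditioned on the extant tip count.

    Simulation starts from two lineages at the root and stops the moment the
    extant count first reaches ``n_extant``; extinct lineages become fossil
    tips, randomly thinned to ``n_fossil`` (retrying the whole simulation if
    too few went extinct).
    """
    rng = np.random.default_rng(seed)
    lam, mu = scenario.birth_rate, scenario.death_rate
    if scenario.n_fossil > 0 and mu == 0:
        raise ValueError("fossil tips require a positive death rate")
    if scenario.n_extant < 2:
        raise ValueError("need at least 2 extant tips")
    for _ in range(max_retries):
        # node records: (parent, birth_time); times grow from the root at 0
        parent = [-1, 0, 0]
        btime = [0.0, 0.0, 0.0]
        active = [1, 2]
        extinct: list[int] = []
        end_time: dict[int, float] = {}
        t = 0.0
        failed = False
        while len(active) < scenario.n_extant:
            n = len(active)
            total = n * (lam + mu)
            t += rng.exponential(1.0 / total)
            node = active[rng.integers(n)]
            if rng.random() < lam / (lam + mu):
                c1, c2 = len(parent), len(parent) + 1
                parent.extend([node, node])
                btime.extend([t, t])
                end_time[node] = t
                active.remove(node)
                active.extend([c1, c2])
            else:
                end_time[node] = t
                active.remove(node)
                extinct.append(node)
                if len(active) < 2:
                    failed = True
                    break
        if failed or len(extinct) < scenario.n_fossil:
            continue
        # run on to (just before) the next event so the last-born tips have
        # positive length; Yule mean root age becomes sum_{k=2..n} 1/(k*lam)
        t += rng.exponential(1.0 / (len(active) * (lam + mu)))
        for node in active:
            end_time[node] = t
        keep_fossils = set(
            rng.choice(extinct, size=scenario.n_fossil, replace=False).tolist()
        )
        drop = set(extinct) - keep_fossils
        return _build_phylogeny(parent, btime, end_time, set(active), keep_fossils, drop)
    raise RuntimeError(
        f"could not condition tree on {scenario.n_extant} extant / "
        f"{scenario.n_fossil} fossil tips in {max_retries} attempts"
    )


def _build_phylogeny(parent, btime, end_time, extant, fossils, drop) -> Phylogeny:
    """Assemble a Phylogeny from simulation records, pruning dropped tips and
    suppressing the resulting degree-2 nodes."""
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    # keep set: union of ancestors of retained tips
    keep = set()
    for tip in list(extant) + list(fossils):
        j = tip
        while j != -1 and j not in keep:
            keep.add(j)
            j = parent[j]

    def emit(old: int, plen: float, rows: list, par_new: int) -> None:
        kept_kids = [c for c in children[old] if c in keep]
        length = end_time[old] - btime[old] if old in end_time else 0.0
        while len(kept_kids) == 1:  # suppress degree-2 pass-throughs
            nxt = kept_kids[0]
            length += end_time[nxt] - btime[nxt] if nxt in end_time else 0.0
            old = nxt
            kept_kids = [c for c in children[old] if c in keep]
        idx = len(rows)
        is_tip = not kept_kids
        rows.append([par_new, plen + length, old, is_tip])
        for c in kept_kids:
            emit(c, 0.0, rows, idx)

    rows: list = []
    root_kids = [c for c in children[0] if c in keep]
    rows.append([-1, 0.0, 0, False])
    for c in root_kids:
        emit(c, 0.0, rows, 0)
    par = np.array([r[0] for r in rows])
    blen = np.array([r[1] for r in rows])
    is_tip = np.array([r[3] for r in rows])
    labels = []
    n_t = n_f = n_i = 0
    for r, (p_, l_, old, tip) in enumerate(rows):
        if tip and old in fossils:
            n_f += 1
            labels.append(f"f{n_f}")
        elif tip:
            n_t += 1
            labels.append(f"t{n_t}")
        else:
            n_i += 1
            labels.append(f"N{n_i}")
    return Phylogeny(par, blen, labels, is_tip)


def jittered_tree_sample(
    tree: Phylogeny, scenario: SyntheticScenario, seed: int | None = None
) -> TreeSample:
    """Tree sample emulating posterior branch-length spread: the base tree
    plus copies with lognormal multiplicative branch-length noise.

    This is a synthetic stand-in for a Bayesian posterior sample; topology
    is shared, so every tree contributes to every node's consensus.
    """
    rng = np.random.default_rng(seed)
    trees = [tree]
    for _ in range(max(0, scenario.n_trees - 1)):
        blen = tree.blen * np.exp(
            rng.normal(0.0, scenario.tree_jitter_sigma, size=tree.n_nodes)
        )
        blen[0] = 0.0
        trees.append(Phylogeny(tree.parent.copy(), blen, list(tree.labels), tree.is_tip.copy()))
    return TreeSample(trees)


# ---------------------------------------------------------------------------
# Character simulation
# ---------------------------------------------------------------------------

def simulate_characters(
    tree: Phylogeny, scenario: SyntheticScenario, seed: int | None = None
) -> tuple[CharacterMatrix, np.ndarray, np.ndarray]:
    """Evolve characters under ER Mk along the dated tree.

    Returns (complete matrix over tips, true states for every node as an
    (n_characters, n_nodes) array, per-character rates).  With
    ``regime_multiplier != 1`` every branch inside the larger root clade
    uses q * multiplier, creating a two-regime structure.
    """
    rng = np.random.default_rng(seed)
    p = scenario.n_characters
    ks = rng.choice(scenario.state_counts, size=p, p=scenario.state_count_probs)
    q = scenario.rate_median * np.exp(rng.normal(0.0, scenario.rate_sigma, size=p))
    mult = np.ones(tree.n_nodes)
    if scenario.regime_multiplier != 1.0:
        kids = tree.children[0]
        clades = tree.clade_tipsets()
        target = max(kids, key=lambda c: len(clades[c]))
        inside = np.zeros(tree.n_nodes, dtype=bool)
        inside[target] = True
        for i in range(1, tree.n_nodes):
            if inside[tree.parent[i]]:
                inside[i] = True
        mult[inside] = scenario.regime_multiplier

    states = np.empty((p, tree.n_nodes), dtype=np.int16)
    for r in range(p):
        states[r, 0] = rng.integers(ks[r])
    for i in range(1, tree.n_nodes):
        t = float(tree.blen[i]) * mult[i]
        e = np.exp(-ks * q * t)
        p_same = 1.0 / ks + (1.0 - 1.0 / ks) * e
        stay = rng.random(p) < p_same
        shift = rng.integers(1, np.maximum(ks - 1, 1) + 1)
        parent_states = states[:, tree.parent[i]]
        states[:, i] = np.where(
            stay, parent_states, (parent_states + shift) % ks
        )

    tips = tree.tip_indices
    cells = states[:, tips].T.copy()  # taxa x characters
    characters = [f"c{j + 1}" for j in range(p)]
    primary = rng.integers(0, len(CATEGORY_NAMES), size=p)
    partitions: dict[str, list[str]] = {name: [] for name in CATEGORY_NAMES}
    for j in range(p):
        partitions[CATEGORY_NAMES[primary[j]]].append(characters[j])
        if rng.random() < scenario.second_category_prob:
            other = (primary[j] + 1 + rng.integers(len(CATEGORY_NAMES) - 1)) % len(
                CATEGORY_NAMES
            )
            partitions[CATEGORY_NAMES[other]].append(characters[j])
    partitions = {k: v for k, v in partitions.items() if v}
    m = CharacterMatrix(tree.tip_labels, characters, cells, partitions)
    return m, states, q


def apply_missingness(
    m: CharacterMatrix,
    scenario: SyntheticScenario,
    seed: int | None = None,
    fossil_taxa: list[str] | None = None,
) -> tuple[CharacterMatrix, np.ndarray]:
    """Mask a complete matrix: i.i.d. on extant tips, block-by-category on
    fossils.  Returns (masked matrix, boolean mask of removed cells)."""
    if (m.cells < 0).any():
        raise ValueError("input matrix must be complete")
    rng = np.random.default_rng(seed)
    if fossil_taxa is None:
        fossil_taxa = [t for t in m.taxa if t.startswith("f")]
    fossil_set = set(fossil_taxa)
    mask = np.zeros(m.cells.shape, dtype=bool)
    extant_rows = [i for i, t in enumerate(m.taxa) if t not in fossil_set]
    if scenario.extant_missing_fraction > 0:
        sub = rng.random((len(extant_rows), m.n_characters)) < scenario.extant_missing_fraction
        mask[extant_rows] = sub
    block_chars = set()
    for cat in scenario.fossil_missing_categories:
        block_chars |= set(m.partitions.get(cat, []))
    block_idx = [j for j, c in enumerate(m.characters) if c in block_chars]
    for i, t in enumerate(m.taxa):
        if t in fossil_set:
            mask[i, block_idx] = True
    masked = m.copy()
    masked.cells[mask] = MISSING
    return masked, mask


def assign_ploidy(
    tree: Phylogeny,
    scenario: SyntheticScenario,
    seed: int | None = None,
    presence: PresenceMatrix | None = None,
) -> tuple[PloidyAnnotation, PresenceMatrix | None]:
    """Poisson WGD events per branch, cumulative per tip; optionally couple
    complexity to ploidy by flipping ``ploidy_effect`` absent characters to
    present per inherited event (creating a known true association)."""
    rng = np.random.default_rng(seed)
    counts = {
        tree.labels[i]: int(rng.poisson(scenario.ploidy_rate * tree.blen[i]))
        for i in range(1, tree.n_nodes)
    }
    ann = PloidyAnnotation.from_branch_counts(tree, counts)
    shifted = None
    if presence is not None and scenario.ploidy_effect > 0:
        cells = presence.cells.copy()
        for r, taxon in enumerate(presence.taxa):
            events = ann.tip_cumulative.get(taxon, 0)
            n_flip = int(round(scenario.ploidy_effect * events))
            absent = np.flatnonzero(cells[r] == 0)
            if n_flip and absent.size:
                flip = rng.choice(absent, size=min(n_flip, absent.size), replace=False)
                cells[r, flip] = 1
        shifted = PresenceMatrix(list(presence.taxa), list(presence.characters), cells)
    return ann, shifted


def missingness_silhouette(m: CharacterMatrix, fossil_taxa: list[str]) -> float:
    """Mean silhouette of fossil tips on a missingness-pattern clustering.

    Units are described by their binary is-missing indicator vectors
    (Hamming distances); labels are fossil vs extant.  A high value means
    fossils cluster together purely by shared missing data — the artefact
    imputation should remove.  Degenerate units (zero distance everywhere)
    score 0.
    """
    indicator = (m.cells == MISSING).astype(float)
    d = np.abs(indicator[:, None, :] - indicator[None, :, :]).mean(axis=2)
    fossil = np.array([t in set(fossil_taxa) for t in m.taxa])
    if fossil.sum() == 0 or (~fossil).sum() == 0:
        raise ValueError("need both fossil and extant taxa")
    scores = []
    for i in np.flatnonzero(fossil):
        same = fossil.copy()
        same[i] = False
        a = d[i, same].mean() if same.any() else 0.0
        b = d[i, ~fossil].mean()
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


@dataclass
class SyntheticDataset:
    """One generated study: tree sample, masked matrix, and full truth."""

    scenario: SyntheticScenario
    tree: Phylogeny
    trees: TreeSample
    matrix: CharacterMatrix  # masked
    truth_matrix: CharacterMatrix  # complete
    truth_node_states: np.ndarray  # (n_characters, n_nodes) on `tree`
    mask: np.ndarray
    rates: np.ndarray
    ploidy: PloidyAnnotation
    presence: PresenceMatrix = None  # type: ignore[assignment]


def generate(scenario: SyntheticScenario, seed: int | None = None) -> SyntheticDataset:
    """Run the whole generator with named sub-streams of one master seed."""
    ss = np.random.SeedSequence(seed)
    s_tree, s_chars, s_mask, s_ploidy, s_sample = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    )
    tree = simulate_tree(scenario, seed=s_tree)
    complete, node_states, rates = simulate_characters(tree, scenario, seed=s_chars)
    masked, mask = apply_missingness(complete, scenario, seed=s_mask)
    trees = jittered_tree_sample(tree, scenario, seed=s_sample)
    # presence view of the truth: state 0 = absent, any positive state = present
    pres_cells = (complete.cells > 0).astype(np.int16)
    presence = PresenceMatrix(list(complete.taxa), list(complete.characters), pres_cells)
    ploidy, shifted = assign_ploidy(tree, scenario, seed=s_ploidy, presence=presence)
    if shifted is not None:
        presence = shifted
    return SyntheticDataset(
        scenario, tree, trees, masked, complete, node_states, mask, rates, ploidy, presence
    )
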