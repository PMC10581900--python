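"""Mk-model machinery: pruning likelihoods, stochastic character mapping
and imputation of missing tip states.

The model is the equal-rates (ER) Mk process: a continuous-time Markov chain
on ``k`` unordered states with every off-diagonal rate equal to ``q`` (per
Myr).  Its transition probabilities have the closed form

    P(same state after t) = 1/k + (1 - 1/k) * exp(-k q t)
    P(any given other)    = 1/k - (1/k)     * exp(-k q t)

Likelihoods use Felsenstein pruning with per-node rescaling.  Stochastic
mapping samples joint node states root-down from the pruning conditionals
and then draws the within-branch substitution history by uniformization
(with total rate k*q the uniformized jump chain is the uniform matrix, so
intermediate states of a conditioned bridge are i.i.d. uniform — exact and
cheap).

Imputation follows the consensus protocol: per character and per tree the
mapper is run with missing tips free over that character's *observed*
states, the per-tree modal sampled state is taken, and the cross-tree
consensus is the modal state of the per-tree modes (ties broken to the
lowest state code, flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .matrix_io import INAPPLICABLE, MISSING, CharacterMatrix
from .trees import Phylogeny, TreeSample, link_tree_matrix

logger = logging.getLogger("phytodisparity")

#: Rate floor returned for characters with no signal (invariant / one tip).
RATE_FLOOR = 1e-8
_RATE_CEIL = 1e3


@dataclass
class MkCharacterModel:
    """Equal-rates Mk model for one character.

    ``q`` is the per-Myr rate of each specific state-to-state change; the
    total leaving rate from any state is ``(k-1) q``.
    """

    k: int
    q: float
    root_prior: np.ndarray | None = None
    at_floor: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.q < 0:
            raise ValueError("q must be nonnegative")
        if self.root_prior is None:
            self.root_prior = np.full(self.k, 1.0 / self.k)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        if abs(self.root_prior.sum() - 1.0) > 1e-9 or len(self.root_prior) != self.k:
            raise ValueError("root prior must be a length-k probability vector")

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form ER transition probabilities; rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        k, q = self.k, self.q
        e = np.exp(-k * q * t)
        same = 1.0 / k + (1.0 - 1.0 / k) * e
        diff = 1.0 / k - (1.0 / k) * e
        P = np.full((k, k), diff)
        np.fill_diagonal(P, same)
        return P


@dataclass
class MappedHistory:
    """One sampled character history on one tree.

    ``node_states[i]`` is the sampled state at node ``i``;
    ``branch_segments[i]`` lists (state, dwell-time) segments along the
    branch above node ``i``, parent-to-child order, dwell times summing to
    the branch length and ending in the child's state.
    """

    node_states: np.ndarray
    branch_segments: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    @property
    def n_changes(self) -> int:
        return sum(len(seg) - 1 for seg in self.branch_segments.values())


# ---------------------------------------------------------------------------
# Tip-state encoding and pruning
# ---------------------------------------------------------------------------

def _tip_likelihoods(tree: Phylogeny, tip_states, k: int) -> np.ndarray:
    """(n_nodes, k) partial-likelihood seed: one-hot for observed tips,
    indicator for ambiguity sets, all-ones for missing tips and internals."""
    L = np.ones((tree.n_nodes, k))
    for i in tree.tip_indices:
        s = tip_states.get(tree.labels[i]) if hasattr(tip_states, "get") else tip_states[i]
        if s is None:
            continue
        if isinstance(s, (set, frozenset, list, tuple, np.ndarray)):
            vec = np.zeros(k)
            for x in s:
                if not 0 <= int(x) < k:
                    raise ValueError(f"tip state {x} outside 0..{k - 1}")
                vec[int(x)] = 1.0
            if vec.sum() == 0:
                raise ValueError(f"empty state set for tip {tree.labels[i]!r}")
            L[i] = vec
        else:
            if not 0 <= int(s) < k:
                raise ValueError(f"tip state {s} outside 0..{k - 1}")
            L[i] = 0.0
            L[i, int(s)] = 1.0
    return L


def _prune(tree: Phylogeny, L: np.ndarray, model: MkCharacterModel):
    """Upward pass.  Returns (partials, log scale, transition matrices)."""
    n = tree.n_nodes
    partial = L.copy()
    Pmats = [None] * n
    for i in range(1, n):
        Pmats[i] = model.transition_matrix(float(tree.blen[i]))
    log_scale = 0.0
    for i in range(n - 1, -1, -1):
        if tree.is_tip[i]:
            continue
        acc = partial[i].copy()  # ones unless constrained
        for c in tree.children[i]:
            acc = acc * (Pmats[c] @ partial[c])
        mx = acc.max()
        if mx <= 0:
            return None, -np.inf, Pmats
        acc /= mx
        log_scale += np.log(mx)
        partial[i] = acc
    return partial, log_scale, Pmats


def mk_likelihood(tree: Phylogeny, tip_states, model: MkCharacterModel) -> float:
    """Felsenstein-pruning log-likelihood of one character.

    ``tip_states`` maps tip label to an integer state, a set of states
    (ambiguity) or None (missing, all states allowed).
    """
    L = _tip_likelihoods(tree, tip_states, model.k)
    partial, log_scale, _ = _prune(tree, L, model)
    if partial is None:
        return -np.inf
    lik = float(model.root_prior @ partial[0])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def marginal_node_states(tree: Phylogeny, tip_states, model: MkCharacterModel) -> np.ndarray:
    """(n_nodes, k) marginal posterior state probabilities at every node."""
    L = _tip_likelihoods(tree, tip_states, model.k)
    partial, _, Pmats = _prune(tree, L, model)
    if partial is None:
        raise ValueError("zero likelihood: tip data inconsistent with model")
    n, k = tree.n_nodes, model.k
    outside = np.zeros((n, k))
    outside[0] = model.root_prior
    for i in range(n):
        if tree.is_tip[i]:
            continue
        msgs = {c: Pmats[c] @ partial[c] for c in tree.children[i]}
        for c in tree.children[i]:
            sib = outside[i].copy()
            for s in tree.children[i]:
                if s != c:
                    sib = sib * msgs[s]
            out = Pmats[c].T @ sib
            mx = out.max()
            outside[c] = out / mx if mx > 0 else out
    marg = outside * partial
    return marg / marg.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Rate fitting
# ---------------------------------------------------------------------------

def fit_rate(
    tree: Phylogeny,
    tip_states,
    k: int,
    root_prior: np.ndarray | None = None,
) -> MkCharacterModel:
    """Maximum-likelihood ER rate by bounded 1-D optimization over log10 q.

    Characters with no signal (fewer than two distinct observed states)
    take the floor rate and are flagged via ``at_floor``.
    """
    observed = set()
    for v in (tip_states.values() if hasattr(tip_states, "values") else tip_states):
        if v is None:
            continue
        if isinstance(v, (set, frozenset, list, tuple)):
            continue  # ambiguity carries no point signal for the rate
        observed.add(int(v))
    if len(observed) < 2:
        return MkCharacterModel(k, RATE_FLOOR, root_prior, at_floor=True)

    L = _tip_likelihoods(tree, tip_states, k)

    def nll(log10_q: float) -> float:
        model = MkCharacterModel(k, 10.0**log10_q, root_prior)
        partial, log_scale, _ = _prune(tree, L, model)
        if partial is None:
            return np.inf
        lik = float(model.root_prior @ partial[0])
        if lik <= 0:
            return np.inf
        return -(np.log(lik) + log_scale)

    res = minimize_scalar(
        nll,
        bounds=(np.log10(RATE_FLOOR), np.log10(_RATE_CEIL)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    if not res.success:
        raise RuntimeError(f"rate optimization failed to converge: {res.message}")
    q = float(10.0**res.x)
    at_floor = res.x <= np.log10(RATE_FLOOR) + 1e-3
    return MkCharacterModel(k, RATE_FLOOR if at_floor else q, root_prior, at_floor=at_floor)


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------

def _sample_node_states(
    tree: Phylogeny, L: np.ndarray, model: MkCharacterModel, n_sims: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_sims, n_nodes) joint node-state samples, root-down."""
    partial, _, Pmats = _prune(tree, L, model)
    if partial is None:
        raise ValueError("zero likelihood: tip data inconsistent with model")
    n, k = tree.n_nodes, model.k
    states = np.empty((n_sims, n), dtype=np.int16)

    def categorical(probs: np.ndarray) -> np.ndarray:
        totals = probs.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("degenerate sampling distribution at a node")
        cum = np.cumsum(probs / totals, axis=1)
        u = rng.random((probs.shape[0], 1))
        return (u > cum[:, :-1]).sum(axis=1).astype(np.int16)

    root_p = np.broadcast_to(model.root_prior * partial[0], (n_sims, k))
    states[:, 0] = categorical(np.ascontiguousarray(root_p))
    for i in range(1, n):
        # partial == seed L at tips, so one expression covers both cases
        probs = Pmats[i][states[:, tree.parent[i]]] * partial[i]
        states[:, i] = categorical(probs)
    return states


def _bridge_segments(
    i_state: int, j_state: int, t: float, model: MkCharacterModel,
    rng: np.random.Generator, max_retry: int = 1000,
) -> list[tuple[int, float]]:
    """Substitution path on one branch conditioned on its endpoint states.

    Uniformization with total rate mu = k*q, whose jump chain is the uniform
    k x k matrix: the number of virtual jumps is Poisson(mu*t) conditioned on
    the endpoints and intermediate states are i.i.d. uniform.
    """
    k, q = model.k, model.q
    if q == 0 or t == 0:
        if i_state != j_state:
            raise ValueError("state change on a zero-opportunity branch")
        return [(i_state, t)]
    mu = k * q
    lam = mu * t
    # Virtual jump count N | endpoints by inverse cdf:
    # weight(0) = e^-lam (only when endpoints match); weight(n>=1) = pois(n)/k.
    same = i_state == j_state
    u = rng.random()
    e = np.exp(-lam)
    norm = (1.0 / k + (1 - 1.0 / k) * e) if same else (1.0 / k - e / k)  # P_ij(t)
    acc = e / norm if same else 0.0
    n_jumps = 0
    pois_n = e  # Poisson pmf at current n
    while u > acc:
        n_jumps += 1
        pois_n = pois_n * lam / n_jumps
        acc += pois_n / k / norm
        if n_jumps > 1000 + int(100 * lam):  # cdf rounding guard
            break
    # States at virtual jumps: i.i.d. uniform, last fixed to j_state.
    seq = [i_state]
    if n_jumps > 0:
        seq.extend(int(x) for x in rng.integers(0, k, size=n_jumps - 1))
        seq.append(j_state)
    times = np.sort(rng.random(n_jumps)) * t if n_jumps else np.empty(0)
    # Collapse virtual (self) jumps into dwell segments.
    segments: list[tuple[int, float]] = []
    bounds = np.concatenate([[0.0], times, [t]])
    cur_state = seq[0]
    cur_start = 0.0
    for idx in range(1, len(seq)):
        if seq[idx] != cur_state:
            segments.append((cur_state, float(bounds[idx] - cur_start)))
            cur_state = seq[idx]
            cur_start = float(bounds[idx])
    segments.append((cur_state, float(t - cur_start)))
    return segments


def stochastic_map(
    tree: Phylogeny,
    tip_states,
    model: MkCharacterModel,
    n_sims: int,
    seed: int | None = None,
    simulate_paths: bool = True,
) -> list[MappedHistory]:
    """Sample full character histories consistent with the tip data.

    Node states are drawn jointly from the pruning conditionals (observed
    tips are fixed with probability 1); branch histories are then simulated
    conditional on their endpoint states.  Fixed seed gives identical output.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    L = _tip_likelihoods(tree, tip_states, model.k)
    states = _sample_node_states(tree, L, model, n_sims, rng)
    out = []
    for s in range(n_sims):
        hist = MappedHistory(states[s].copy())
        if simulate_paths:
            for i in range(1, tree.n_nodes):
                hist.branch_segments[i] = _bridge_segments(
                    int(states[s, tree.parent[i]]),
                    int(states[s, i]),
                    float(tree.blen[i]),
                    model,
                    rng,
                )
        out.append(hist)
    return out


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Consensus states and sampling frequencies for imputed units.

    ``frequencies[(unit, character)]`` maps original state codes to the
    fraction of trees whose per-tree modal sample was that state.  ``units``
    covers imputed tips (originally missing cells only) and all reference
    internal nodes (every character).
    """

    consensus: dict[tuple[str, str], int]
    frequencies: dict[tuple[str, str], dict[int, float]]
    ties: set[tuple[str, str]]
    node_labels: list[str]
    characters: list[str]

    def to_frame(self):
        import pandas as pd

        rows = []
        for (unit, char), freqs in sorted(self.frequencies.items()):
            for state, f in sorted(freqs.items()):
                rows.append(
                    {
                        "unit": unit,
                        "character": char,
                        "state": state,
                        "frequency": f,
                        "consensus": self.consensus[(unit, char)],
                        "tie_flag": (unit, char) in self.ties,
                    }
                )
        return pd.DataFrame(rows)


def _modal(counts: dict[int, int]) -> tuple[int, bool]:
    best = max(counts.values())
    winners = sorted(s for s, c in counts.items() if c == best)
    return winners[0], len(winners) > 1


def impute_matrix(
    m: CharacterMatrix,
    trees: TreeSample | Phylogeny,
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[CharacterMatrix, ImputationResult]:
    """Impute missing tip states and reconstruct node states by consensus
    stochastic mapping across a tree sample.

    Per character and per tree: the ER rate is fitted by ML, ``n_sims``
    stochastic maps are drawn with missing tips free over the character's
    observed states (uniform prior), and the modal sampled state is kept.
    The cross-tree consensus is the modal state of those per-tree modes;
    ties break to the lowest original state code and are flagged.
    Inapplicable cells pass through unchanged; characters with no scored
    tip are left missing with a warning.  Node consensus is keyed to the
    first (reference) tree's clades; nodes of other trees contribute only
    where their tip set matches a reference clade exactly.
    """
    sample = trees if isinstance(trees, TreeSample) else TreeSample([trees])
    ref = sample[0]
    link_tree_matrix(ref, m.taxa)
    ref_clades = ref.clade_tipsets()
    ref_internal = [i for i in range(ref.n_nodes) if not ref.is_tip[i]]
    node_labels = [ref.labels[i] for i in ref_internal]
    clade_to_label = {ref_clades[i]: ref.labels[i] for i in ref_internal}

    master = np.random.SeedSequence(seed)
    focal = m.copy()
    consensus: dict[tuple[str, str], int] = {}
    frequencies: dict[tuple[str, str], dict[int, float]] = {}
    ties: set[tuple[str, str]] = set()

    tree_internal = []
    for t in sample:
        clades = t.clade_tipsets()
        tree_internal.append(
            [
                (i, clade_to_label[clades[i]])
                for i in range(t.n_nodes)
                if not t.is_tip[i] and clades[i] in clade_to_label
            ]
        )

    for j, char in enumerate(m.characters):
        col = m.cells[:, j]
        obs_states = m.observed_states(j)
        missing_tips = [
            lbl
            for lbl in sample.tip_labels
            if col[m.taxon_index(lbl)] == MISSING
        ]
        if len(obs_states) == 0:
            logger.warning("character %r has no scored tips; left missing", char)
            continue
        # per-unit accumulated per-tree modal states
        unit_counts: dict[str, dict[int, int]] = {u: {} for u in missing_tips}
        for lbl in node_labels:
            unit_counts[lbl] = {}
        if len(obs_states) == 1:
            only = int(obs_states[0])
            for u in unit_counts:
                unit_counts[u][only] = len(sample)
        else:
            code_of = {int(s): r for r, s in enumerate(obs_states)}
            state_of = {r: int(s) for r, s in enumerate(obs_states)}
            k = len(obs_states)
            for t_idx, t in enumerate(sample):
                tip_states = {}
                for lbl in t.tip_labels:
                    cell = int(col[m.taxon_index(lbl)])
                    tip_states[lbl] = code_of[cell] if cell >= 0 else None
                model = fit_rate(t, tip_states, k)
                child_seed = np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(t_idx, j)
                )
                rng = np.random.default_rng(child_seed)
                L = _tip_likelihoods(t, tip_states, k)
                states = _sample_node_states(t, L, model, n_sims, rng)
                # modal per unit for this tree
                for lbl in missing_tips:
                    i = t.labels.index(lbl)
                    vals, counts = np.unique(states[:, i], return_counts=True)
                    mode = state_of[int(vals[np.argmax(counts)])]
                    unit_counts[lbl][mode] = unit_counts[lbl].get(mode, 0) + 1
                for i, lbl in tree_internal[t_idx]:
                    vals, counts = np.unique(states[:, i], return_counts=True)
                    mode = state_of[int(vals[np.argmax(counts)])]
                    unit_counts[lbl][mode] = unit_counts[lbl].get(mode, 0) + 1
        for unit, counts in unit_counts.items():
            if not counts:
                continue
            total = sum(counts.values())
            state, tie = _modal(counts)
            key = (unit, char)
            consensus[key] = state
            frequencies[key] = {s: c / total for s, c in sorted(counts.items())}
            if tie:
                ties.add(key)
            if unit in missing_tips:
                focal.cells[m.taxon_index(unit), j] = state

    return focal, ImputationResult(consensus, frequencies, ties, node_labels, list(m.characters))


def focal_with_nodes(
    focal: CharacterMatrix, result: ImputationResult, reference: Phylogeny
) -> CharacterMatrix:
    """Append reconstructed internal-node rows to a focal matrix.

    Node rows carry the cross-tree consensus state for every character;
    characters without a node consensus (e.g. zero scored tips) stay
    missing.
    """
    rows = []
    for lbl in result.node_labels:
        row = np.full(focal.n_characters, MISSING, dtype=np.int16)
        for j, char in enumerate(focal.characters):
            key = (lbl, char)
            if key in result.consensus:
                row[j] = result.consensus[key]
        rows.append(row)
    cells = np.vstack([focal.cells, np.array(rows, dtype=np.int16)])
    return CharacterMatrix(
        list(focal.taxa) + list(result.node_labels),
        list(focal.characters),
        cells,
        {k: list(v) for k, v in focal.partitions.items()},
    )
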