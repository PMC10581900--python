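"""Mk likelihoods, stochastic mapping and imputation against independent
oracles: exhaustive enumeration over internal-node states, closed-form
transition probabilities, and simulation with known truth."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytodisparity import (
    MkCharacterModel,
    Phylogeny,
    SyntheticScenario,
    TreeSample,
    apply_missingness,
    fit_rate,
    focal_with_nodes,
    impute_matrix,
    marginal_node_states,
    mk_likelihood,
    simulate_characters,
    simulate_tree,
    stochastic_map,
)
from phytodisparity.matrix_io import INAPPLICABLE, MISSING, CharacterMatrix

from conftest import random_tree


def enumeration_loglik(tree: Phylogeny, tips: dict, model: MkCharacterModel) -> float:
    """Brute-force sum over every internal-node state assignment."""
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    P = {i: model.transition_matrix(float(tree.blen[i])) for i in range(1, tree.n_nodes)}
    total = 0.0
    for assign in itertools.product(range(model.k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for i in tree.tip_indices:
            st[i] = tips[tree.labels[i]]
        pr = model.root_prior[st[0]]
        for i in range(1, tree.n_nodes):
            pr *= P[i][st[int(tree.parent[i])], st[i]]
        total += pr
    return float(np.log(total))


def test_zero_branch_lengths_root_prior_only():
    t = Phylogeny.from_newick("((A:0,B:0):0,C:0);")
    model = MkCharacterModel(2, 0.7)
    ll = mk_likelihood(t, {"A": 0, "B": 0, "C": 0}, model)
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


def test_two_tip_closed_form():
    t1, t2, q = 0.8, 1.3, 0.25
    t = Phylogeny.from_newick(f"(A:{t1},B:{t2});")
    model = MkCharacterModel(2, q)

    def p_same(tt):
        return 0.5 + 0.5 * np.exp(-2 * q * tt)

    expected = 0.5 * p_same(t1) * p_same(t2) + 0.5 * (1 - p_same(t1)) * (1 - p_same(t2))
    ll = mk_likelihood(t, {"A": 0, "B": 0}, model)
    assert ll == pytest.approx(np.log(expected), abs=1e-12)


@pytest.mark.parametrize("k", [2, 3, 4])
def test_likelihood_matches_enumeration(k):
    rng = np.random.default_rng(k)
    for _ in range(8):
        t = random_tree(rng, int(rng.integers(3, 7)))
        model = MkCharacterModel(k, float(rng.uniform(0.05, 1.0)))
        tips = {lbl: int(rng.integers(k)) for lbl in t.tip_labels}
        assert mk_likelihood(t, tips, model) == pytest.approx(
            enumeration_loglik(t, tips, model), abs=1e-10
        )


def test_ambiguous_and_missing_tips():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    model = MkCharacterModel(3, 0.2)
    ll_missing = mk_likelihood(t, {"A": 0, "B": 1, "C": None}, model)
    total = np.logaddexp.reduce(
        [mk_likelihood(t, {"A": 0, "B": 1, "C": s}, model) for s in range(3)]
    )
    assert ll_missing == pytest.approx(total, abs=1e-10)
    ll_set = mk_likelihood(t, {"A": 0, "B": 1, "C": {0, 2}}, model)
    partial = np.logaddexp(
        mk_likelihood(t, {"A": 0, "B": 1, "C": 0}, model),
        mk_likelihood(t, {"A": 0, "B": 1, "C": 2}, model),
    )
    assert ll_set == pytest.approx(partial, abs=1e-10)


@pytest.mark.parametrize("k,q,t", [(2, 0.1, 3.0), (3, 0.5, 0.2), (5, 2.0, 10.0), (4, 0.0, 1.0)])
def test_transition_rows_sum_to_one(k, q, t):
    P = MkCharacterModel(k, q).transition_matrix(t)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    assert (P >= 0).all()


@settings(derandomize=True, max_examples=100)
@given(
    k=st.integers(2, 10),
    q=st.floats(0.0, 50.0, allow_nan=False),
    t=st.floats(0.0, 500.0, allow_nan=False),
)
def test_transition_matrix_is_stochastic_everywhere(k, q, t):
    """Rows sum to 1 and entries stay in [0, 1] across the parameter space,
    approaching the uniform stationary distribution for large q*t."""
    P = MkCharacterModel(k, q).transition_matrix(t)
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
    assert (P >= -1e-15).all() and (P <= 1 + 1e-15).all()
    if q * t > 20:
        assert np.allclose(P, 1.0 / k, atol=1e-6)


def test_fit_rate_invariant_character_floors():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    model = fit_rate(t, {"A": 0, "B": 0, "C": 0}, 2)
    assert model.at_floor
    single = fit_rate(t, {"A": 1, "B": None, "C": None}, 2)
    assert single.at_floor


def test_fit_rate_recovery():
    """Pooled per-character ML rates centre on the simulation rate."""
    sc = SyntheticScenario(
        n_extant=64, n_fossil=0, death_rate=0.0, birth_rate=0.35,
        n_characters=200, rate_median=0.05, rate_sigma=0.0,
    )
    tree = simulate_tree(sc, seed=5)
    m, _, _ = simulate_characters(tree, sc, seed=6)
    qs = []
    for j in range(m.n_characters):
        obs = m.observed_states(j)
        if len(obs) < 2:
            continue
        code = {int(s): r for r, s in enumerate(obs)}
        tips = {lbl: code[int(m.cells[m.taxon_index(lbl), j])] for lbl in tree.tip_labels}
        qs.append(fit_rate(tree, tips, len(obs)).q)
    assert 0.03 <= np.median(qs) <= 0.08


def test_stochastic_map_zero_rate_no_changes():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    model = MkCharacterModel(2, 0.0)
    hists = stochastic_map(t, {"A": 1, "B": 1, "C": 1}, model, 20, seed=0)
    for h in hists:
        assert h.n_changes == 0
        assert (h.node_states == 1).all()


def test_observed_tips_fixed_in_every_simulation():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    model = MkCharacterModel(2, 0.5)
    tips = {"A": 0, "B": 1, "C": None}
    hists = stochastic_map(t, tips, model, 200, seed=1)
    ia, ib = t.labels.index("A"), t.labels.index("B")
    for h in hists:
        assert h.node_states[ia] == 0
        assert h.node_states[ib] == 1


def test_history_segments_consistent():
    rng = np.random.default_rng(9)
    t = random_tree(rng, 6)
    model = MkCharacterModel(3, 0.6)
    tips = {lbl: int(rng.integers(3)) for lbl in t.tip_labels}
    for h in stochastic_map(t, tips, model, 30, seed=2):
        for i in range(1, t.n_nodes):
            segs = h.branch_segments[i]
            assert sum(d for _, d in segs) == pytest.approx(float(t.blen[i]), abs=1e-9)
            assert segs[0][0] == h.node_states[int(t.parent[i])]
            assert segs[-1][0] == h.node_states[i]
            assert all(a[0] != b[0] for a, b in zip(segs, segs[1:]))


def test_node_frequencies_match_marginals():
    """Law of large numbers: sampled node-state frequencies converge to the
    pruning marginal posteriors."""
    t = Phylogeny.from_newick("((A:1,B:2):0.5,(C:1.5,D:0.7):1);")
    model = MkCharacterModel(2, 0.3)
    tips = {"A": 0, "B": 1, "C": 1, "D": 0}
    marg = marginal_node_states(t, tips, model)
    n = 20000
    hists = stochastic_map(t, tips, model, n, seed=3, simulate_paths=False)
    states = np.array([h.node_states for h in hists])
    for i in range(t.n_nodes):
        if t.is_tip[i]:
            continue
        freq = (states[:, i] == 0).mean()
        se = np.sqrt(marg[i, 0] * (1 - marg[i, 0]) / n)
        assert abs(freq - marg[i, 0]) < 4 * se + 1e-9


def _matrix_on_tree(tree, columns):
    cells = np.array(columns, dtype=np.int16).T
    chars = [f"c{j + 1}" for j in range(cells.shape[1])]
    return CharacterMatrix(tree.tip_labels, chars, cells)


def test_impute_complete_matrix_unchanged():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    m = _matrix_on_tree(t, [[0, 1, 1]])
    focal, result = impute_matrix(m, t, n_sims=50, seed=0)
    assert np.array_equal(focal.cells, m.cells)


def test_impute_monophyletic_clade_low_rate():
    """A masked tip inside a clade uniformly scored 1 imputes to 1."""
    t = Phylogeny.from_newick("(((A:1,B:1):1,C:2):2,(D:2,E:2):2);")
    order = [t.labels.index(x) for x in ("A", "B", "C", "D", "E")]
    col = np.zeros(5, dtype=np.int16)
    for lbl, s in zip("ABCDE", [1, MISSING, 1, 0, 0]):
        col["ABCDE".index(lbl)] = s
    m = CharacterMatrix(list("ABCDE"), ["c1"], col[:, None])
    # reorder rows to tree tip order
    m = CharacterMatrix(t.tip_labels, ["c1"], m.cells[[list("ABCDE").index(x) for x in t.tip_labels]])
    focal, result = impute_matrix(m, t, n_sims=400, seed=1)
    assert focal.cells[focal.taxon_index("B"), 0] == 1


def test_impute_inapplicable_passthrough_and_unscored_warning(caplog):
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    cells = np.array([[INAPPLICABLE], [MISSING], [MISSING]], dtype=np.int16)
    m = CharacterMatrix(t.tip_labels, ["c1"], cells)
    with caplog.at_level(logging.WARNING, logger="phytodisparity"):
        focal, _ = impute_matrix(m, t, n_sims=10, seed=0)
    assert focal.cells[0, 0] == INAPPLICABLE
    assert (focal.cells[1:, 0] == MISSING).all()
    assert "no scored tips" in caplog.text


def test_single_tree_consensus_equals_per_tree_mode():
    """With one input tree the cross-tree consensus is that tree's modal
    sampled state, reproducible from the same seeded sampler."""
    t = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    m = _matrix_on_tree(t, [[0, MISSING, 1, 1]])
    focal1, r1 = impute_matrix(m, t, n_sims=200, seed=7)
    focal2, r2 = impute_matrix(m, TreeSample([t]), n_sims=200, seed=7)
    assert np.array_equal(focal1.cells, focal2.cells)
    assert r1.consensus == r2.consensus
    for key, freqs in r1.frequencies.items():
        assert sum(freqs.values()) == pytest.approx(1.0)
        assert r1.consensus[key] in freqs
        assert freqs[r1.consensus[key]] == max(freqs.values())


def test_focal_with_nodes_has_node_rows():
    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    m = _matrix_on_tree(t, [[0, 1, 1], [1, 1, 0]])
    focal, result = impute_matrix(m, t, n_sims=50, seed=0)
    combined = focal_with_nodes(focal, result, t)
    assert set(result.node_labels) <= set(combined.taxa)
    assert combined.n_taxa == m.n_taxa + len(result.node_labels)


@pytest.fixture(scope="module")
def imputation_experiment():
    """64+16-tip, 100-character recovery runs at two rates and two masks."""
    out = {}
    for key, (rate, frac) in {
        "low": (0.002, 0.2), "high": (0.02, 0.2), "heavy": (0.002, 0.45),
    }.items():
        sc = SyntheticScenario(
            n_extant=32, n_fossil=8, n_characters=60,
            rate_median=rate, rate_sigma=0.0, extant_missing_fraction=frac,
        )
        tree = simulate_tree(sc, seed=101)
        complete, _, _ = simulate_characters(tree, sc, seed=102)
        masked, mask = apply_missingness(complete, sc, seed=103)
        focal, _ = impute_matrix(masked, tree, n_sims=100, seed=104)
        hits = total = 0
        chance = 0.0
        for i, j in zip(*np.nonzero(mask)):
            col = masked.cells[:, j]
            obs = col[col >= 0]
            if obs.size == 0 or focal.cells[i, j] < 0:
                continue
            total += 1
            hits += focal.cells[i, j] == complete.cells[i, j]
            chance += float((obs == complete.cells[i, j]).mean())
        out[key] = (hits / total, chance / total)
    return out


def test_imputation_beats_chance(imputation_experiment):
    acc, chance = imputation_experiment["low"]
    assert acc > chance


def test_imputation_accuracy_degrades_with_rate_and_masking(imputation_experiment):
    assert imputation_experiment["low"][0] >= imputation_experiment["high"][0]
    assert imputation_experiment["low"][0] >= imputation_experiment["heavy"][0] - 0.02
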