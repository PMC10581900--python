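import numpy as np
import pytest

from phytodisparity import (
    GroupAssignment,
    Phylogeny,
    disparity_diversity_tests,
    dtt,
    groups_from_tree,
    mean_disparity,
    partial_disparity,
    sum_of_variances,
)
from phytodisparity.distances import DistanceMatrix
from phytodisparity.ordination import OrdinationResult


def _dm_from_pairs(labels, pairs):
    n = len(labels)
    vals = np.zeros((n, n))
    for (i, j), v in pairs.items():
        vals[i, j] = vals[j, i] = v
    return DistanceMatrix(labels, vals)


def test_mean_disparity_basic_cases():
    labels = ["a", "b", "c", "d"]
    d = _dm_from_pairs(
        labels, {(0, 1): 0.2, (0, 2): 0.4, (1, 2): 0.6, (0, 3): 0.5, (1, 3): 0.5, (2, 3): 0.5}
    )
    groups = GroupAssignment({"a": "g", "b": "g", "c": "g", "d": "solo"})
    s = mean_disparity(d, groups, n_boot=50, seed=0)
    assert s.per_group["g"].estimate == pytest.approx(0.4)
    assert s.per_group["solo"].flagged
    assert np.isnan(s.per_group["solo"].estimate)


def test_mean_disparity_two_member_and_identical():
    labels = ["a", "b", "c"]
    d = _dm_from_pairs(labels, {(0, 1): 0.8, (0, 2): 0.0, (1, 2): 0.8})
    s = mean_disparity(d, GroupAssignment({"a": "x", "b": "x"}), n_boot=0)
    assert s.per_group["x"].estimate == pytest.approx(0.8)
    s2 = mean_disparity(d, GroupAssignment({"a": "y", "c": "y"}), n_boot=0)
    assert s2.per_group["y"].estimate == 0.0


def test_sum_of_variances_unit_square_and_duplication():
    sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    assert sum_of_variances(sq) == pytest.approx(2 / 3)
    assert sum_of_variances(np.ones((5, 3))) == 0.0
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 2))
    doubled = np.vstack([X, X])
    n = len(X)
    expected = X.var(axis=0, ddof=0).sum() * (2 * n) / (2 * n - 1)
    assert sum_of_variances(doubled) == pytest.approx(expected)


def test_partial_disparity_identities():
    """Squared partial disparities over a partition sum exactly to the total
    sum of variances; a single all-covering group equals it alone."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(20, 3))
    labels = [f"u{i}" for i in range(20)]
    coords = OrdinationResult(labels, X, "pcoa")
    total = sum_of_variances(X)
    one = partial_disparity(coords, GroupAssignment({l: "all" for l in labels}), n_boot=0)
    assert one.per_group["all"].estimate == pytest.approx(total, abs=1e-12)
    split = GroupAssignment({l: ("A" if i % 3 else "B") for i, l in enumerate(labels)})
    s = partial_disparity(coords, split, n_boot=0)
    assert s.per_group["A"].estimate + s.per_group["B"].estimate == pytest.approx(
        total, abs=1e-10
    )


def test_partial_disparity_member_at_centroid():
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
    coords = OrdinationResult(["a", "b", "c"], X, "pcoa")
    s = partial_disparity(coords, GroupAssignment({"c": "centre"}), n_boot=0)
    assert s.per_group["centre"].estimate == pytest.approx(0.0, abs=1e-12)


def _dated_tree_with_coords():
    """Two clades splitting at 10 Ma; tips at 0, internal nodes labelled."""
    t = Phylogeny.from_newick("((A:4,B:4)N1:6,(C:8,D:8)N2:2)R;")
    coords = {
        "R": [0.0, 0.0], "N1": [-1.0, 0.0], "N2": [1.0, 0.0],
        "A": [-2.0, 1.0], "B": [-2.0, -1.0], "C": [2.0, 1.0], "D": [2.0, -1.0],
    }
    labels = list(coords)
    ordn = OrdinationResult(labels, np.array([coords[l] for l in labels]), "nmds")
    return t, ordn


def test_dtt_present_equals_extant_disparity():
    t, ordn = _dated_tree_with_coords()
    extant = ordn.coords_of(["A", "B", "C", "D"])
    for model in ("gradual", "punctuated"):
        curve = dtt(ordn, t, model=model, bin_Myr=4.0, n_boot=50, seed=0)
        assert curve.times[-1] == 0.0
        assert curve.estimates[-1] == pytest.approx(sum_of_variances(extant), abs=1e-12)


def test_dtt_gradual_interpolation_boundaries():
    t, ordn = _dated_tree_with_coords()
    # slice at N1/N2 age boundary handled by lineages_at convention; use the
    # midpoint of the A branch: A spans ages 4..0, coordinates N1->A
    curve = dtt(ordn, t, model="gradual", n_boot=0, times=np.array([2.0]))
    from phytodisparity.disparity import _slice_points

    pts = _slice_points(ordn, t, 2.0, "gradual", None)
    # A's branch at its midpoint: halfway between N1 (-1,0) and A (-2,1)
    assert any(np.allclose(p, [-1.5, 0.5]) for p in pts)
    # slice exactly at a node's age returns the node's own coordinates
    pts4 = _slice_points(ordn, t, 4.0, "gradual", None)
    assert any(np.allclose(p, [-1.0, 0.0]) for p in pts4)


def test_dtt_envelopes_nested_and_ordered():
    t, ordn = _dated_tree_with_coords()
    curve = dtt(ordn, t, model="gradual", bin_Myr=3.0, n_boot=200, seed=1)
    assert np.all(np.diff(curve.times) < 0)  # old -> young
    e = curve.envelopes
    assert np.all(e[2.5] <= e[25.0] + 1e-12)
    assert np.all(e[25.0] <= curve.medians + 1e-12)
    assert np.all(curve.medians <= e[75.0] + 1e-12)
    assert np.all(e[75.0] <= e[97.5] + 1e-12)


def test_dtt_gradual_continuity():
    t, ordn = _dated_tree_with_coords()
    times = np.linspace(0.0, t.root_age - 1e-6, 60)
    curve = dtt(ordn, t, model="gradual", n_boot=0, times=times)
    jumps = np.abs(np.diff(curve.estimates))
    # continuous except where the lineage count changes
    counts = curve.n_lineages
    smooth = jumps[np.diff(counts) == 0]
    assert smooth.max() < 0.5


def test_dtt_late_radiation_rises_late():
    """A clade that diversifies late in morphospace produces a DTT curve
    that is higher near the present than mid-history."""
    t = Phylogeny.from_newick("((A:2,B:2)N1:8,(C:2,D:2)N2:8)R;")
    coords = {
        "R": [0.0, 0.0], "N1": [0.1, 0.0], "N2": [-0.1, 0.0],
        "A": [5.0, 0.0], "B": [-5.0, 0.0], "C": [0.0, 5.0], "D": [0.0, -5.0],
    }
    labels = list(coords)
    ordn = OrdinationResult(labels, np.array([coords[l] for l in labels]), "nmds")
    curve = dtt(ordn, t, model="gradual", bin_Myr=2.0, n_boot=0)
    assert curve.estimates[-1] > 5 * curve.estimates[2]


def test_dtt_requires_embedded_nodes():
    t, ordn = _dated_tree_with_coords()
    tips_only = OrdinationResult(
        ["A", "B", "C", "D"], ordn.coords_of(["A", "B", "C", "D"]), "nmds"
    )
    with pytest.raises(ValueError, match="not embedded"):
        dtt(tips_only, t)


def test_groups_from_tree():
    t, _ = _dated_tree_with_coords()
    g = groups_from_tree(t, 9.0)
    assert sorted(set(g.groups.values())) == ["N1", "N2"]
    assert g.groups["A"] == "N1" and g.groups["C"] == "N2"


def test_disparity_diversity_tests_rank_agreement():
    labels = list("abcdefgh")
    d = DistanceMatrix(labels, np.zeros((8, 8)))
    per = {}
    from phytodisparity.disparity import DisparitySummary, GroupDisparity

    disp = [0.1, 0.2, 0.3, 0.4]
    per = {f"g{i}": GroupDisparity(v) for i, v in enumerate(disp)}
    summary = DisparitySummary("mean_pairwise", per)
    groups = GroupAssignment(
        {}, diversity={f"g{i}": 10 * (i + 1) for i in range(4)},
        ages={f"g{i}": float(i) for i in range(4)},
    )
    out = disparity_diversity_tests(summary, groups)
    assert out["disparity_vs_diversity"].coefficient == pytest.approx(1.0)
    assert out["disparity_vs_age"].coefficient == pytest.approx(1.0)


def test_disparity_diversity_constant_disparity_warns(caplog):
    import logging

    from phytodisparity.disparity import DisparitySummary, GroupDisparity

    per = {f"g{i}": GroupDisparity(0.5) for i in range(4)}
    summary = DisparitySummary("mean_pairwise", per)
    groups = GroupAssignment({}, diversity={f"g{i}": float(i) for i in range(4)})
    with caplog.at_level(logging.WARNING, logger="phytodisparity"):
        out = disparity_diversity_tests(summary, groups)
    assert np.isnan(out["disparity_vs_diversity"].coefficient)


def test_spearman_type_one_error_on_few_groups():
    """At alpha=0.05 with 8 independent groups the t-approximate Spearman
    test rejects at roughly nominal rate."""
    from phytodisparity import correlate

    rng = np.random.default_rng(6)
    n_rej = 0
    reps = 3000
    for _ in range(reps):
        x, y = rng.normal(size=(2, 8))
        n_rej += correlate(x, y, "spearman").p_value <= 0.05
    assert 0.02 <= n_rej / reps <= 0.08


def test_bootstrap_percentiles_bracket_estimate():
    rng = np.random.default_rng(7)
    labels = [f"u{i}" for i in range(30)]
    X = rng.normal(size=(30, 2))
    d = DistanceMatrix.from_coordinates(labels, X)
    s = mean_disparity(d, GroupAssignment({l: "all" for l in labels}), n_boot=500, seed=1)
    g = s.per_group["all"]
    assert g.percentiles[2.5] <= g.estimate <= g.percentiles[97.5]
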