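import numpy as np
import pytest

from phytodisparity import (
    convex_hull,
    hull_area,
    nmds,
    ordination_concordance,
    pcoa,
    phylomorphospace,
)
from phytodisparity.distances import DistanceMatrix


def _dm(points, labels=None):
    labels = labels or [f"u{i}" for i in range(len(points))]
    return DistanceMatrix.from_coordinates(labels, np.asarray(points, float))


def test_nmds_unit_square_geometry():
    d = _dm([[0, 0], [1, 0], [1, 1], [0, 1]])
    r = nmds(d, k=2, n_starts=20, seed=0)
    assert r.stress < 1e-3
    # with only two distinct dissimilarity values the rank structure alone is
    # degenerate (any rectangle fits); tie-averaging restores the geometry
    r2 = nmds(d, k=2, n_starts=20, seed=0, ties="secondary")
    assert r2.stress < 1e-3
    dd = r2.distances().values
    side = dd[0, 1]
    assert dd[0, 2] / side == pytest.approx(np.sqrt(2), rel=1e-3)
    assert dd[1, 3] / side == pytest.approx(np.sqrt(2), rel=1e-3)


def test_nmds_two_points_zero_stress():
    d = DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
    r = nmds(d, k=2, n_starts=5, seed=0)
    assert r.stress == pytest.approx(0.0, abs=1e-8)


def test_nmds_perfect_one_dimensional_structure():
    d = _dm([[x, 0.0] for x in [0, 1, 2.5, 4, 7]])
    r = nmds(d, k=2, n_starts=10, seed=1)
    assert r.stress < 1e-6


def test_nmds_stress_monotone_per_iteration():
    rng = np.random.default_rng(5)
    d = _dm(rng.normal(size=(20, 3)))
    r = nmds(d, k=2, n_starts=5, seed=2)
    h = r.stress_history
    assert all(a >= b - 1e-9 for a, b in zip(h, h[1:]))


def test_nmds_more_dimensions_never_hurt():
    rng = np.random.default_rng(6)
    d = _dm(rng.normal(size=(15, 4)))
    s2 = nmds(d, k=2, n_starts=10, seed=3).stress
    s3 = nmds(d, k=3, n_starts=10, seed=3).stress
    assert s3 <= s2 + 1e-6


def test_nmds_zero_weight_for_flagged_pairs():
    pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
    d = _dm(pts)
    flagged = np.zeros((4, 4), dtype=bool)
    flagged[0, 3] = flagged[3, 0] = True
    d_bad = DistanceMatrix(d.labels, np.where(flagged, 10.0, d.values), None, flagged)
    r = nmds(d_bad, k=2, n_starts=10, seed=4)
    # the absurd flagged value is ignored, so the square still embeds cleanly
    assert r.stress < 1e-3


def test_pcoa_recovers_planar_coordinates():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(9, 2))
    r = pcoa(_dm(X))
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(X, r.coordinates[:, :2])
    assert np.sqrt(disparity) < 1e-8
    assert np.all(np.diff(r.eigenvalues) <= 1e-9)


def test_pcoa_simplex_equal_distances():
    n = 6
    vals = np.ones((n, n)) - np.eye(n)
    r = pcoa(DistanceMatrix([f"u{i}" for i in range(n)], vals))
    pos = r.eigenvalues[r.eigenvalues > 1e-10]
    assert len(pos) == n - 1
    assert np.allclose(pos, pos[0])


def test_pcoa_identical_units_zero():
    n = 4
    r = pcoa(DistanceMatrix([f"u{i}" for i in range(n)], np.zeros((n, n))))
    assert np.allclose(r.coordinates, 0.0)


def test_pcoa_matches_skbio():
    """Independent implementation check against scikit-bio."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(8)
    X = rng.normal(size=(10, 3))
    d = _dm(X)
    ours = pcoa(d)
    theirs = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(d.values, ids=d.labels), method="eigh"
    )
    k = 3
    assert np.allclose(
        np.sort(ours.eigenvalues[:k]), np.sort(theirs.eigvals.values[:k]), atol=1e-8
    )
    assert np.allclose(
        np.abs(ours.coordinates[:, :k]), np.abs(theirs.samples.values[:, :k]), atol=1e-6
    )


def test_concordance_self_and_rigid_motion():
    rng = np.random.default_rng(9)
    from phytodisparity.ordination import OrdinationResult

    X = rng.normal(size=(12, 2))
    a = OrdinationResult([f"u{i}" for i in range(12)], X, "nmds")
    r_self = ordination_concordance(a, a, n_perm=99, seed=0)
    assert r_self.coefficient == pytest.approx(1.0)
    assert r_self.p_value == pytest.approx(1 / 100)
    flipped = OrdinationResult(a.labels, X[:, ::-1] * np.array([1, -1]), "nmds")
    assert ordination_concordance(a, flipped, n_perm=9, seed=0).coefficient == pytest.approx(1.0)


def test_concordance_independent_embeddings_null():
    rng = np.random.default_rng(10)
    from phytodisparity.ordination import OrdinationResult

    labels = [f"u{i}" for i in range(30)]
    a = OrdinationResult(labels, rng.normal(size=(30, 2)), "nmds")
    b = OrdinationResult(labels, rng.normal(size=(30, 2)), "nmds")
    r = ordination_concordance(a, b, n_perm=199, seed=1)
    assert abs(r.coefficient) < 0.3
    assert r.p_value > 0.05


def test_concordance_euclidean_inputs_high():
    """Metricity check: on genuinely planar data NMDS and PCoA agree."""
    rng = np.random.default_rng(11)
    d = _dm(rng.normal(size=(25, 2)))
    r = ordination_concordance(
        nmds(d, k=2, n_starts=10, seed=0), pcoa(d), n_perm=99, seed=0
    )
    assert r.coefficient > 0.95


def test_phylomorphospace_requires_node_rows():
    from phytodisparity import CharacterMatrix, Phylogeny

    t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
    m = CharacterMatrix(["A", "B", "C"], ["c1"], np.array([[0], [1], [1]], dtype=np.int16))
    with pytest.raises(ValueError, match="lacks rows"):
        phylomorphospace(m, t)


def test_phylomorphospace_two_regimes_bridged(default_dataset):
    """Ancestor chain connects tip clusters: at least one plotted branch
    joins units assigned to different tip clusters."""
    from phytodisparity import (
        SyntheticScenario, simulate_tree, simulate_characters, impute_matrix,
        focal_with_nodes,
    )

    sc = SyntheticScenario(
        n_extant=24, n_fossil=0, death_rate=0.0, n_characters=80,
        rate_median=0.002, regime_multiplier=12.0,
    )
    tree = simulate_tree(sc, seed=21)
    m, _, _ = simulate_characters(tree, sc, seed=22)
    focal, result = impute_matrix(m, tree, n_sims=50, seed=23)
    combined = focal_with_nodes(focal, result, tree)
    ordn, edges = phylomorphospace(combined, tree, seed=24)
    from sklearn.cluster import KMeans

    tips = tree.tip_labels
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(ordn.coords_of(tips))
    centers = km.cluster_centers_
    index = {l: i for i, l in enumerate(ordn.labels)}

    def nearest(lbl):
        return int(np.argmin(((centers - ordn.coordinates[index[lbl]]) ** 2).sum(axis=1)))

    crossing = sum(nearest(a) != nearest(b) for a, b in edges)
    assert crossing >= 1


def test_phylomorphospace_star_identical_tips():
    from phytodisparity import CharacterMatrix, Phylogeny

    t = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
    rows = np.tile(np.array([0, 1, 1], dtype=np.int16), (5, 1))
    m = CharacterMatrix(["A", "B", "C", "D", "N0"], ["c1", "c2", "c3"], rows)
    ordn, edges = phylomorphospace(m, t, seed=0)
    assert np.allclose(ordn.coordinates, ordn.coordinates[0], atol=1e-8)
    assert len(edges) == 4


def test_convex_hull_square_centre_and_collinear():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
    hull = convex_hull(pts)
    assert len(hull) == 4
    assert hull_area(hull) == pytest.approx(1.0)
    seg = convex_hull(np.array([[0, 0], [1, 1], [2, 2]]))
    assert len(seg) == 2
    assert hull_area(seg) == 0.0


def test_convex_hull_area_matches_qhull_oracle():
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(12)
    pts = rng.normal(size=(100, 2))
    ours = hull_area(convex_hull(pts))
    assert ours == pytest.approx(ConvexHull(pts).volume, rel=1e-10)
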