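"""Morphospace construction: NMDS, PCoA, phylomorphospace, convex hulls.

NMDS embeds units so that ordination distances are monotone in the observed
dissimilarities, by stress majorization (SMACOF) alternating an isotonic
("primary" tie handling) regression of disparities on dissimilarity rank
with weighted Guttman configuration updates.  Quality is Kruskal stress-1.
Flagged dissimilarities (pairs with no comparable characters) get zero
weight: they carry no information.

PCoA is the metric counterpart: double-centred squared dissimilarities,
eigendecomposed; coordinates use the positive eigenvalues, negative ones are
reported uncorrected as a metricity diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.isotonic import isotonic_regression

from .distances import DistanceMatrix
from .matrix_io import CharacterMatrix
from .stats import CorrelationReport, mantel
from .trees import Phylogeny

logger = logging.getLogger("phytodisparity")


@dataclass
class OrdinationResult:
    """Low-dimensional coordinates for tips (and optionally nodes)."""

    labels: list[str]
    coordinates: np.ndarray
    method: str
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    shepard: np.ndarray | None = None  # columns: observed dissimilarity, ordination distance
    converged: bool = True
    stress_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if len(self.labels) != self.coordinates.shape[0]:
            raise ValueError("one coordinate row per label required")

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def coords_of(self, labels: list[str]) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.labels)}
        return self.coordinates[[index[l] for l in labels]]

    def distances(self) -> DistanceMatrix:
        return DistanceMatrix.from_coordinates(self.labels, self.coordinates)

    def to_frame(self, is_node=lambda lbl: False):
        import pandas as pd

        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis{i + 1}" for i in range(self.k)],
        )
        df.insert(0, "unit", self.labels)
        df.insert(1, "is_node", [bool(is_node(l)) for l in self.labels])
        return df


def _standardize_orientation(X: np.ndarray) -> np.ndarray:
    """Centre, rotate to principal axes, and fix signs (first unit >= 0)."""
    X = X - X.mean(axis=0)
    if X.shape[0] > 1:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        X = X @ vt.T
    for a in range(X.shape[1]):
        col = X[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            X[:, a] = -col
    return X


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
    ties: str = "primary",
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with isotonic disparities.

    Best configuration over ``n_starts`` random starts; deterministic under
    a fixed seed.  Stress-1 = sqrt(sum w (dhat - dist)^2 / sum w dist^2).
    ``ties="primary"`` (Kruskal) lets tied dissimilarities take different
    disparities; ``"secondary"`` forces equal disparities within tie blocks
    (needed when the rank structure alone is degenerate, e.g. few points
    with many exact ties).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ties not in {"primary", "secondary"}:
        raise ValueError(f"unknown tie treatment {ties!r}")
    n = d.n
    if n == 1:
        return OrdinationResult(list(d.labels), np.zeros((1, k)), "nmds", stress=0.0)
    iu = np.triu_indices(n, k=1)
    delta = d.values[iu]
    w = (~d.flagged[iu]).astype(float)
    if w.sum() == 0:
        raise ValueError("all pairs flagged; nothing to embed")
    if (delta[w > 0] == 0).all():
        # all informative dissimilarities vanish: every unit coincides
        return OrdinationResult(list(d.labels), np.zeros((n, k)), "nmds", stress=0.0)
    rng = np.random.default_rng(seed)
    if ties == "secondary":
        _, tie_group = np.unique(delta, return_inverse=True)
        n_groups = tie_group.max() + 1
        group_w = np.bincount(tie_group, weights=w, minlength=n_groups)

    W = np.ones((n, n))
    W[d.flagged] = 0.0
    np.fill_diagonal(W, 0.0)
    uniform_w = bool((W + np.eye(n) == 1).all())
    if not uniform_w:
        V = np.diag(W.sum(axis=1)) - W
        Vp = np.linalg.pinv(V)

    best = None
    for _ in range(max(1, n_starts)):
        X = rng.normal(size=(n, k))
        last = np.inf
        history: list[float] = []
        converged = False
        for _ in range(max_iter):
            D = _pairwise(X)
            dist = D[iu]
            if ties == "primary":
                # within tied dissimilarities, order by current configuration
                # distance so ties impose no constraint
                o = np.lexsort((dist, delta))
                dhat = np.empty_like(dist)
                dhat[o] = isotonic_regression(
                    dist[o], sample_weight=np.maximum(w[o], 1e-12)
                )
            else:
                means = np.bincount(
                    tie_group, weights=w * dist, minlength=n_groups
                ) / np.maximum(group_w, 1e-12)
                fitted = isotonic_regression(
                    means, sample_weight=np.maximum(group_w, 1e-12)
                )
                dhat = fitted[tie_group]
            # anchor the disparity scale to a fixed sum of squares so the
            # configuration cannot drift toward collapse (stress-1 is
            # scale-invariant and provides no restoring force)
            dhat *= np.sqrt(w.sum() / max((w * dhat**2).sum(), 1e-300))
            denom = (w * dist**2).sum()
            stress = float(np.sqrt((w * (dhat - dist) ** 2).sum() / denom))
            history.append(stress)
            if last - stress < tol:
                converged = True
                break
            last = stress
            # Guttman transform
            Dhat = np.zeros((n, n))
            Dhat[iu] = dhat
            Dhat += Dhat.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(D > 0, Dhat / np.maximum(D, 1e-300), 0.0)
            B = -W * ratio
            np.fill_diagonal(B, -B.sum(axis=1))
            X = (Vp @ (B @ X)) if not uniform_w else (B @ X) / n
        if best is None or history[-1] < best[0]:
            best = (history[-1], X, history, converged)

    stress, X, history, converged = best
    if not converged:
        logger.warning("NMDS did not converge in any start (best stress %.4g)", stress)
    X = _standardize_orientation(X)
    dist = _pairwise(X)[iu]
    shepard = np.column_stack([delta[w > 0], dist[w > 0]])
    return OrdinationResult(
        list(d.labels), X, "nmds", stress=stress, shepard=shepard,
        converged=converged, stress_history=history,
    )


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigenvalues are reported in full, negatives uncorrected; coordinates are
    eigenvectors scaled by sqrt of the positive eigenvalues.
    """
    n = d.n
    D2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2
    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0)
    if pos.any():
        X = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    else:
        X = np.zeros((n, 1))
    for a in range(X.shape[1]):
        col = X[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            X[:, a] = -col
    iu = np.triu_indices(n, k=1)
    shepard = np.column_stack([d.values[iu], _pairwise(X)[iu]])
    return OrdinationResult(list(d.labels), X, "pcoa", eigenvalues=eigvals, shepard=shepard)


def ordination_concordance(
    a: OrdinationResult,
    b: OrdinationResult,
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelationReport:
    """Mantel correlation between two embeddings' pairwise distances."""
    if a.labels != b.labels:
        raise ValueError("ordinations must share labels in the same order")
    return mantel(a.distances(), b.distances(), n_perm=n_perm, seed=seed)


def phylomorphospace(
    m_focal: CharacterMatrix,
    tree: Phylogeny,
    distance_fun=None,
    ordination_fun=None,
    seed: int | None = None,
) -> tuple[OrdinationResult, list[tuple[str, str]]]:
    """Joint ordination of tips and reconstructed ancestors, plus the edge
    list pairing each internal node with its children for branch plotting.

    ``m_focal`` must contain a row for every tree node (tips and internals),
    as produced by imputation followed by ``focal_with_nodes``.
    """
    from .distances import gower as _gower

    missing = [lbl for lbl in tree.labels if lbl not in set(m_focal.taxa)]
    if missing:
        raise ValueError(
            f"focal matrix lacks rows for tree nodes {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    d = (distance_fun or _gower)(m_focal)
    if ordination_fun is None:
        result = nmds(d, k=2, seed=seed)
    else:
        result = ordination_fun(d)
    edges = [
        (tree.labels[int(tree.parent[i])], tree.labels[i])
        for i in range(1, tree.n_nodes)
    ]
    return result, edges


def convex_hull(points: np.ndarray) -> np.ndarray:
    """2-D convex hull by monotone chain, counterclockwise.

    Collinear input returns the extreme segment; single points return
    themselves.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    uniq = np.unique(pts, axis=0)
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    P = uniq[order]
    if len(P) <= 2:
        return P

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in P:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in P[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # collinear
        return np.array([P[0], P[-1]])
    return np.array(hull)


def hull_area(hull: np.ndarray) -> float:
    """Shoelace area of an ordered hull (0 for degenerate hulls)."""
    if len(hull) < 3:
        return 0.0
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
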