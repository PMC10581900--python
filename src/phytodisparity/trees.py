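"""Dated phylogenies and tree samples.

Trees are stored in a flat, array-backed form (preorder node indexing with
parent pointers and branch lengths in Myr) built from dendropy's parsers.
Node ages (Ma before present) are derived from root-to-node path lengths,
anchoring the deepest tip at the present; tips with positive ages are
extinct (fossil) taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("phytodisparity")

_AGE_TOL = 1e-9


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in Myr.

    Nodes are indexed in preorder (root = 0).  ``parent[i]`` is the parent
    index (-1 for the root) and ``blen[i]`` the length of the branch above
    node ``i`` (0 for the root).  Internal nodes without input labels get
    stable automatic labels ``N<i>``.
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list[str]
    is_tip: np.ndarray

    children: list[list[int]] = field(init=False, repr=False)
    ages: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=float)
        self.is_tip = np.asarray(self.is_tip, dtype=bool)
        n = len(self.parent)
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise TreeError("tree must have exactly one root at index 0")
        if (self.blen < 0).any():
            i = int(np.argmin(self.blen))
            raise TreeError(f"negative branch length above node {self.labels[i]!r}")
        n_zero = int((self.blen[1:] == 0).sum())
        if n_zero:
            logger.warning("%d zero-length branches present", n_zero)
        tip_labels = [self.labels[i] for i in range(n) if self.is_tip[i]]
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        self.children = [[] for _ in range(n)]
        for i in range(1, n):
            if self.parent[i] >= i:
                raise TreeError("nodes must be in preorder (parent before child)")
            self.children[self.parent[i]].append(i)
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[self.parent[i]] + self.blen[i]
        self.ages = depth.max() - depth

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        labels: list[str] = []
        is_tip = np.zeros(len(nodes), dtype=bool)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    name = nd.taxon.label if nd.taxon else (nd.label or f"N{i}")
                    raise TreeError(f"missing branch length above node {name!r}")
                blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                is_tip[i] = True
                labels.append(nd.taxon.label if nd.taxon else (nd.label or f"t{i}"))
            else:
                labels.append(nd.label or (nd.taxon.label if nd.taxon else f"N{i}"))
        return cls(parent, blen, labels, is_tip)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        import dendropy

        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            raise TreeError(f"newick parse failure ({exc})") from exc
        return cls.from_dendropy(tree)

    # -- basic access -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def root_age(self) -> float:
        return float(self.ages[0])

    @property
    def extinct_tips(self) -> list[str]:
        return [
            self.labels[i] for i in self.tip_indices if self.ages[i] > 1e-6
        ]

    def postorder(self) -> Iterable[int]:
        return range(self.n_nodes - 1, -1, -1)

    def preorder(self) -> Iterable[int]:
        return range(self.n_nodes)

    def clade_tipsets(self) -> dict[int, frozenset[str]]:
        """Tip-label set under each node (tips map to their own singleton)."""
        sets: dict[int, frozenset[str]] = {}
        for i in self.postorder():
            if self.is_tip[i]:
                sets[i] = frozenset([self.labels[i]])
            else:
                acc: set[str] = set()
                for c in self.children[i]:
                    acc |= sets[c]
                sets[i] = frozenset(acc)
        return sets

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_tip[i]:
                core = self.labels[i].replace(" ", "_")
            else:
                core = (
                    "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
                    + self.labels[i].replace(" ", "_")
                )
            if self.parent[i] == -1:
                return core
            return f"{core}:{self.blen[i]:.10g}"

        return fmt(0) + ";"

    # -- analyses ---------------------------------------------------------
    def patristic_distances(self):
        """Sum of branch lengths along tip-to-tip paths.

        Returns a :class:`~phytodisparity.distances.DistanceMatrix` over tips.
        """
        from .distances import DistanceMatrix

        tips = self.tip_indices
        n = len(tips)
        n_nodes = self.n_nodes
        depth = self.ages[0] - self.ages  # root-to-node path length
        anc = np.zeros((n, n_nodes), dtype=bool)
        for r, i in enumerate(tips):
            j = i
            while j != -1:
                anc[r, j] = True
                j = int(self.parent[j])
        d = np.zeros((n, n))
        for r in range(n):
            common = anc[r] & anc  # (n, n_nodes)
            lca_depth = np.where(common, depth, -np.inf).max(axis=1)
            d[r] = depth[tips[r]] + depth[tips] - 2 * lca_depth
        d[np.arange(n), np.arange(n)] = 0.0
        comparable = np.full((n, n), self.n_nodes)
        return DistanceMatrix(self.tip_labels, d, comparable)

    def lineages_at(self, time: float) -> list[int]:
        """Branches (identified by child-node index) crossing ``time`` Ma.

        A branch crosses when parent age > time >= child age, so the slice is
        closed at the child: a slice at a node's age includes that node's
        branch, and the present-day slice returns exactly the extant tips.
        At the root age the root's child branches are returned.
        """
        if time < -_AGE_TOL or time > self.root_age + _AGE_TOL:
            raise ValueError(
                f"slice time {time} outside [0, root age {self.root_age:.6g}]"
            )
        if abs(time - self.root_age) <= _AGE_TOL:
            return list(self.children[0])
        return [
            i
            for i in range(1, self.n_nodes)
            if self.ages[self.parent[i]] > time + _AGE_TOL
            and time >= self.ages[i] - _AGE_TOL
        ]


@dataclass
class TreeSample:
    """Ordered collection of trees over an identical tip set."""

    trees: list[Phylogeny]

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=2):
            if set(t.tip_labels) != ref:
                raise TreeError(f"tree {k} has a different tip set from tree 1")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def read_trees(path: str | Path, format: str | None = None) -> TreeSample:
    """Read one or more rooted trees (Newick or NEXUS TREES block)."""
    import dendropy

    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".nxs"} else "newick"
    tl = dendropy.TreeList.get(
        path=str(path), schema=format, suppress_internal_node_taxa=True
    )
    if not tl:
        raise TreeError(f"no trees found in {path}")
    return TreeSample([Phylogeny.from_dendropy(t) for t in tl])


def write_trees(sample: TreeSample | Phylogeny, path: str | Path) -> None:
    trees = sample.trees if isinstance(sample, TreeSample) else [sample]
    Path(path).write_text("\n".join(t.to_newick() for t in trees) + "\n")


def load_tip_ages(path: str | Path) -> dict[str, float]:
    """Read a tip-age sidecar CSV with columns (taxon, age_Ma)."""
    import pandas as pd

    df = pd.read_csv(path)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def link_tree_matrix(tree: Phylogeny, taxa: Sequence[str]) -> None:
    """Validate that every tree tip has a matrix row; raise listing strays."""
    stray = sorted(set(tree.tip_labels) - set(taxa))
    if stray:
        raise TreeError(f"tree tips absent from matrix: {stray}")
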