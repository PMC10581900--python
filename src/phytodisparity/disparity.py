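"""Clade disparity indices and disparity-through-time by time-slicing.

Mean disparity of a clade is the mean pairwise dissimilarity among its
members.  Partial disparity is a clade's contribution to total variance:
the sum of its members' (squared, by default) distances to the grand
centroid divided by n - 1 with n the total units in the analysis; in
squared mode partial disparities over a partition sum exactly to the total
sum of variances.

Disparity through time slices a dated tree every ``bin_Myr`` (plus the root
age), takes the lineages crossing each slice, assigns each a morphospace
point — linear interpolation between its parent and child embeddings under
the gradual model, a random endpoint under the punctuated model — and
measures the sum of variances of the slice points, with bootstrap
percentile envelopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix
from .ordination import OrdinationResult
from .stats import CorrelationReport, correlate
from .trees import Phylogeny

logger = logging.getLogger("phytodisparity")

_PCTS = (2.5, 25.0, 75.0, 97.5)


@dataclass
class GroupAssignment:
    """Unit -> group map with optional per-group diversity counts and ages."""

    groups: dict[str, str]
    diversity: dict[str, float] | None = None
    ages: dict[str, float] | None = None

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for unit, grp in self.groups.items():
            out.setdefault(grp, []).append(unit)
        return out

    def validate_against(self, labels: list[str]) -> None:
        stray = sorted(set(self.groups) - set(labels))
        if stray:
            raise ValueError(f"grouped units missing from analysis: {stray[:5]}")


@dataclass
class GroupDisparity:
    estimate: float
    bootstrap: np.ndarray | None = None
    percentiles: dict[float, float] | None = None
    flagged: bool = False


@dataclass
class DisparitySummary:
    metric: str
    per_group: dict[str, GroupDisparity]

    def to_frame(self):
        import pandas as pd

        rows = []
        for grp in sorted(self.per_group):
            g = self.per_group[grp]
            row = {"group": grp, "metric": self.metric, "estimate": g.estimate,
                   "flagged": g.flagged}
            if g.percentiles:
                for p in _PCTS:
                    row[f"p{p:g}"] = g.percentiles[p]
            rows.append(row)
        return pd.DataFrame(rows)


def _pcts(boot: np.ndarray) -> dict[float, float]:
    return {p: float(np.percentile(boot, p)) for p in _PCTS}


def groups_from_tree(tree: Phylogeny, age: float) -> GroupAssignment:
    """Clades defined by the branches crossing ``age``: each crossing branch's
    tip descendants form one group named after its child node.  Fossil tips
    whose lineages terminated before the cut belong to no crossing clade and
    are pooled into a "stem" group, so the groups partition every tip."""
    clades = tree.clade_tipsets()
    groups: dict[str, str] = {}
    ages: dict[str, float] = {}
    for i in tree.lineages_at(age):
        name = tree.labels[i]
        for tip in clades[i]:
            groups[tip] = name
        ages[name] = float(tree.ages[i])
    stem = [t for t in tree.tip_labels if t not in groups]
    if stem:
        for tip in stem:
            groups[tip] = "stem"
        ages["stem"] = float(tree.root_age)
    return GroupAssignment(groups, ages=ages)


def mean_disparity(
    d: DistanceMatrix,
    groups: GroupAssignment,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DisparitySummary:
    """Mean pairwise distance within each group, with a bootstrap over group
    members (resampled with replacement)."""
    groups.validate_against(d.labels)
    index = {l: i for i, l in enumerate(d.labels)}
    rng = np.random.default_rng(seed)
    out: dict[str, GroupDisparity] = {}
    for grp, members in sorted(groups.members().items()):
        idx = np.array([index[m] for m in members])
        if len(idx) < 2:
            logger.warning("group %r has <2 members; mean disparity undefined", grp)
            out[grp] = GroupDisparity(float("nan"), flagged=True)
            continue
        sub = d.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        est = float(sub[iu].mean())
        boot = None
        pct = None
        if n_boot > 0:
            boot = np.empty(n_boot)
            for b in range(n_boot):
                r = rng.integers(0, len(idx), size=len(idx))
                boot[b] = sub[np.ix_(r, r)][iu].mean()
            pct = _pcts(boot)
        out[grp] = GroupDisparity(est, boot, pct)
    return DisparitySummary("mean_pairwise", out)


def sum_of_variances(coords: np.ndarray) -> float:
    """Sum over axes of the sample variance (denominator n - 1)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("coords must be 2-D")
    if coords.shape[0] < 2:
        logger.warning("sum_of_variances needs >=2 units; returning 0")
        return 0.0
    return float(coords.var(axis=0, ddof=1).sum())


def partial_disparity(
    coords: OrdinationResult,
    groups: GroupAssignment,
    squared: bool = True,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DisparitySummary:
    """Per-group contribution to total disparity.

    Sum over members of (squared) distance to the grand centroid of *all*
    units, divided by (n_total - 1).  Squared mode makes contributions over
    a partition sum to the total sum of variances.  Bootstrap resamples
    group members with the centroid and n_total held fixed.
    """
    groups.validate_against(coords.labels)
    X = coords.coordinates
    centroid = X.mean(axis=0)
    n_total = X.shape[0]
    dist = np.sqrt(((X - centroid) ** 2).sum(axis=1))
    contrib = dist**2 if squared else dist
    index = {l: i for i, l in enumerate(coords.labels)}
    rng = np.random.default_rng(seed)
    out: dict[str, GroupDisparity] = {}
    for grp, members in sorted(groups.members().items()):
        idx = np.array([index[m] for m in members])
        if len(idx) == 0:
            out[grp] = GroupDisparity(0.0, flagged=True)
            continue
        vals = contrib[idx]
        est = float(vals.sum() / (n_total - 1))
        boot = None
        pct = None
        if n_boot > 0:
            draws = rng.integers(0, len(idx), size=(n_boot, len(idx)))
            boot = vals[draws].sum(axis=1) / (n_total - 1)
            pct = _pcts(boot)
        out[grp] = GroupDisparity(est, boot, pct)
    return DisparitySummary("partial" + ("_squared" if squared else ""), out)


@dataclass
class DTTCurve:
    """Disparity at successive time slices, old to young, with envelopes."""

    times: np.ndarray  # Ma, descending
    estimates: np.ndarray
    medians: np.ndarray
    envelopes: dict[float, np.ndarray]
    model: str
    n_lineages: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flagged is None:
            self.flagged = np.zeros(len(self.times), dtype=bool)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_Ma": self.times,
                "model": self.model,
                "n_lineages": self.n_lineages,
                "estimate": self.estimates,
                "median": self.medians,
                "flagged": self.flagged,
            }
        )
        for p in _PCTS:
            df[f"p{p:g}"] = self.envelopes[p]
        return df


def _slice_points(
    coords: OrdinationResult,
    tree: Phylogeny,
    time: float,
    model: str,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Morphospace point of each lineage crossing ``time``.

    A branch sliced exactly at its child's age contributes the child's own
    coordinates under either model (so the present-day slice is exactly the
    extant tips).
    """
    index = {l: i for i, l in enumerate(coords.labels)}
    X = coords.coordinates
    pts = []
    for i in tree.lineages_at(time):
        p = int(tree.parent[i])
        ci, pi = index[tree.labels[i]], index[tree.labels[p]]
        age_c, age_p = float(tree.ages[i]), float(tree.ages[p])
        if abs(time - age_c) <= 1e-9 or age_p - age_c <= 0:
            pts.append(X[ci])
        elif model == "gradual":
            frac = (age_p - time) / (age_p - age_c)
            pts.append(X[pi] + frac * (X[ci] - X[pi]))
        elif model == "punctuated":
            assert rng is not None
            pts.append(X[ci] if rng.random() < 0.5 else X[pi])
        else:
            raise ValueError(f"unknown model {model!r}")
    return np.array(pts)


def dtt(
    coords: OrdinationResult,
    tree: Phylogeny,
    model: str = "gradual",
    bin_Myr: float = 50.0,
    n_boot: int = 1000,
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> DTTCurve:
    """Disparity through time by time-slicing.

    Slices run every ``bin_Myr`` back from the present plus one at the root
    age.  The statistic per slice is the sum of variances of the crossing
    lineages' points; envelopes come from bootstrap resampling of the slice
    points (the punctuated model re-randomizes its endpoint choices per
    replicate, propagating model uncertainty into the envelopes).
    """
    missing = [l for l in tree.labels if l not in set(coords.labels)]
    if missing:
        raise ValueError(f"tree nodes not embedded: {missing[:5]}")
    if times is None:
        times = np.arange(0.0, tree.root_age, bin_Myr)
        times = np.unique(np.append(times, tree.root_age))
    times = np.sort(np.asarray(times, dtype=float))[::-1]  # old -> young
    rng = np.random.default_rng(seed)
    est = np.empty(len(times))
    med = np.empty(len(times))
    nlin = np.empty(len(times), dtype=int)
    flagged = np.zeros(len(times), dtype=bool)
    env = {p: np.empty(len(times)) for p in _PCTS}
    for s, t in enumerate(times):
        point_rng = np.random.default_rng(rng.integers(2**31))
        pts = _slice_points(coords, tree, float(t), model, point_rng)
        nlin[s] = len(pts)
        if len(pts) < 2:
            logger.warning("slice at %.4g Ma has <2 lineages", t)
            est[s] = med[s] = 0.0
            flagged[s] = True
            for p in _PCTS:
                env[p][s] = 0.0
            continue
        est[s] = sum_of_variances(pts)
        if n_boot > 0:
            boot = np.empty(n_boot)
            for b in range(n_boot):
                if model == "punctuated":
                    rep_rng = np.random.default_rng(rng.integers(2**31))
                    rep_pts = _slice_points(coords, tree, float(t), model, rep_rng)
                else:
                    rep_pts = pts
                r = rng.integers(0, len(rep_pts), size=len(rep_pts))
                boot[b] = sum_of_variances(rep_pts[r])
            med[s] = float(np.median(boot))
            for p in _PCTS:
                env[p][s] = float(np.percentile(boot, p))
        else:
            med[s] = est[s]
            for p in _PCTS:
                env[p][s] = est[s]
    return DTTCurve(times, est, med, env, model, nlin, flagged)


def disparity_diversity_tests(
    summary: DisparitySummary, groups: GroupAssignment
) -> dict[str, CorrelationReport]:
    """Spearman disparity-vs-diversity and Pearson disparity-vs-clade-age."""
    names = [
        g for g in sorted(summary.per_group)
        if not summary.per_group[g].flagged and np.isfinite(summary.per_group[g].estimate)
    ]
    disp = np.array([summary.per_group[g].estimate for g in names])
    out: dict[str, CorrelationReport] = {}
    if groups.diversity is not None:
        have = [g for g in names if g in groups.diversity]
        if len(have) < 3:
            raise ValueError("need >=3 groups with diversity counts")
        div = np.array([groups.diversity[g] for g in have])
        dd = np.array([summary.per_group[g].estimate for g in have])
        try:
            out["disparity_vs_diversity"] = correlate(dd, div, "spearman")
        except ValueError:
            logger.warning("disparity constant across groups; Spearman undefined")
            out["disparity_vs_diversity"] = CorrelationReport(
                "spearman", float("nan"), float("nan"), len(have)
            )
    if groups.ages is not None:
        have = [g for g in names if g in groups.ages]
        if len(have) < 3:
            raise ValueError("need >=3 groups with ages")
        ages = np.array([groups.ages[g] for g in have])
        dd = np.array([summary.per_group[g].estimate for g in have])
        try:
            out["disparity_vs_age"] = correlate(dd, ages, "pearson")
        except ValueError:
            out["disparity_vs_age"] = CorrelationReport(
                "pearson", float("nan"), float("nan"), len(have)
            )
    if not out:
        raise ValueError("groups carry neither diversity counts nor ages")
    return out
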