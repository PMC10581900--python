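"""Correlation and permutation machinery shared across the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .distances import DistanceMatrix


@dataclass
class CorrelationReport:
    """Result of a correlation test, with enough metadata to reproduce it."""

    method: str
    coefficient: float
    p_value: float
    n: int
    n_perm: int | None = None
    seed: int | None = None
    tail: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _pearson_vec(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        raise ValueError("zero variance input")
    return float((x * y).sum() / denom)


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int | str = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> CorrelationReport:
    """Mantel test between two distance matrices over identical labels.

    The statistic is the Pearson correlation of the off-diagonal upper
    triangles; the null distribution comes from simultaneous row/column
    permutations of ``b``.  One-tailed (greater) by default, matching the
    directional hypotheses it backs; p uses the add-one rule and is never 0.
    ``n_perm="all"`` enumerates every permutation (tiny n only), with
    p = #{r_perm >= r_obs} / n! (the identity permutation keeps p > 0).
    """
    if a.labels != b.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if tail not in {"greater", "two-sided"}:
        raise ValueError(f"unknown tail {tail!r}")
    n = a.n
    iu = np.triu_indices(n, k=1)
    av = a.values[iu]
    r_obs = _pearson_vec(av, b.values[iu])
    B = b.values

    def exceeds(r_perm: float) -> bool:
        return r_perm >= r_obs if tail == "greater" else abs(r_perm) >= abs(r_obs)

    if n_perm == "all":
        from itertools import permutations
        from math import factorial

        count = sum(
            exceeds(_pearson_vec(av, B[np.ix_(p, p)][iu]))
            for p in permutations(range(n))
        )
        total = factorial(n)
        return CorrelationReport(
            "mantel", r_obs, count / total, n, n_perm=total, seed=seed, tail=tail
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        count += exceeds(_pearson_vec(av, B[np.ix_(p, p)][iu]))
    p_value = (count + 1) / (n_perm + 1)
    return CorrelationReport(
        "mantel", r_obs, float(p_value), n, n_perm=n_perm, seed=seed, tail=tail
    )


def correlate(x, y, method: str = "pearson") -> CorrelationReport:
    """Pearson or Spearman correlation with t-approximation p-values.

    Spearman mid-ranks ties; its p uses the same t transform on the rank
    correlation (scipy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationReport(method, float(r), float(p), len(x))
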