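"""Correlation-based feature subset selection (CFS) with best-first search.

CFS scores a candidate subset S of k features by the merit

    merit(S) = k * r_cf / sqrt(k + k*(k-1) * r_ff)

where ``r_cf`` is the mean absolute Pearson correlation between each feature
in S and the class (encoded {0, 1}) and ``r_ff`` the mean absolute pairwise
Pearson correlation among the features of S. The merit rewards features that
track the class while penalizing redundancy among them. Association is
measured with Pearson correlation on the continuous features directly (no
discretization dialect), so selected subsets are deterministic functions of
the matrix alone.

The search is forward best-first from the empty set: subsets are expanded by
single-feature additions, kept in a priority queue by merit, and the search
stops after ``stall_limit`` consecutive expansions without improving the
global best (with a hard cap on evaluated subsets as a safety bound).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .featurematrix import FeatureMatrix

MAX_EVALUATIONS = 10_000


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean()
    b0 = b - b.mean()
    den = np.sqrt(np.sum(a0 * a0) * np.sum(b0 * b0))
    if den == 0.0:
        return 0.0  # zero-variance feature: treated as uncorrelated
    return abs(float(np.sum(a0 * b0) / den))


def _correlation_tables(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """|corr(feature, class)| vector and |corr(feature, feature)| matrix."""
    y = fm.encoded_labels()
    k = len(fm.feature_names)
    rcf = np.array([_abs_corr(fm.X[:, j], y) for j in range(k)])
    rff = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rff[i, j] = rff[j, i] = _abs_corr(fm.X[:, i], fm.X[:, j])
    return rcf, rff


def _merit_from_tables(idx: tuple[int, ...], rcf: np.ndarray, rff: np.ndarray) -> float:
    k = len(idx)
    if k == 0:
        return 0.0
    ids = np.asarray(idx)
    mean_cf = float(rcf[ids].mean())
    if k == 1:
        return mean_cf
    sub = rff[np.ix_(ids, ids)]
    iu = np.triu_indices(k, 1)
    mean_ff = float(sub[iu].mean())
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_merit(subset: list[str], fm: FeatureMatrix) -> float:
    """CFS merit of a named subset, recomputed from scratch on the matrix."""
    fm.require_two_classes()
    if not subset:
        return 0.0
    missing = [n for n in subset if n not in fm.feature_names]
    if missing:
        raise ConfigError(f"unknown features {missing}")
    sub = fm.select_features(list(subset))
    rcf, rff = _correlation_tables(sub)
    return _merit_from_tables(tuple(range(len(subset))), rcf, rff)


@dataclass
class SelectionResult:
    """Outcome of a CFS search: the best subset, its merit and the search log."""

    selected: list[str]
    merit: float
    evaluated: int
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)


def cfs_select(fm: FeatureMatrix, stall_limit: int = 5) -> SelectionResult:
    """Best-first CFS over the matrix's features.

    Deterministic: ties in merit break toward the canonically earliest
    subset (feature order as listed in the matrix).
    """
    fm.require_two_classes()
    rcf, rff = _correlation_tables(fm)
    k = len(fm.feature_names)

    evaluated = 0
    trace: list[tuple[tuple[str, ...], float]] = []
    visited: set[tuple[int, ...]] = set()
    heap: list[tuple[float, tuple[int, ...]]] = []

    def evaluate(idx: tuple[int, ...]) -> float:
        nonlocal evaluated
        evaluated += 1
        m = _merit_from_tables(idx, rcf, rff)
        trace.append((tuple(fm.feature_names[i] for i in idx), m))
        return m

    best_idx: tuple[int, ...] = ()
    best_merit = 0.0
    heapq.heappush(heap, (0.0, ()))
    visited.add(())
    stall = 0
    while heap and stall < stall_limit and evaluated < MAX_EVALUATIONS:
        _, current = heapq.heappop(heap)
        improved = False
        for j in range(k):
            if j in current:
                continue
            child = tuple(sorted(current + (j,)))
            if child in visited:
                continue
            visited.add(child)
            m = evaluate(child)
            heapq.heappush(heap, (-m, child))
            if m > best_merit + 1e-12:
                best_merit = m
                best_idx = child
                improved = True
            if evaluated >= MAX_EVALUATIONS:
                break
        stall = 0 if improved else stall + 1
    if not best_idx:
        # degenerate matrix: fall back to the single best class-correlated feature
        best_idx = (int(np.argmax(rcf)),)
        best_merit = _merit_from_tables(best_idx, rcf, rff)
    selected = [fm.feature_names[i] for i in sorted(best_idx)]
    return SelectionResult(selected=selected, merit=best_merit, evaluated=evaluated, trace=trace)
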