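"""Optimal categorization of a single continuous exposure.

The central primitive is a search over contiguous partitions of the sorted
observations that minimizes a reciprocal-F loss: the partition that makes the
one-way ANOVA F statistic of (values ~ category) as large as possible.  Three
routes are provided:

* :func:`exhaustive_categorize` — enumerate every placement of ``k - 1``
  boundaries (testing oracle; capped at small ``n``),
* :func:`linear_search_step` / :func:`adaptive_categorize` — grow the
  partition one boundary at a time, keeping previously found boundaries fixed,
  with the number of categories chosen adaptively by the F-test p-value,
* :func:`quantile_categorize` — the fixed sample-quantile baseline.

Thresholds are stored as half-open upper bounds: category ``j`` holds the
values in ``(t[j-1], t[j]]``, so a value exactly at a threshold falls in the
lower category.  Candidate boundaries are only ever placed between distinct
adjacent sorted values (the stored threshold is their midpoint), hence tied
observations always share a category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .errors import (
    DegeneratePartitionError,
    InfeasibleKError,
    NoCandidateError,
)

__all__ = [
    "SearchConfig",
    "Categorization",
    "loss",
    "f_test_log_pvalue",
    "exhaustive_categorize",
    "iter_boundary_placements",
    "linear_search_step",
    "adaptive_categorize",
    "quantile_categorize",
    "apply_thresholds",
    "categorize_table",
]

#: hard cap on the exhaustive oracle's sample size
_EXHAUSTIVE_N_MAX = 30
#: hard cap on the number of enumerated boundary placements
_EXHAUSTIVE_COMBO_MAX = 5_000_000


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of the categorization search.

    Parameters
    ----------
    k_max : int
        Largest number of categories the adaptive search will consider.
    k_fixed : int, optional
        When set, adaptive selection is disabled and the linear search is run
        up to exactly ``k_fixed`` categories.
    min_category_fraction : float
        Minimum fraction of the sample each category must hold; boundaries
        that would create a smaller category are never candidates.
    """

    k_max: int = 10
    k_fixed: Optional[int] = None
    min_category_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.k_fixed is not None and not (2 <= self.k_fixed <= self.k_max):
            raise ValueError("k_fixed must satisfy 2 <= k_fixed <= k_max")
        if not (0.0 <= self.min_category_fraction < 0.5):
            raise ValueError("min_category_fraction must be in [0, 0.5)")


@dataclass(frozen=True, eq=False)
class Categorization:
    """A fitted partition of one exposure into ordered categories.

    ``thresholds`` has ``k - 1`` strictly increasing cut values; category
    ``j`` is ``(thresholds[j-1], thresholds[j]]``.  ``labels`` are integer
    category indices for the observations in their original order.
    ``loss`` is the reciprocal of ``f_statistic``; ``p_value`` is the
    survival probability of the F distribution with ``(k - 1, n - k)``
    degrees of freedom (``log_p_value`` is kept alongside because the
    p-value itself underflows for well-separated data).
    """

    thresholds: tuple[float, ...]
    k: int
    labels: np.ndarray
    counts: tuple[int, ...]
    loss: float
    f_statistic: float
    p_value: float
    log_p_value: float = float("nan")
    degenerate: bool = False

    @property
    def n(self) -> int:
        return int(self.labels.size)

    def to_dict(self) -> dict:
        """JSON-serializable summary (labels omitted)."""
        return {
            "k": self.k,
            "thresholds": [float(t) for t in self.thresholds],
            "counts": [int(c) for c in self.counts],
            "loss": float(self.loss),
            "f_statistic": float(self.f_statistic),
            "p_value": float(self.p_value),
            "degenerate": bool(self.degenerate),
        }


def f_test_log_pvalue(f_stat: float, df1: int, df2: int) -> float:
    """Natural log of the F-distribution survival function, usable far in
    the tail where the p-value underflows a double.

    The survival function is the regularized incomplete beta
    ``I_x(df2/2, df1/2)`` with ``x = df2 / (df2 + df1 * f)``; once that
    underflows we switch to its small-``x`` leading term
    ``x^a (1-x)^b / (a B(a, b))``.
    """
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not np.isfinite(f_stat):
        return float("-inf")
    if f_stat <= 0:
        return 0.0
    a = 0.5 * df2
    b = 0.5 * df1
    x = df2 / (df2 + df1 * f_stat)
    p = float(special.betainc(a, b, x))
    if p > 1e-250:
        return float(np.log(p))
    return float(a * np.log(x) + b * np.log1p(-x) - np.log(a) - special.betaln(a, b))


def loss(
    values: Sequence[float], labels: Sequence[int], k: int
) -> tuple[float, float, float, float]:
    """Reciprocal-F loss of an arbitrary labelling.

    Returns ``(loss, f_statistic, within, between)`` where ``within`` and
    ``between`` are the within- and between-category sums of squares and

    ``loss = (within / (n - k)) / (between / (k - 1)) = 1 / F``.

    Raises
    ------
    DegeneratePartitionError
        If all category means coincide (``between == 0``).
    ValueError
        If ``k < 2``, ``n <= k``, or some category in ``0..k-1`` is empty.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=np.int64)
    n = x.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if lab.size != n:
        raise ValueError("labels and values must have equal length")
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError("labels must lie in 0..k-1")
    counts = np.bincount(lab, minlength=k)
    if np.any(counts[:k] == 0):
        raise ValueError("every category 0..k-1 must be nonempty")
    grand = x.mean()
    means = np.bincount(lab, weights=x, minlength=k) / counts
    within = float(np.sum((x - means[lab]) ** 2))
    between = float(np.sum(counts * (means - grand) ** 2))
    if between <= 0.0:
        raise DegeneratePartitionError(
            "all category means are equal; the F statistic is undefined"
        )
    if within == 0.0:
        return 0.0, float("inf"), 0.0, between
    lo = (within / (n - k)) / (between / (k - 1))
    return lo, 1.0 / lo, within, between


class _SortedExposure:
    """Sorted view of one exposure with prefix sums for O(1) block sums of
    squares.  Values are centred before accumulating to avoid cancellation."""

    __slots__ = ("x", "n", "_s1", "_s2", "cand", "total_ss")

    def __init__(self, values: np.ndarray):
        x = np.asarray(values, dtype=float)
        if x.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if x.size < 2:
            raise ValueError("need at least 2 observations")
        if not np.all(np.isfinite(x)):
            raise ValueError("values must be finite")
        self.x = np.sort(x)
        self.n = int(x.size)
        xc = self.x - self.x.mean()
        self._s1 = np.concatenate(([0.0], np.cumsum(xc)))
        self._s2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
        # admissible boundary positions: between distinct adjacent values
        self.cand = np.flatnonzero(np.diff(self.x) > 0) + 1
        self.total_ss = float(self._block_ss_scalar(0, self.n))

    def _block_ss_scalar(self, a: int, b: int) -> float:
        s = self._s1[b] - self._s1[a]
        q = self._s2[b] - self._s2[a]
        return max(float(q - s * s / (b - a)), 0.0)

    def block_ss(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        s = self._s1[b] - self._s1[a]
        q = self._s2[b] - self._s2[a]
        return np.maximum(q - s * s / (b - a), 0.0)

    def within(self, edges: np.ndarray) -> float:
        return float(np.sum(self.block_ss(edges[:-1], edges[1:])))

    def best_split(self, edges: np.ndarray, min_count: int = 1) -> tuple[int, float]:
        """Best single additional boundary given the current ``edges``.

        Returns ``(position, delta_within)`` with ``delta_within <= 0``;
        raises :class:`NoCandidateError` if no admissible position exists.
        """
        inner = self.cand[~np.isin(self.cand, edges[1:-1], assume_unique=True)]
        if inner.size:
            bi = np.searchsorted(edges, inner, side="right") - 1
            a = edges[bi]
            b = edges[bi + 1]
            if min_count > 1:
                keep = (inner - a >= min_count) & (b - inner >= min_count)
                inner, a, b = inner[keep], a[keep], b[keep]
        if inner.size == 0:
            raise NoCandidateError(
                "no admissible boundary position remains "
                f"(min_count={min_count}, k={edges.size - 1})"
            )
        delta = self.block_ss(a, inner) + self.block_ss(inner, b) - self.block_ss(a, b)
        j = int(np.argmin(delta))
        return int(inner[j]), float(delta[j])

    def edges_from_thresholds(self, thresholds: Sequence[float]) -> np.ndarray:
        inner = np.searchsorted(self.x, np.asarray(thresholds, dtype=float), side="left")
        return np.concatenate(([0], inner, [self.n])).astype(np.intp)

    def build(self, original_values: np.ndarray, edges: np.ndarray) -> Categorization:
        """Assemble a :class:`Categorization` from sorted-position edges."""
        edges = np.asarray(edges, dtype=np.intp)
        k = edges.size - 1
        n = self.n
        thresholds = tuple(
            float((self.x[e - 1] + self.x[e]) / 2.0) for e in edges[1:-1]
        )
        if k == 1:
            labels = np.zeros(n, dtype=np.int64)
        else:
            labels = np.searchsorted(
                np.asarray(thresholds), original_values, side="left"
            ).astype(np.int64)
        counts = tuple(int(c) for c in np.diff(edges))
        if k == 1:
            return Categorization(
                thresholds=(),
                k=1,
                labels=labels,
                counts=counts,
                loss=float("nan"),
                f_statistic=float("nan"),
                p_value=float("nan"),
                log_p_value=float("nan"),
            )
        within = self.within(edges)
        between = max(self.total_ss - within, 0.0)
        if between <= 0.0:
            raise DegeneratePartitionError(
                "all category means are equal; the F statistic is undefined"
            )
        if within == 0.0:
            lo, f, logp = 0.0, float("inf"), float("-inf")
        else:
            lo = (within / (n - k)) / (between / (k - 1))
            f = 1.0 / lo
            logp = f_test_log_pvalue(f, k - 1, n - k)
        return Categorization(
            thresholds=thresholds,
            k=k,
            labels=labels,
            counts=counts,
            loss=lo,
            f_statistic=f,
            p_value=float(np.exp(logp)),
            log_p_value=logp,
        )


def apply_thresholds(values: Sequence[float], thresholds: Sequence[float]) -> np.ndarray:
    """Label values by pre-computed thresholds (half-open upper bounds)."""
    return np.searchsorted(
        np.asarray(thresholds, dtype=float), np.asarray(values, dtype=float), side="left"
    ).astype(np.int64)


def iter_boundary_placements(n: int, k: int) -> Iterator[tuple[int, ...]]:
    """All placements of ``k - 1`` boundaries among the ``n - 1`` gaps of a
    sorted sample, ignoring ties; there are ``C(n-1, k-1)`` of them."""
    return combinations(range(1, n), k - 1)


def exhaustive_categorize(values: Sequence[float], k: int) -> Categorization:
    """Globally optimal ``k``-category partition by full enumeration.

    Exists as a testing oracle: every one of the ``C(n-1, k-1)`` boundary
    placements is visited (placements that would split tied values are
    discarded without evaluation).  Capped at ``n <= 30``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n > _EXHAUSTIVE_N_MAX:
        raise ValueError(f"exhaustive search is limited to n <= {_EXHAUSTIVE_N_MAX}")
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise InfeasibleKError(f"need n > k (n={n}, k={k})")
    if math.comb(n - 1, k - 1) > _EXHAUSTIVE_COMBO_MAX:
        raise ValueError("too many boundary placements to enumerate")
    se = _SortedExposure(x)
    if se.cand.size + 1 < k:
        raise InfeasibleKError(
            f"only {se.cand.size + 1} distinct values; cannot form {k} categories"
        )
    admissible = np.zeros(n, dtype=bool)
    admissible[se.cand] = True
    best_within = np.inf
    best_edges: Optional[np.ndarray] = None
    for combo in iter_boundary_placements(n, k):
        if not all(admissible[p] for p in combo):
            continue
        edges = np.concatenate(([0], combo, [n])).astype(np.intp)
        w = se.within(edges)
        if w < best_within:
            best_within = w
            best_edges = edges
    assert best_edges is not None  # guaranteed by the distinct-value check
    return se.build(x, best_edges)


def _min_count(n: int, fraction: float) -> int:
    return max(1, int(math.ceil(fraction * n))) if fraction > 0 else 1


def linear_search_step(
    values: Sequence[float],
    current: Categorization,
    min_category_fraction: float = 0.0,
) -> Categorization:
    """Add the single best boundary to ``current`` (thresholds kept fixed).

    All admissible positions inside every existing category are scanned in
    one vectorized pass; the position minimizing the new loss wins.
    """
    x = np.asarray(values, dtype=float)
    se = _SortedExposure(x)
    if se.n - (current.k + 1) < 1:
        raise NoCandidateError("too few observations to support another category")
    edges = se.edges_from_thresholds(current.thresholds)
    pos, _ = se.best_split(edges, _min_count(se.n, min_category_fraction))
    new_edges = np.sort(np.append(edges, pos))
    return se.build(x, new_edges)


def _single_category(x: np.ndarray, degenerate: bool) -> Categorization:
    return Categorization(
        thresholds=(),
        k=1,
        labels=np.zeros(x.size, dtype=np.int64),
        counts=(int(x.size),),
        loss=float("nan"),
        f_statistic=float("nan"),
        p_value=float("nan"),
        log_p_value=float("nan"),
        degenerate=degenerate,
    )


def adaptive_categorize(
    values: Sequence[float], config: SearchConfig | None = None
) -> Categorization:
    """Categorize one exposure by the incremental F-statistic search.

    With ``config.k_fixed`` set, boundaries are added one at a time up to
    exactly ``k_fixed`` categories.  Otherwise ``k`` starts at 2 and grows
    while the F-test p-value (df ``(k-1, n-k)``) keeps strictly decreasing;
    the first non-decrease returns the previous partition.  The search also
    ends at ``k_max``, when the within-category variation hits zero (the F
    statistic is unbounded there), or when no admissible boundary remains.

    A constant input returns a flagged single-category result rather than
    raising, so batch runs over many exposures stay robust.
    """
    cfg = config or SearchConfig()
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    se = _SortedExposure(x)
    if se.cand.size == 0:  # constant input: no F test possible
        return _single_category(x, degenerate=True)
    min_count = _min_count(se.n, cfg.min_category_fraction)
    n = se.n

    if cfg.k_fixed is not None:
        k_target = cfg.k_fixed
        if k_target > min(n - 1, se.cand.size + 1):
            raise InfeasibleKError(
                f"cannot form {k_target} categories from n={n} "
                f"({se.cand.size + 1} distinct values)"
            )
        edges = np.array([0, n], dtype=np.intp)
        for _ in range(2, k_target + 1):
            pos, _d = se.best_split(edges, min_count)
            edges = np.sort(np.append(edges, pos))
        return se.build(x, edges)

    k_max = min(cfg.k_max, n - 1, se.cand.size + 1)
    if k_max < 2:
        return _single_category(x, degenerate=False)
    edges = np.array([0, n], dtype=np.intp)
    pos, _d = se.best_split(edges, min_count)  # NoCandidateError propagates:
    # a non-constant input can only fail here through the size constraint
    edges = np.sort(np.append(edges, pos))
    current = se.build(x, edges)
    if current.loss == 0.0:
        return current
    k = 2
    while k < k_max:
        try:
            pos, _d = se.best_split(edges, min_count)
        except NoCandidateError:
            break
        new_edges = np.sort(np.append(edges, pos))
        candidate = se.build(x, new_edges)
        if candidate.loss == 0.0:  # perfect fit; F is unbounded from here on
            return candidate
        if candidate.log_p_value >= current.log_p_value:
            return current
        edges, current, k = new_edges, candidate, k + 1
    return current


def quantile_categorize(values: Sequence[float], q: int) -> Categorization:
    """Fixed sample-quantile categorization (cutoffs at ``i/q``).

    Tied values share a label; quantile cutoffs that coincide are collapsed,
    so fewer than ``q`` categories can result on heavily tied data.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if q < 2:
        raise ValueError("q must be >= 2")
    if n < q:
        raise ValueError(f"need n >= q (n={n}, q={q})")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.unique(x).size < q:
        raise InfeasibleKError(
            f"only {np.unique(x).size} distinct values; cannot form {q} groups"
        )
    cuts = np.quantile(x, np.arange(1, q) / q)
    raw_labels = np.searchsorted(cuts, x, side="left")
    occupied = np.unique(raw_labels)
    labels = np.searchsorted(occupied, raw_labels).astype(np.int64)
    k = int(occupied.size)
    if k < 2:
        raise InfeasibleKError("quantile cutoffs collapse to a single category")
    # boundary between consecutive occupied groups: the last cut below the
    # upper group reproduces the same labels via searchsorted(side='left')
    thresholds = tuple(float(cuts[occupied[i + 1] - 1]) for i in range(k - 1))
    counts = tuple(int(c) for c in np.bincount(labels, minlength=k))
    lo, f, within, _between = loss(x, labels, k)
    logp = f_test_log_pvalue(f, k - 1, n - k)
    return Categorization(
        thresholds=thresholds,
        k=k,
        labels=labels,
        counts=counts,
        loss=lo,
        f_statistic=f,
        p_value=float(np.exp(logp)),
        log_p_value=logp,
    )


def categorize_table(
    table: pd.DataFrame,
    config: SearchConfig | None = None,
    columns: Optional[Iterable[str]] = None,
) -> dict[str, Categorization]:
    """Run :func:`adaptive_categorize` on every (or selected) column of an
    exposure table; returns a mapping column -> Categorization."""
    cols = list(columns) if columns is not None else list(table.columns)
    out: dict[str, Categorization] = {}
    for c in cols:
        vals = pd.to_numeric(table[c], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(f"column {c!r} has a non-numeric value at row {bad}")
        out[c] = adaptive_categorize(vals, config)
    return out
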