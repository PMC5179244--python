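"""Standardized pairwise overlap statistic on presence-absence matrices.

A binary species x site matrix is read as a bipartite network: species and
sites are nodes, an entry of 1 is an edge. For a pair of nodes on the same
axis (two species, or two sites) with degrees ``d_i`` and ``d_j`` out of
``n`` possible neighbors, the observed shared-neighbor count ``S`` is
compared with its expectation ``P`` under random placement of the two
neighbor sets, and the deviation is rescaled by the maximum-magnitude
feasible deviation of the same sign so that the score lies in [-1, 1]:

    score = (S - P) / (min(d_i, d_j) - P)            if S > P
    score = (S - P) / (P - max(0, d_i + d_j - n))    if S < P
    score = 0                                        if S = P

+1 means the smaller neighbor set is contained in the larger (perfect
nestedness); -1 means the sets overlap as little as the degrees allow
(complete segregation). The matrix-level statistic ``nbar`` is the mean of
all pair scores, the population standard deviation of the same scores is the
modularity, and a one-sample Z test of the mean against zero gives
significance (Z > 2 ~ p < 0.05, one relevant tail).

``P`` follows the hypergeometric overlap law: placing ``d_i`` and ``d_j``
neighbors uniformly at random among ``n``, the shared count ``S`` is
hypergeometric, and

    P = sum_k k * C(d_j, k) C(n - d_j, d_i - k) / C(n, d_i) = d_i d_j / n.

Both the explicit summation (evaluated in log-gamma space) and the closed
form are provided; the test suite proves them equal, and matrix-level
scoring uses the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy.special import gammaln

AxisMode = Literal["rows", "columns", "both"]

__all__ = [
    "PresenceAbsenceMatrix",
    "PairScore",
    "MatrixStructureResult",
    "expected_shared",
    "expected_shared_closed_form",
    "omega",
    "pair_score",
    "pair_scores",
    "pair_score_details",
    "matrix_structure",
    "z_test",
]


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary species x site incidence matrix with labelled axes.

    Parameters
    ----------
    entries : ndarray of shape (n_species, n_sites)
        Strictly 0/1 values; rows are species, columns are sites.
    row_labels, col_labels : sequence of str
        Unique identifiers for species and sites.
    """

    entries: np.ndarray
    row_labels: tuple = field(default=None)
    col_labels: tuple = field(default=None)

    def __post_init__(self):
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("entries must contain only 0 and 1")
        object.__setattr__(self, "entries", entries.astype(np.int8))
        rows = self.row_labels
        cols = self.col_labels
        if rows is None:
            rows = tuple(f"sp{i}" for i in range(entries.shape[0]))
        if cols is None:
            cols = tuple(f"site{j}" for j in range(entries.shape[1]))
        rows, cols = tuple(map(str, rows)), tuple(map(str, cols))
        if len(rows) != entries.shape[0] or len(cols) != entries.shape[1]:
            raise ValueError("label lengths must match matrix shape")
        if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
            raise ValueError("labels must be unique within each axis")
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)

    @property
    def shape(self) -> tuple:
        return self.entries.shape

    def prune(self) -> "PresenceAbsenceMatrix":
        """Drop empty rows and columns (degree-0 nodes carry no information)."""
        keep_r = self.entries.sum(axis=1) > 0
        keep_c = self.entries.sum(axis=0) > 0
        return PresenceAbsenceMatrix(
            self.entries[np.ix_(keep_r, keep_c)],
            tuple(l for l, k in zip(self.row_labels, keep_r) if k),
            tuple(l for l, k in zip(self.col_labels, keep_c) if k),
        )


@dataclass(frozen=True)
class PairScore:
    """One scored node pair with all its components.

    ``score`` is NaN when the pair is degenerate (the feasible range of S is
    a single point, which happens exactly when max(d_i, d_j) = n); such
    pairs are excluded from matrix-level averaging.
    """

    i: int
    j: int
    S: int
    P: float
    d_i: int
    d_j: int
    omega: float
    score: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.score)


@dataclass(frozen=True)
class MatrixStructureResult:
    """Matrix-level structure: mean pair score, its SD, and the Z test.

    ``nbar`` in [-1, 1] measures nestedness (+) versus segregation (-);
    ``modularity`` in [0, 1] is the population SD of the pair scores, high
    when internally-similar but mutually-dissimilar clusters coexist. All
    three are NaN when fewer than two non-degenerate pairs exist; ``z`` is
    additionally NaN when the scores have zero variance.
    """

    nbar: float
    modularity: float
    z: float
    n_pairs: int
    axis_mode: AxisMode

    @property
    def computable(self) -> bool:
        return self.n_pairs >= 2


def _validate_degrees(n: int, d_i: int, d_j: int) -> None:
    for name, v in (("n", n), ("d_i", d_i), ("d_j", d_j)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    if d_i > n or d_j > n:
        raise ValueError(f"degrees must not exceed n: n={n}, d_i={d_i}, d_j={d_j}")


def expected_shared(n: int, d_i: int, d_j: int) -> float:
    """Expected shared-neighbor count under random placement.

    Evaluates the hypergeometric summation
    ``sum_k k * C(n,k) C(n-k, d_j-k) C(n-d_j, d_i-k) / (C(n,d_j) C(n,d_i))``
    in log-gamma space (stable for n up to a few hundred). Equal to
    ``d_i * d_j / n``; see :func:`expected_shared_closed_form`.
    """
    _validate_degrees(n, d_i, d_j)
    smin = max(0, d_i + d_j - n)
    smax = min(d_i, d_j)
    k = np.arange(max(smin, 1), smax + 1, dtype=float)
    if k.size == 0:
        return 0.0

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    log_terms = (
        logC(n, k)
        + logC(n - k, d_j - k)
        + logC(n - d_j, d_i - k)
        - logC(n, d_j)
        - logC(n, d_i)
    )
    return float(np.sum(np.exp(log_terms) * k))


def expected_shared_closed_form(n: int, d_i: int, d_j: int) -> float:
    """Closed form of the expected shared-neighbor count: d_i * d_j / n."""
    _validate_degrees(n, d_i, d_j)
    return d_i * d_j / n


def _feasible_range(n: int, d_i: int, d_j: int) -> tuple:
    return max(0, d_i + d_j - n), min(d_i, d_j)


def omega(n: int, d_i: int, d_j: int, sign: Literal["positive", "negative"]) -> float:
    """Standardization magnitude: the maximum feasible |deviation| / min degree.

    For positive deviations this is ``(min(d) - P) / min(d)``; for negative
    ones ``(P - max(0, d_i + d_j - n)) / min(d)``. Returns NaN for degenerate
    pairs (feasible S range collapses to one point, i.e. max degree = n),
    which are excluded from averaging rather than scored.
    """
    _validate_degrees(n, d_i, d_j)
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    smin, smax = _feasible_range(n, d_i, d_j)
    if smin == smax:
        return float("nan")
    p = expected_shared_closed_form(n, d_i, d_j)
    mind = min(d_i, d_j)
    return (mind - p) / mind if sign == "positive" else (p - smin) / mind


def pair_score(S: int, n: int, d_i: int, d_j: int) -> float:
    """Standardized overlap score of one node pair, in [-1, 1].

    ``(S - P) / min(d)`` rescaled by the omega of matching sign, so that the
    maximal feasible overlap scores exactly +1, the minimal exactly -1, and
    S = P scores 0. NaN for degenerate pairs. Raises ``ValueError`` when S
    is outside its feasible range.
    """
    _validate_degrees(n, d_i, d_j)
    smin, smax = _feasible_range(n, d_i, d_j)
    if int(S) != S or not smin <= S <= smax:
        raise ValueError(
            f"S={S!r} infeasible for n={n}, d_i={d_i}, d_j={d_j} "
            f"(feasible range [{smin}, {smax}])"
        )
    if smin == smax:
        return float("nan")
    p = expected_shared_closed_form(n, d_i, d_j)
    dev = S - p
    if dev > 0:
        return dev / (min(d_i, d_j) - p)
    if dev < 0:
        return dev / (p - smin)
    return 0.0


def _axis_pair_arrays(entries: np.ndarray, axis: str):
    """Vectorized (i, j, S, d_i, d_j, n) for all pairs on one axis."""
    a = entries if axis == "rows" else entries.T
    if a.shape[0] < 2:
        raise ValueError(f"need at least 2 nodes on axis {axis!r}, got {a.shape[0]}")
    n = a.shape[1]
    shared = (a @ a.T).astype(np.int64)
    deg = a.sum(axis=1).astype(np.int64)
    ii, jj = np.triu_indices(a.shape[0], k=1)
    return ii, jj, shared[ii, jj], deg[ii], deg[jj], n


def _score_arrays(S, d_i, d_j, n):
    """Scores for arrays of pair counts; NaN marks degenerate pairs."""
    S = np.asarray(S, dtype=float)
    d_i = np.asarray(d_i, dtype=float)
    d_j = np.asarray(d_j, dtype=float)
    mind = np.minimum(d_i, d_j)
    smin = np.maximum(0.0, d_i + d_j - n)
    p = d_i * d_j / n
    dev = S - p
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = dev / (mind - p)
        neg = dev / (p - smin)
    out = np.where(dev > 0, pos, np.where(dev < 0, neg, 0.0))
    out = np.where(mind == smin, np.nan, out)
    return out


def pair_scores(m: PresenceAbsenceMatrix, axis: Literal["rows", "columns"]) -> np.ndarray:
    """All pair scores on one axis, NaN marking degenerate pairs."""
    ii, jj, S, d_i, d_j, n = _axis_pair_arrays(m.entries, axis)
    return _score_arrays(S, d_i, d_j, n)


def pair_score_details(
    m: PresenceAbsenceMatrix, axis: Literal["rows", "columns"]
) -> Iterator[PairScore]:
    """Yield every pair on one axis with its full component breakdown."""
    ii, jj, S, d_i, d_j, n = _axis_pair_arrays(m.entries, axis)
    scores = _score_arrays(S, d_i, d_j, n)
    for k in range(len(ii)):
        s, di, dj = int(S[k]), int(d_i[k]), int(d_j[k])
        p = expected_shared_closed_form(n, di, dj)
        sign = "positive" if s >= p else "negative"
        yield PairScore(
            i=int(ii[k]), j=int(jj[k]), S=s, P=p, d_i=di, d_j=dj,
            omega=omega(n, di, dj, sign), score=float(scores[k]),
        )


def _pooled_scores(m: PresenceAbsenceMatrix, axis_mode: AxisMode) -> np.ndarray:
    if axis_mode == "rows":
        parts = [pair_scores(m, "rows")]
    elif axis_mode == "columns":
        parts = [pair_scores(m, "columns")]
    elif axis_mode == "both":
        parts = [pair_scores(m, "rows"), pair_scores(m, "columns")]
    else:
        raise ValueError(f"axis_mode must be rows|columns|both, got {axis_mode!r}")
    pooled = np.concatenate(parts)
    return pooled[np.isfinite(pooled)]


def z_test(scores: Sequence[float]) -> float:
    """One-sample Z of the mean pair score against zero.

    Z = mean / (sd / sqrt(n)) with the population SD. NaN when the scores
    have no variance (the test is then undefined, not significant).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("z_test requires at least one score")
    sd = float(scores.std())  # population SD, ddof=0
    if sd == 0.0:
        return float("nan")
    return float(scores.mean() / (sd / np.sqrt(scores.size)))


def matrix_structure(
    m: PresenceAbsenceMatrix, axis_mode: AxisMode = "both"
) -> MatrixStructureResult:
    """Matrix-level nestedness/segregation mean, modularity SD, and Z.

    By default pools species pairs (row axis) and site pairs (column axis),
    since pair overlap reads equally as distributional overlap of two
    species and compositional overlap of two sites; single-axis modes are
    available. Degenerate pairs are excluded. With fewer than two scorable
    pairs the result is flagged non-computable (NaN statistics, n_pairs as
    found).
    """
    scores = _pooled_scores(m, axis_mode)
    if scores.size < 2:
        return MatrixStructureResult(
            nbar=float("nan"), modularity=float("nan"), z=float("nan"),
            n_pairs=int(scores.size), axis_mode=axis_mode,
        )
    return MatrixStructureResult(
        nbar=float(scores.mean()),
        modularity=float(scores.std()),
        z=z_test(scores),
        n_pairs=int(scores.size),
        axis_mode=axis_mode,
    )
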