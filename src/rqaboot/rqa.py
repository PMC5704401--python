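"""Recurrence matrices, line-length distributions and the RR/DET/LAM measures.

The recurrence matrix marks pairs of embedded states closer than a radius ε,

    R_ij = Θ(ε − ‖S_i − S_j‖),

by default under the maximum norm. From it we extract the distributions of
maximal diagonal and vertical line lengths and the standard complexity
measures:

    RR  = (recurrence points) / (matrix cells),
    DET = Σ_{l≥l_min} l·P(l) / Σ_{l≥1} l·P(l)   (diagonal lines),
    LAM = Σ_{v≥v_min} v·P(v) / Σ_{v≥1} v·P(v)   (vertical lines).

A Theiler window of half-width ``theiler`` masks the band |i−j| < theiler
around the line of identity from every statistic (default 1: the trivially
recurrent main diagonal is excluded; 0 reproduces the literal definition).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "RecurrenceResult",
    "LineDistribution",
    "RQAMeasures",
    "distance_matrix",
    "threshold_for_target_rr",
    "recurrence_matrix",
    "diagonal_line_distribution",
    "vertical_line_distribution",
    "rqa_measures",
    "write_pgm",
]

_NORMS = {"max": "chebyshev", "euclidean": "euclidean", "manhattan": "cityblock"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise state distances under a named norm (max | euclidean | manhattan)."""

    entries: np.ndarray
    norm: str

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class RecurrenceResult:
    """Thresholded recurrence matrix with its radius, norm and Theiler window.

    ``matrix[i, j]`` is True iff distance(i, j) <= epsilon; cells with
    |i − j| < theiler are masked from all downstream statistics (they stay in
    the stored matrix so the literal Θ(ε − d_ij) structure is preserved).
    """

    matrix: np.ndarray
    epsilon: float
    theiler: int
    norm: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def unmasked(self) -> np.ndarray:
        """Boolean mask of cells outside the Theiler band."""
        n = self.n
        i, j = np.indices((n, n), sparse=True)
        return np.abs(i - j) >= self.theiler

    @property
    def n_unmasked(self) -> int:
        n, w = self.n, self.theiler
        if w == 0:
            return n * n
        band = n + 2 * sum(n - k for k in range(1, w))
        return n * n - band

    def recurrence_points(self) -> int:
        """Recurrence points in the unmasked region."""
        return int(np.count_nonzero(self.matrix & self.unmasked()))


@dataclass(frozen=True)
class LineDistribution:
    """Histogram of maximal line lengths (lengths >= 1, singletons included).

    ``kind`` is "diagonal" (counted once per triangle of the symmetric matrix)
    or "vertical" (counted over every column). ``n_cells`` records the number
    of unmasked cells of the region the lines were extracted from, so that
    Σ l·counts(l) equals the recurrence points of that same region.
    """

    kind: str
    counts: dict[int, int]
    n_cells: int

    def __post_init__(self) -> None:
        if self.kind not in ("diagonal", "vertical"):
            raise ValueError(f"unknown line kind {self.kind!r}")
        if any(length < 1 or c < 0 for length, c in self.counts.items()):
            raise ValueError("line lengths must be >= 1 and counts >= 0")

    @property
    def total_structures(self) -> int:
        return sum(self.counts.values())

    @property
    def total_points(self) -> int:
        return sum(l * c for l, c in self.counts.items())

    def fraction_at_least(self, lmin: int) -> float:
        """Σ_{l≥lmin} l·P(l) / Σ_{l≥1} l·P(l); 0 when there are no points."""
        denom = self.total_points
        if denom == 0:
            return 0.0
        num = sum(l * c for l, c in self.counts.items() if l >= lmin)
        return num / denom


@dataclass(frozen=True)
class RQAMeasures:
    rr: float
    det: float
    lam: float
    lmin: int
    vmin: int
    epsilon: float


def distance_matrix(states: np.ndarray, norm: str = "max") -> DistanceMatrix:
    """Exact pairwise distance matrix of a state trajectory (rows = states)."""
    if norm not in _NORMS:
        raise ValueError(f"unknown norm {norm!r}; supported: {sorted(_NORMS)}")
    states = np.asarray(states, dtype=float)
    if states.ndim == 1:
        states = states[:, None]
    if states.shape[0] < 2:
        raise ValueError("need at least 2 states")
    d = squareform(pdist(states, metric=_NORMS[norm]))
    return DistanceMatrix(entries=d, norm=norm)


def _upper_distances(dm: DistanceMatrix, theiler: int) -> np.ndarray:
    """Distances of the unmasked strict-upper-triangle cells (offset >= max(theiler, 1))."""
    n = dm.n
    iu, ju = np.triu_indices(n, k=max(theiler, 1))
    return dm.entries[iu, ju]


def threshold_for_target_rr(
    dm: DistanceMatrix, target_rr: float, theiler: int = 1
) -> tuple[float, float]:
    """Radius ε giving a recurrence rate closest to ``target_rr``.

    ε is an exact order statistic of the unmasked distances: since the matrix
    is symmetric, off-diagonal cells recur in pairs, so the k-th smallest
    per-triangle distance is chosen with k = round(target·n_offdiag/2). For
    generic (distinct) distances the achieved RR — returned alongside ε —
    differs from the target by at most one cell in n_unmasked. Delay-embedded
    states can produce exactly tied maximum-norm distances; the count then
    moves in tie-block steps and the radius lands on whichever side of the
    block is closest to the target, so the achieved RR is always the closest
    achievable one.
    """
    if not 0 < target_rr < 1:
        raise ValueError("target_rr must lie in (0, 1)")
    upper = _upper_distances(dm, theiler)
    if upper.size == 0:
        raise ValueError("Theiler window leaves no unmasked cells")
    if np.all(upper == upper[0]):
        raise ValueError("all unmasked distances identical: RR not tunable")
    n = dm.n
    diag_extra = n if theiler == 0 else 0  # zero diagonal always recurs
    if theiler == 0:
        n_unmasked = n * n
    else:
        n_unmasked = n * n - (n + 2 * sum(n - t for t in range(1, theiler)))
    k = int(round((target_rr * n_unmasked - diag_extra) / 2))
    k = min(max(k, 1), upper.size)
    upper.sort()
    eps = float(upper[k - 1])
    # distances of shifted state pairs can coincide exactly under the max
    # norm, so the count can only jump in tie-block steps; pick the side of
    # the block whose achieved RR is closest to the target
    c_hi = int(np.searchsorted(upper, eps, side="right"))
    c_lo = int(np.searchsorted(upper, eps, side="left"))
    target_half = (target_rr * n_unmasked - diag_extra) / 2.0
    if c_lo > 0 and abs(c_lo - target_half) < abs(c_hi - target_half):
        eps = float(upper[c_lo - 1])
        count = int(np.searchsorted(upper, eps, side="right"))
    else:
        count = c_hi
    achieved = (2 * count + diag_extra) / n_unmasked
    return eps, achieved


def recurrence_matrix(
    dm: DistanceMatrix, epsilon: float, theiler: int = 1
) -> RecurrenceResult:
    """Threshold a distance matrix at radius ε."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if theiler < 0:
        raise ValueError("theiler must be >= 0")
    return RecurrenceResult(
        matrix=dm.entries <= epsilon, epsilon=float(epsilon), theiler=theiler, norm=dm.norm
    )


def _run_lengths(flat: np.ndarray) -> Counter:
    """Counts of maximal runs of True in a 1-D boolean array."""
    if flat.size == 0:
        return Counter()
    padded = np.concatenate(([False], flat, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    lengths = ends - starts
    return Counter(lengths.tolist())


def diagonal_line_distribution(rec: RecurrenceResult) -> LineDistribution:
    """Maximal diagonal runs, counted once per triangle of the symmetric matrix.

    Offsets from max(theiler, 1) to n−1 are scanned (with theiler = 0 the main
    diagonal is included as one run of length n per triangle convention — it is
    scanned once, as offset 0).
    """
    n = rec.n
    m = rec.matrix
    first = max(rec.theiler, 1)
    pieces = []
    if rec.theiler == 0:
        pieces.append(np.concatenate((m.diagonal(0), [False])))
    for k in range(first, n):
        pieces.append(np.concatenate((m.diagonal(k), [False])))
    flat = np.concatenate(pieces) if pieces else np.array([], dtype=bool)
    counts = _run_lengths(flat)
    if rec.theiler == 0:
        n_cells = n + (rec.n_unmasked - n) // 2
    else:
        n_cells = rec.n_unmasked // 2
    return LineDistribution(kind="diagonal", counts=dict(counts), n_cells=n_cells)


def vertical_line_distribution(rec: RecurrenceResult) -> LineDistribution:
    """Maximal vertical runs down every column; Theiler-masked cells break runs."""
    work = rec.matrix & rec.unmasked()
    padded = np.vstack([work, np.zeros((1, rec.n), dtype=bool)])
    flat = padded.T.reshape(-1)
    counts = _run_lengths(flat)
    return LineDistribution(kind="vertical", counts=dict(counts), n_cells=rec.n_unmasked)


def rqa_measures(rec: RecurrenceResult, lmin: int = 2, vmin: int = 2) -> RQAMeasures:
    """RR, DET and LAM of a recurrence matrix.

    Zero-recurrence matrices yield RR = DET = LAM = 0 by convention (with a
    warning) rather than NaN.
    """
    if lmin < 1 or vmin < 1:
        raise ValueError("lmin and vmin must be >= 1")
    points = rec.recurrence_points()
    rr = points / rec.n_unmasked
    if points == 0:
        warnings.warn("recurrence matrix has no recurrence points; DET = LAM = 0")
        return RQAMeasures(rr=0.0, det=0.0, lam=0.0, lmin=lmin, vmin=vmin, epsilon=rec.epsilon)
    det = diagonal_line_distribution(rec).fraction_at_least(lmin)
    lam = vertical_line_distribution(rec).fraction_at_least(vmin)
    return RQAMeasures(rr=rr, det=det, lam=lam, lmin=lmin, vmin=vmin, epsilon=rec.epsilon)


def write_pgm(rec: RecurrenceResult, path) -> None:
    """Export the recurrence matrix as a plain-text PBM (P1) image.

    Row 0 of the matrix is drawn at the bottom so time runs up and right, the
    usual recurrence-plot orientation.
    """
    m = rec.matrix.astype(np.uint8)[::-1]
    with open(path, "w") as fh:
        fh.write("P1\n")
        fh.write(f"{rec.n} {rec.n}\n")
        for row in m:
            fh.write(" ".join("1" if x else "0" for x in row) + "\n")
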