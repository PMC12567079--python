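"""Recurrence quantification analysis for display-height time series.

The consistency of a cartwheel display is quantified on the recurrence
matrix of the edge male's vertical-position series: two time points ``i``
and ``j`` recur when ``|y_i - y_j| <= r`` for a tolerance radius ``r``.
From the binary matrix we derive

* recurrence rate (RR) — percentage of recurrent cells; inverse height
  variability,
* determinism (DET) — share of recurrent points on diagonal lines;
  predictability of future motion from past motion,
* laminarity (LAM) — share of recurrent points on vertical lines;
  proportion of stationary episodes,
* microstate entropy (MCEntr) — Shannon entropy (nats) of randomly
  sampled 2x2 sub-blocks; sensitive to subtle dynamical change,

and the radius itself, selected by maximizing microstate entropy over a
candidate grid (maximum-entropy principle).

No phase-space embedding is applied: the analysis operates directly on the
scalar height series (embedding dimension 1). An optional ``(m, tau)``
time-delay embedding hook is provided for experimentation but is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RecurrenceMatrix",
    "RQAMetrics",
    "LineHistogram",
    "recurrence_matrix",
    "recurrence_rate",
    "line_histogram",
    "determinism",
    "laminarity",
    "microstate_entropy",
    "select_radius",
    "rqa_summary",
    "embed",
]

#: number of evenly spaced radius candidates spanning the series range
DEFAULT_N_CANDIDATES = 50
#: Monte-Carlo budget for microstate sampling
DEFAULT_N_SAMPLES = 10_000
#: microstate block edge length
DEFAULT_Q = 2


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary, symmetric recurrence matrix with unit main diagonal."""

    R: np.ndarray
    radius: float

    @property
    def n(self) -> int:
        return self.R.shape[0]

    def __post_init__(self) -> None:
        R = np.asarray(self.R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("recurrence matrix must be square")


@dataclass(frozen=True)
class RQAMetrics:
    """The five consistency metrics of one display."""

    rr: float  # percent
    det: float  # percent
    lam: float  # percent
    mcentr: float  # nats
    radius: float  # series units (px)
    n_samples_mc: int = DEFAULT_N_SAMPLES
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "rr": self.rr,
            "det": self.det,
            "lam": self.lam,
            "mcentr": self.mcentr,
            "radius": self.radius,
            "n_samples_mc": self.n_samples_mc,
            "seed": self.seed,
        }


@dataclass
class LineHistogram:
    """Counts of maximal line lengths off the main diagonal."""

    orientation: Literal["diagonal", "vertical"]
    counts: dict[int, int] = field(default_factory=dict)

    def total_points(self) -> int:
        """Recurrent points covered by maximal lines: sum of l * count."""
        return sum(l * c for l, c in self.counts.items())

    def points_at_least(self, l_min: int) -> int:
        return sum(l * c for l, c in self.counts.items() if l >= l_min)


def embed(y: np.ndarray, m: int = 1, tau: int = 1) -> np.ndarray:
    """Time-delay embedding hook; ``m=1`` returns the series unchanged."""
    y = np.asarray(y, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("embedding dimension and delay must be >= 1")
    if m == 1:
        return y[:, None]
    n = y.size - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short for requested embedding")
    return np.column_stack([y[i * tau : i * tau + n] for i in range(m)])


def recurrence_matrix(y: Sequence[float] | np.ndarray, radius: float) -> RecurrenceMatrix:
    """Build the recurrence matrix ``R[i, j] = 1 iff |y_i - y_j| <= radius``.

    The comparison is inclusive, so ``radius=0`` reproduces exact-match
    recurrence. The result is symmetric with a unit main diagonal by
    construction.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("cannot build a recurrence matrix from an empty series")
    if y.size < 2:
        raise ValueError("series must have length >= 2")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    R = (np.abs(y[:, None] - y[None, :]) <= radius).astype(np.uint8)
    return RecurrenceMatrix(R=R, radius=float(radius))


def _as_matrix(R: RecurrenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(R, RecurrenceMatrix):
        return np.asarray(R.R, dtype=np.uint8)
    R = np.asarray(R, dtype=np.uint8)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("recurrence matrix must be square")
    return R


def recurrence_rate(R: RecurrenceMatrix | np.ndarray) -> float:
    """Percentage of recurrent cells, main diagonal included."""
    M = _as_matrix(R)
    return 100.0 * float(M.sum()) / float(M.size)


def _run_lengths(bits: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 1-D binary array."""
    if bits.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([0], bits.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def line_histogram(
    R: RecurrenceMatrix | np.ndarray,
    orientation: Literal["diagonal", "vertical"] = "diagonal",
) -> LineHistogram:
    """Histogram of maximal line lengths, excluding the main diagonal.

    Diagonal orientation walks every off-main diagonal. Vertical
    orientation walks columns with the main-diagonal cell deleted before
    run construction (a Theiler window of 1): the trivially recurrent
    self-comparison neither extends nor interrupts a vertical line, so a
    constant series still yields a single length N-1 run per column.
    """
    M = _as_matrix(R)
    n = M.shape[0]
    counts: dict[int, int] = {}

    def _add(lengths: np.ndarray) -> None:
        for l in lengths:
            counts[int(l)] = counts.get(int(l), 0) + 1

    if orientation == "diagonal":
        for k in range(1, n):
            d = np.diagonal(M, offset=k)
            _add(_run_lengths(d))
            d = np.diagonal(M, offset=-k)
            _add(_run_lengths(d))
    elif orientation == "vertical":
        for j in range(n):
            col = np.delete(M[:, j], j)
            _add(_run_lengths(col))
    else:
        raise ValueError(f"unknown orientation: {orientation!r}")
    return LineHistogram(orientation=orientation, counts=counts)


def determinism(
    R: RecurrenceMatrix | np.ndarray,
    l_min: int = 2,
    include_loi: bool = False,
) -> float:
    """Percent of off-diagonal recurrent points on diagonal lines of length >= l_min.

    ``include_loi=True`` restores the line of identity (main diagonal) to
    the histogram, which makes DET trivially large; the default excludes it.
    Returns 0 when there are no off-diagonal recurrent points.
    """
    M = _as_matrix(R)
    hist = line_histogram(M, "diagonal")
    counts = dict(hist.counts)
    if include_loi:
        n = M.shape[0]
        counts[n] = counts.get(n, 0) + 1
    denom = sum(l * c for l, c in counts.items())
    if denom == 0:
        return 0.0
    num = sum(l * c for l, c in counts.items() if l >= l_min)
    return 100.0 * num / denom


def laminarity(
    R: RecurrenceMatrix | np.ndarray,
    v_min: int = 2,
) -> float:
    """Percent of recurrent points on vertical lines of length >= v_min.

    Vertical runs are built with the main-diagonal cell deleted from each
    column, so an all-ones matrix yields LAM = 100 (one length N-1 run per
    column) and an identity matrix yields 0.
    """
    hist = line_histogram(R, "vertical")
    denom = hist.total_points()
    if denom == 0:
        return 0.0
    return 100.0 * hist.points_at_least(v_min) / denom


def _microstate_ids_exhaustive(M: np.ndarray, q: int) -> np.ndarray:
    """Microstate id of every valid q x q block (all top-left positions)."""
    n = M.shape[0]
    m = n - q + 1
    ids = np.zeros((m, m), dtype=np.int64)
    weight = 1
    for dj in range(q):
        for di in range(q):
            ids += M[di : di + m, dj : dj + m].astype(np.int64) * weight
            weight <<= 1
    return ids.ravel()


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(float)
    p /= p.sum()
    return float(-(p * np.log(p)).sum() + 0.0)  # +0.0 normalizes -0.0


def microstate_entropy(
    R: RecurrenceMatrix | np.ndarray,
    q: int = DEFAULT_Q,
    n_samples: int = DEFAULT_N_SAMPLES,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool = False,
) -> float:
    """Shannon entropy (nats) of the sampled q x q microstate distribution.

    ``n_samples`` top-left block positions are drawn uniformly with
    replacement from the ``(N - q + 1)^2`` valid positions; each binary
    block maps to one of ``2**(q*q)`` microstates and the plug-in entropy
    of the empirical distribution is returned. Blocks may straddle the
    main diagonal. ``exhaustive=True`` enumerates every position instead
    of sampling, giving the exact plug-in entropy of the full microstate
    distribution.
    """
    M = _as_matrix(R)
    n = M.shape[0]
    if n < q:
        raise ValueError(f"matrix size {n} smaller than microstate size {q}")
    if n < q + 1:
        raise ValueError(f"matrix size {n} must be >= q + 1 = {q + 1}")
    if exhaustive:
        ids = _microstate_ids_exhaustive(M, q)
        return _entropy_from_counts(np.bincount(ids, minlength=1 << (q * q)))
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    gen = np.random.default_rng(rng)
    m = n - q + 1
    i = gen.integers(0, m, size=n_samples)
    j = gen.integers(0, m, size=n_samples)
    ids = np.zeros(n_samples, dtype=np.int64)
    weight = 1
    for dj in range(q):
        for di in range(q):
            ids += M[i + di, j + dj].astype(np.int64) * weight
            weight <<= 1
    return _entropy_from_counts(np.bincount(ids, minlength=1 << (q * q)))


def radius_candidates(y: np.ndarray, n_candidates: int = DEFAULT_N_CANDIDATES) -> np.ndarray:
    """Default radius grid: evenly spaced over [1%, 100%] of the series range."""
    y = np.asarray(y, dtype=float).ravel()
    span = float(np.ptp(y))
    if span == 0.0:
        return np.array([0.0])
    return np.linspace(0.01, 1.0, n_candidates) * span


def select_radius(
    y: Sequence[float] | np.ndarray,
    candidates: Sequence[float] | np.ndarray | None = None,
    q: int = DEFAULT_Q,
    n_samples: int = DEFAULT_N_SAMPLES,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, np.ndarray]:
    """Radius maximizing microstate entropy over a candidate grid.

    Each candidate is scored with an identically seeded sampler so the
    comparison across candidates is not confounded by Monte-Carlo noise.
    Ties break to the smallest candidate; a constant series yields the
    single candidate 0. Returns ``(radius, curve)`` where ``curve`` has
    rows ``(candidate, entropy)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty series")
    if y.size < 2:
        raise ValueError("series must have length >= 2")
    if candidates is None:
        cand = radius_candidates(y)
    else:
        cand = np.sort(np.asarray(candidates, dtype=float))
        if cand.size == 0:
            raise ValueError("candidate set is empty")
    seed_seq = np.random.SeedSequence(rng if isinstance(rng, int) else 0)
    base_state = seed_seq.generate_state(1)[0]
    entropies = np.empty(cand.size)
    for k, r in enumerate(cand):
        R = recurrence_matrix(y, r)
        entropies[k] = microstate_entropy(
            R, q=q, n_samples=n_samples, rng=np.random.default_rng(base_state)
        )
    best = int(np.argmax(entropies))  # argmax returns the first (smallest) maximizer
    curve = np.column_stack([cand, entropies])
    return float(cand[best]), curve


def rqa_summary(
    y: Sequence[float] | np.ndarray,
    radius: float | None = None,
    q: int = DEFAULT_Q,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    l_min: int = 2,
    v_min: int = 2,
) -> RQAMetrics:
    """All five consistency metrics of a display series.

    The radius is chosen by :func:`select_radius` unless given; RR, DET,
    LAM and MCEntr are then computed on the single recurrence matrix at
    that radius. Fixed ``seed`` makes the result bit-reproducible.
    """
    values = getattr(y, "y", y)  # accept DisplaySeries or raw array
    values = np.asarray(values, dtype=float).ravel()
    if radius is None:
        radius, _ = select_radius(values, q=q, n_samples=n_samples, rng=seed)
    R = recurrence_matrix(values, radius)
    mc_rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    return RQAMetrics(
        rr=recurrence_rate(R),
        det=determinism(R, l_min=l_min),
        lam=laminarity(R, v_min=v_min),
        mcentr=microstate_entropy(R, q=q, n_samples=n_samples, rng=mc_rng),
        radius=float(radius),
        n_samples_mc=n_samples,
        seed=seed,
    )
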