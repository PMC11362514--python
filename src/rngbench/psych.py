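"""Randomness measures from the psychological RNG-task literature.

The battery collected by Towse & Neil and implemented in tools such as
RgCalc and randseqR: the redundancy index, the RNG and RNG2 indices, the
null-score quotient, the coupon score, the repetition gap, the adjacency
index, the turning point index, the runs index, and the phi index.  Each
measure targets a characteristic human bias — uneven response usage,
stereotyped transitions, repetition avoidance, seriation, or over-regular
cycling through the alphabet.

Conventions shared by all pair-based measures: pairs are counted without
wrap-around (the pair formed by the last and, after starting over, the
first response is never counted), and ``0 * log 0`` is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Sequence, UndefinedMeasureError

__all__ = [
    "PairCounts",
    "pair_counts",
    "redundancy_index",
    "rng_index",
    "null_score_quotient",
    "coupon_score",
    "repetition_gap",
    "adjacency_index",
    "turning_points",
    "turning_point_index",
    "ascending_runs",
    "runs_index",
    "phi_index",
]


@dataclass(frozen=True)
class PairCounts:
    """Ordered-pair frequencies ``n_ij`` at a given lag (no wrap-around).

    ``matrix[i-1, j-1]`` counts pairs whose first response is ``i`` and
    whose second, ``lag`` positions later, is ``j``.  The total pair count
    is ``L - lag``.
    """

    matrix: np.ndarray
    lag: int

    @property
    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


def pair_counts(seq: Sequence, lag: int = 1) -> PairCounts:
    """Count ordered response pairs at the given lag (1 = adjacent)."""
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if len(seq) < lag + 1:
        raise ValueError(
            f"sequence of length {len(seq)} too short for lag {lag} pairs"
        )
    a = seq.alphabet_size
    first = seq.values[:-lag]
    second = seq.values[lag:]
    matrix = np.zeros((a, a), dtype=np.int64)
    np.add.at(matrix, (first - 1, second - 1), 1)
    return PairCounts(matrix=matrix, lag=lag)


def _xlogx(x: np.ndarray) -> np.ndarray:
    """x * log(x) with the 0 log 0 := 0 convention (natural log)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def redundancy_index(seq: Sequence) -> float:
    """Shannon-entropy redundancy of the response frequencies, in percent.

    ``R = 100 * (1 - H / Hmax)`` with ``H`` the Shannon entropy (bits) of
    the observed single-response frequencies over the declared alphabet
    and ``Hmax = log2(a)``.  0 means perfectly equal usage of all
    responses; 100 means a single response was used throughout.
    """
    a = seq.alphabet_size
    if a < 2:
        raise ValueError("redundancy index requires an alphabet of at least 2")
    counts = np.bincount(seq.values, minlength=a + 1)[1:]
    p = counts / len(seq)
    h = -np.sum(_xlogx(p)) / np.log(2)
    # the formula is bounded by [0, 100]; clip float round-off at the ends
    return float(np.clip(100.0 * (1.0 - h / np.log2(a)), 0.0, 100.0))


def rng_index(seq: Sequence, lag: int = 1) -> float:
    """Evenness of response-pair usage given first-response frequencies.

    With pair counts ``n_ij`` at the given lag and row sums ``n_i.``,
    returns ``100 * sum_ij n_ij log n_ij / sum_i n_i. log n_i.``.  0 means
    transition probabilities as equal as the marginals allow; 100 means
    every transition is deterministic.  ``lag=2`` gives the interleaved
    variant (RNG2): in 4-1-5-6 the pairs considered are 4-5 and 1-6.

    The log base cancels in the ratio; natural log is used internally.
    A sequence whose row sums are all 0 or 1 carries no pair information
    and scores 0.
    """
    pc = pair_counts(seq, lag=lag)
    num = np.sum(_xlogx(pc.matrix))
    den = np.sum(_xlogx(pc.row_sums))
    if den == 0.0:
        return 0.0
    return 100.0 * num / den


def null_score_quotient(seq: Sequence) -> float:
    """Percentage of possible ordered response pairs absent at lag 1.

    ``100 * Z / a**2`` where ``Z`` counts ordered pairs over the alphabet
    (repeats included) that never occur as adjacent responses.  0 means
    every possible pair occurs.
    """
    pc = pair_counts(seq, lag=1)
    a = seq.alphabet_size
    absent = int(np.sum(pc.matrix == 0))
    return 100.0 * absent / (a * a)


def coupon_score(seq: Sequence) -> float:
    """Mean responses needed to produce every alphabet symbol once.

    Scans left to right, counting draws until all ``a`` responses have
    occurred; records the count, resets, and repeats.  The trailing
    incomplete segment is discarded; the score is the mean of the recorded
    counts.  A sequence that never uses some response scores ``L + 1``.
    Low scores indicate fast coverage of the alphabet (the human cycling
    tendency); the theoretical minimum is ``a``.
    """
    a = seq.alphabet_size
    counts: list[int] = []
    seen: set[int] = set()
    current = 0
    for v in seq.values:
        current += 1
        seen.add(int(v))
        if len(seen) == a:
            counts.append(current)
            seen.clear()
            current = 0
    if not counts:
        return float(len(seq) + 1)
    return float(np.mean(counts))


def repetition_gap(seq: Sequence, statistic: str = "mean") -> float:
    """Gap between successive occurrences of the same response.

    For each response value, the positional differences between its
    consecutive occurrences are collected; the gaps of all responses are
    pooled and summarised by the requested statistic (``mean``, ``median``
    or ``mode``; the median of an even count is the midpoint average, and
    modal ties break to the smallest gap).

    Raises
    ------
    UndefinedMeasureError
        If no response occurs twice anywhere in the sequence.  The measure
        is then reported as missing, never as zero.
    """
    if statistic not in ("mean", "median", "mode"):
        raise ValueError(f"unknown statistic {statistic!r}")
    gaps: list[int] = []
    last_pos: dict[int, int] = {}
    for pos, v in enumerate(seq.values.tolist(), start=1):
        if v in last_pos:
            gaps.append(pos - last_pos[v])
        last_pos[v] = pos
    if not gaps:
        raise UndefinedMeasureError(
            f"sequence {seq.id!r} contains no repeated response; "
            "repetition gap is undefined"
        )
    arr = np.asarray(gaps)
    if statistic == "mean":
        return float(arr.mean())
    if statistic == "median":
        return float(np.median(arr))
    values, freqs = np.unique(arr, return_counts=True)
    return float(values[np.argmax(freqs)])  # ties: np.argmax takes smallest gap


def adjacency_index(seq: Sequence, mode: str = "combined") -> float:
    """Percentage of numerically adjacent lag-1 response pairs.

    A pair ``(x, y)`` is ascending-adjacent if ``y = x + 1`` and
    descending-adjacent if ``y = x - 1`` (no value wrap: 9 -> 1 does not
    count).  ``mode`` selects ``ascending``, ``descending`` or
    ``combined``; the count is scaled by ``100 / (L - 1)``.  Elevated
    values reflect seriation / prepotent-associate pairs such as 4-5 and
    7-6.
    """
    if mode not in ("ascending", "descending", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(seq) < 2:
        raise ValueError("adjacency index requires at least 2 responses")
    diff = np.diff(seq.values)
    if mode == "ascending":
        count = int(np.sum(diff == 1))
    elif mode == "descending":
        count = int(np.sum(diff == -1))
    else:
        count = int(np.sum(np.abs(diff) == 1))
    return 100.0 * count / (len(seq) - 1)


def turning_points(seq: Sequence) -> int:
    """Number of strict interior extrema (local minima and maxima).

    Position ``i`` (2-based through L-1) is a turning point if its value
    is strictly greater or strictly smaller than both neighbours; tied
    neighbours produce no turning point.
    """
    if len(seq) < 3:
        raise ValueError("turning points require at least 3 responses")
    v = seq.values
    left, mid, right = v[:-2], v[1:-1], v[2:]
    maxima = (left < mid) & (mid > right)
    minima = (left > mid) & (mid < right)
    return int(np.sum(maxima | minima))


def turning_point_index(seq: Sequence) -> float:
    """Observed turning points relative to the chance expectation, x100.

    The expected number of turning points in a random sequence of length
    ``L`` is ``(2/3) * (L - 2)``; the index is ``100 * observed / expected``.
    Values above 100 mean more direction changes than chance.
    """
    expected = (2.0 / 3.0) * (len(seq) - 2)
    return 100.0 * turning_points(seq) / expected


def ascending_runs(seq: Sequence) -> list[int]:
    """Lengths of maximal strictly ascending runs.

    An equal or smaller successor starts a new run; e.g. 1-4-7-3-5 decomposes
    into runs 1-4-7 and 3-5, giving lengths [3, 2].  Lengths sum to ``L``.
    """
    lengths: list[int] = []
    current = 1
    v = seq.values
    for i in range(1, len(v)):
        if v[i] > v[i - 1]:
            current += 1
        else:
            lengths.append(current)
            current = 1
    lengths.append(current)
    return lengths


def runs_index(seq: Sequence, variance: str = "population") -> float:
    """Variance of the lengths of maximal strictly ascending runs.

    0 means all runs share one length; larger values mean frequent
    switching between short and long ascending stretches.  ``variance``
    selects the ``population`` (divide by run count, default) or
    ``sample`` (n-1) estimator.
    """
    if variance not in ("population", "sample"):
        raise ValueError(f"unknown variance type {variance!r}")
    lengths = np.asarray(ascending_runs(seq), dtype=float)
    if lengths.size == 1:
        return 0.0
    ddof = 0 if variance == "population" else 1
    return float(lengths.var(ddof=ddof))


def _span_repeats(values: np.ndarray, d: int) -> int:
    """Number of length-d blocks whose first and last response coincide."""
    return int(np.sum(values[: len(values) - d + 1] == values[d - 1 :]))


def phi_index(seq: Sequence, d: int) -> float:
    """Repetition score over blocks of length ``d`` (first vs last response).

    Counts the blocks of ``d`` consecutive responses whose first and last
    elements coincide (``O_d`` out of ``N_d = L - d + 1`` blocks) and
    compares this with the expectation derived from blocks one response
    smaller: ``E_d = N_d * O_{d-1} / N_{d-1}`` for ``d >= 3``.  At the
    base case ``d = 2`` a length-1 block's first and last response always
    coincide, so the expectation comes from chance repetition under the
    observed marginal frequencies, using the unbiased pair-sampling
    estimator ``E_2 = N_2 * sum_s count_s (count_s - 1) / (L (L - 1))``
    (the plug-in ``sum_s (count_s/L)**2`` would overestimate chance
    repetition by ``(1 - 1/a)/L`` and bias the index negative on i.i.d.
    input; with the unbiased form the index averages 0 at every ``d``
    under the i.i.d. null).

    Returns ``100 * (O_d - E_d) / N_d``: negative values mean fewer
    repetitions at that span than expected (repetition avoidance),
    positive values mean more.
    """
    if not 2 <= d <= 10:
        raise ValueError(f"phi index block length must be in 2..10, got {d}")
    L = len(seq)
    if L < d + 1:
        raise ValueError(f"sequence of length {L} too short for phi index d={d}")
    n_d = L - d + 1
    o_d = _span_repeats(seq.values, d)
    if d == 2:
        counts = np.bincount(seq.values, minlength=seq.alphabet_size + 1)[1:]
        e_d = n_d * float(np.sum(counts * (counts - 1))) / (L * (L - 1))
    else:
        n_prev = L - (d - 1) + 1
        o_prev = _span_repeats(seq.values, d - 1)
        e_d = n_d * o_prev / n_prev
    return 100.0 * (o_d - e_d) / n_d
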