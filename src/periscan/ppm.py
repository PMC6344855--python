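"""Phase 2: position-period matrix and periodicity score.

For each highly repetitive region (HRR) of size *h*, the surrounding region
of size *h* ± *m* is rescanned with a sliding window of size *h*.  Whenever
the window's leftmost k-mer occurs several times inside the window, each
consecutive pair of occurrences votes at the matrix row equal to their
distance, in every column covered by the two k-mer spans; the first pair of
the window votes with the occurrence count *n*, later pairs with 1.  Row
marginals of the resulting position-period matrix (PPM) therefore peak at
the repeat period, and the periodicity score is the fraction of matrix mass
within ±20% of the dominant period, relative to all distances up to half
the region size.  An HRR whose score reaches the threshold *P* becomes a
periodic repeat region (PRR).
"""

from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import EmptyMatrixError, NoPeriodError, UndefinedScoreError
from .kscan import HighlyRepetitiveRegion
from .seqio import ParameterSet


@dataclass(frozen=True)
class PositionPeriodMatrix:
    """Identical-k-mer pair distances (rows) against position (columns).

    ``matrix[d, j]`` counts votes of pairs at distance ``d`` covering
    region-local column ``j``; row 0 is unused padding so that row index
    equals distance.  ``region_offset`` locates column 0 on the source
    sequence; ``window`` is the effective sliding-window size.
    """

    matrix: np.ndarray
    region_offset: int
    window: int

    @property
    def max_distance(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def ncol(self) -> int:
        return self.matrix.shape[1]

    def row_marginal(self) -> np.ndarray:
        """Total votes per distance (index = distance; entry 0 is zero)."""
        return self.matrix.sum(axis=1)

    def to_frame(self):
        """Sparse (distance, position, count) table, e.g. for heat maps."""
        import pandas as pd

        rows, cols = np.nonzero(self.matrix)
        return pd.DataFrame({
            "distance": rows,
            "position": cols + self.region_offset,
            "count": self.matrix[rows, cols],
        })


@dataclass(frozen=True)
class PeriodicRepeatRegion:
    """An HRR promoted by its periodicity score, carrying the period d."""

    start: int
    end: int
    peak_height: int
    period: int
    periodicity_score: float
    source_record: Optional[str] = None
    k_seed: Optional[str] = None
    units: Optional[list[tuple[int, int]]] = None

    def __len__(self) -> int:
        return self.end - self.start


def period_band(d: int, max_distance: Optional[int] = None) -> tuple[int, int]:
    """Inclusive distance band [floor(0.8 d), ceil(1.2 d)] around a period.

    The lower bound is floored and the upper bound ceiled so that the band
    always contains ``d`` itself, even for small periods.
    """
    lo = max(1, math.floor(0.8 * d))
    hi = math.ceil(1.2 * d)
    if max_distance is not None:
        hi = min(hi, max_distance)
    return lo, hi


def build_ppm(seq: str, hrr: HighlyRepetitiveRegion,
              params: ParameterSet) -> PositionPeriodMatrix:
    """Build the position-period matrix for the region around one HRR.

    The scanned region is ``[hrr.start - m, hrr.end + m)`` clipped to the
    sequence; the sliding window is the HRR size (clipped to the region).
    Pair distances beyond half the region size fall outside the matrix and
    are ignored, matching the periodicity-score denominator.
    """
    k = params.kmer_size
    m = params.flank
    lo = max(0, hrr.start - m)
    hi = min(len(seq), hrr.end + m)
    region = seq[lo:hi]
    R = len(region)
    if R < k:
        raise EmptyMatrixError(
            f"scanned region of length {R} is shorter than k={k}")
    h = min(hrr.end - hrr.start, R)
    h = max(h, k)
    d_max = R // 2
    ambiguous = params.ambiguous_letter

    matrix = np.zeros((d_max + 1, R), dtype=np.int64)
    index: dict[str, deque[int]] = defaultdict(deque)
    for p in range(0, h - k + 1):
        index[region[p:p + k]].append(p)

    # The window slides until its start reaches the last k-mer of the
    # region (extent clipped at the region end), so positions near the
    # right edge of a clipped region still seed their occurrence chains.
    last_start = R - k
    for i in range(last_start + 1):
        kmer = region[i:i + k]
        occ = index[kmer]
        n = len(occ)
        if ambiguous not in kmer and n >= 2:
            prev = None
            first = True
            for p in occ:
                if prev is not None:
                    dist = p - prev
                    value = n if first else 1
                    first = False
                    if 1 <= dist <= d_max:
                        if dist >= k:
                            matrix[dist, prev:prev + k] += value
                            matrix[dist, p:p + k] += value
                        else:
                            matrix[dist, prev:p + k] += value
                prev = p
        occ.popleft()
        if not occ:
            del index[kmer]
        entering = i + 1 + h - k
        if i < last_start and entering <= R - k:
            index[region[entering:entering + k]].append(entering)

    return PositionPeriodMatrix(matrix=matrix, region_offset=lo, window=h)


def dominant_period(ppm: PositionPeriodMatrix) -> int:
    """Distance with the largest row marginal; ties go to the smaller period."""
    marginal = ppm.row_marginal()
    if marginal.sum() == 0:
        raise NoPeriodError("position-period matrix carries no mass")
    # argmax returns the first (smallest) index on ties.
    return int(np.argmax(marginal[1:])) + 1


def periodicity_score(ppm: PositionPeriodMatrix, d: int) -> float:
    """Fraction of PPM mass at distances within ±20% of ``d``.

    Numerator: rows floor(0.8 d) .. ceil(1.2 d) (inclusive, clipped to the
    matrix).  Denominator: rows 1 .. floor(ncol / 2), i.e. every distance
    the matrix can represent.
    """
    if not 1 <= d <= ppm.max_distance:
        raise NoPeriodError(f"period {d} outside matrix rows 1..{ppm.max_distance}")
    marginal = ppm.row_marginal()
    denominator = int(marginal[1:].sum())
    if denominator == 0:
        raise UndefinedScoreError("periodicity score denominator is zero")
    lo, hi = period_band(d, ppm.max_distance)
    numerator = int(marginal[lo:hi + 1].sum())
    return numerator / denominator


def promote_to_prr(hrr: HighlyRepetitiveRegion, ppm: PositionPeriodMatrix,
                   params: ParameterSet) -> Optional[PeriodicRepeatRegion]:
    """Promote an HRR to a periodic repeat region when its score reaches P."""
    d = dominant_period(ppm)
    score = periodicity_score(ppm, d)
    if score < params.score_threshold:
        return None
    return PeriodicRepeatRegion(
        start=hrr.start, end=hrr.end, peak_height=hrr.peak_height,
        period=d, periodicity_score=score, source_record=hrr.source_record,
    )
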