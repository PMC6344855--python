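"""Phase 1: sliding-window cumulative k-mer scoring.

A window of size *w* slides over the sequence one position at a time.  At
window start *i* the window's leftmost k-mer is looked up inside the window;
when it occurs *n* ≥ 2 times, *n* is added to the score of every position of
the leftmost occurrence and 1 to every position of each further occurrence.
Windows whose leftmost k-mer is unique within the window contribute nothing,
so the cumulative score is zero across non-repetitive sequence and maximal
runs of positive score ("peak areas") delimit repetitive neighbourhoods.
Peak areas whose height reaches the threshold *s*, together with any
positive runs reachable through zero-score gaps of at most *g* positions,
are merged into highly repetitive regions (HRRs).

The scan keeps a rolling index of the k-mer occurrences inside the current
window, giving an amortised near-linear runtime; the literal
double-loop-over-windows scorer lives in the test suite as the oracle.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import EmptyTrackError, ValidationError
from .seqio import ParameterSet


@dataclass(frozen=True)
class ScoreTrack:
    """Cumulative k-mer score per sequence position."""

    scores: np.ndarray
    params: ParameterSet

    def __post_init__(self) -> None:
        if len(self.scores) and int(self.scores.min()) < 0:
            raise ValidationError("score track must be non-negative")

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self):
        """Score track as a two-column table (position, score) for plotting."""
        import pandas as pd

        return pd.DataFrame(
            {"position": np.arange(len(self.scores)), "score": self.scores}
        )


@dataclass(frozen=True)
class HighlyRepetitiveRegion:
    """Phase-1 interval (0-based half-open) with its peak score."""

    start: int
    end: int
    peak_height: int
    source_record: Optional[str] = None

    def __len__(self) -> int:
        return self.end - self.start


def cumulative_kmer_scores(seq: str, params: ParameterSet) -> ScoreTrack:
    """Score every position of ``seq`` by cumulative k-mer counting.

    The effective window is ``min(window_size, len(seq))`` so short
    sequences are scanned with a single full-length window.  Leftmost k-mers
    containing the ambiguous letter (N for DNA, X for protein) are skipped
    as window seeds; ambiguous k-mers still count as occurrences when they
    are letter-identical to a seed.
    """
    k = params.kmer_size
    L = len(seq)
    if L < k:
        raise EmptyTrackError(f"sequence of length {L} is shorter than k={k}")
    w = min(params.window_size, L)
    ambiguous = params.ambiguous_letter

    # diff is a difference array; prefix summation at the end yields scores.
    diff = np.zeros(L + 1, dtype=np.int64)
    index: dict[str, deque[int]] = defaultdict(deque)
    for p in range(0, w - k + 1):
        index[seq[p:p + k]].append(p)

    last_start = L - w
    for i in range(last_start + 1):
        kmer = seq[i:i + k]
        occ = index[kmer]
        if ambiguous not in kmer and len(occ) >= 2:
            n = len(occ)
            diff[i] += n
            diff[i + k] -= n
            first = True
            for p in occ:
                if first:
                    first = False
                    continue
                diff[p] += 1
                diff[p + k] -= 1
        # Slide: drop the leaving leftmost k-mer, admit the entering one.
        occ.popleft()
        if not occ:
            del index[kmer]
        if i < last_start:
            entering = i + 1 + w - k
            index[seq[entering:entering + k]].append(entering)

    scores = np.cumsum(diff)[:L]
    return ScoreTrack(scores=scores, params=params)


def _positive_runs(scores: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of strictly positive score, as half-open intervals."""
    positive = scores > 0
    if not positive.any():
        return []
    padded = np.concatenate(([False], positive, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def extract_ckpas(track: ScoreTrack, s: Optional[int] = None) -> list[tuple[int, int]]:
    """Extract cumulative k-mer peak areas.

    A peak area is a maximal run of positive score whose maximum reaches the
    peak threshold ``s`` (default: the track's parameter set).  Returned
    intervals are sorted and disjoint.
    """
    if s is None:
        s = track.params.peak_threshold
    scores = track.scores
    return [
        (a, b) for a, b in _positive_runs(scores) if int(scores[a:b].max()) >= s
    ]


def merge_to_hrrs(
    ckpas: list[tuple[int, int]],
    track: ScoreTrack,
    g: Optional[int] = None,
    source_record: Optional[str] = None,
) -> list[HighlyRepetitiveRegion]:
    """Merge peak areas into the broadest possible highly repetitive regions.

    All positive-score runs (including sub-threshold shoulders) separated by
    zero-score gaps of at most ``g`` positions are chained; a chain becomes
    an HRR when it contains at least one peak area of threshold height.  The
    HRR spans the outermost positive positions of its chain.
    """
    if g is None:
        g = track.params.merge_gap
    if not ckpas:
        return []
    ckpa_starts = {a for a, _ in ckpas}
    runs = _positive_runs(track.scores)

    hrrs: list[HighlyRepetitiveRegion] = []
    chain_start, chain_end = runs[0][0], runs[0][1]
    chain_has_peak = runs[0][0] in ckpa_starts
    for a, b in runs[1:]:
        if a - chain_end <= g:
            chain_end = b
            chain_has_peak = chain_has_peak or a in ckpa_starts
        else:
            if chain_has_peak:
                hrrs.append(_make_hrr(chain_start, chain_end, track, source_record))
            chain_start, chain_end = a, b
            chain_has_peak = a in ckpa_starts
    if chain_has_peak:
        hrrs.append(_make_hrr(chain_start, chain_end, track, source_record))
    return hrrs


def _make_hrr(start: int, end: int, track: ScoreTrack,
              source_record: Optional[str]) -> HighlyRepetitiveRegion:
    peak = int(track.scores[start:end].max())
    return HighlyRepetitiveRegion(start=start, end=end, peak_height=peak,
                                  source_record=source_record)


def find_hrrs(seq: str, params: ParameterSet,
              source_record: Optional[str] = None) -> list[HighlyRepetitiveRegion]:
    """Run the full phase-1 scan: score, extract peak areas, merge."""
    track = cumulative_kmer_scores(seq, params)
    ckpas = extract_ckpas(track)
    return merge_to_hrrs(ckpas, track, source_record=source_record)
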