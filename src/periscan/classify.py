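"""Downstream descriptors and benchmark statistics.

Covers CRISPR candidate filtering by period and interspace size, region
overlap agreement (ROA, the interval Jaccard index), recall/precision
against a truth set of intervals at an ROA threshold, the positive
likelihood ratio (recall / false positive rate), and the per-protein
maximum repeat unit size (maxRUSPP) filter used for repeat-family
benchmarks.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .seqio import Alphabet

# Inclusive CRISPR candidate bounds (bp): period 58..81, interspace 25..60.
CRISPR_PERIOD_RANGE = (58, 81)
CRISPR_INTERSPACE_RANGE = (25, 60)


@dataclass(frozen=True)
class RepeatDescriptor:
    """Summary numbers for one detected periodic repeat region."""

    prr_id: str
    alphabet: Alphabet
    period: int
    unit_count: int
    unit_size: float          # median mapped-unit length
    interspace: float         # median gap between consecutive mapped units

    def __post_init__(self) -> None:
        if self.unit_count < 2:
            raise ValidationError("a repeat needs at least two units")


@dataclass(frozen=True)
class BenchmarkResult:
    recall: float
    precision: float
    false_positive_rate: Optional[float]
    positive_likelihood_ratio: Optional[float]
    roa_threshold: float


def describe(prr_id: str, alphabet: Alphabet, period: int,
             units: Sequence[tuple[int, int]]) -> RepeatDescriptor:
    """Build a descriptor from mapped unit intervals.

    Unit size and interspace are medians, which keeps edge-truncated units
    and the odd irregular spacer from skewing the summary.
    """
    if len(units) < 2:
        raise ValidationError("need at least two mapped units")
    ordered = sorted(units)
    sizes = [b - a for a, b in ordered]
    gaps = [max(0, nxt[0] - cur[1]) for cur, nxt in zip(ordered, ordered[1:])]
    return RepeatDescriptor(
        prr_id=prr_id, alphabet=alphabet, period=period,
        unit_count=len(ordered),
        unit_size=float(statistics.median(sizes)),
        interspace=float(statistics.median(gaps)),
    )


def is_crispr_candidate(desc: RepeatDescriptor) -> bool:
    """CRISPR-like array test: interspace 25–60 bp and period 58–81 bp.

    Bounds are inclusive.  Only meaningful for nucleotide repeats.
    """
    if desc.alphabet is not Alphabet.NUCLEOTIDE:
        raise TypeError("CRISPR candidate filtering applies to DNA repeats only")
    p_lo, p_hi = CRISPR_PERIOD_RANGE
    i_lo, i_hi = CRISPR_INTERSPACE_RANGE
    return p_lo <= desc.period <= p_hi and i_lo <= desc.interspace <= i_hi


def region_overlap_agreement(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Interval Jaccard index: overlap size over union size.

    Intervals are half-open on the same record; symmetric, in [0, 1], and
    exactly 1 iff the intervals are identical.
    """
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValidationError("empty interval")
    overlap = max(0, min(a1, b1) - max(a0, b0))
    union = (a1 - a0) + (b1 - b0) - overlap
    return overlap / union


def _keyed(intervals: Iterable) -> list[tuple[str, int, int]]:
    out = []
    for item in intervals:
        if len(item) == 2:
            out.append(("", int(item[0]), int(item[1])))
        else:
            out.append((str(item[0]), int(item[1]), int(item[2])))
    return out


def evaluate_predictions(pred: Iterable, truth: Iterable,
                         roa_threshold: float) -> BenchmarkResult:
    """Recall and precision of predicted intervals against a truth set.

    Intervals are ``(start, end)`` or ``(record, start, end)`` tuples.
    Matching is greedy one-to-one by descending ROA within each record; a
    pair counts when its ROA reaches the (inclusive) threshold.
    """
    preds = _keyed(pred)
    truths = _keyed(truth)
    if not truths:
        raise ValidationError("recall is undefined for an empty truth set")
    pairs = []
    for ti, (trec, t0, t1) in enumerate(truths):
        for pi, (prec, p0, p1) in enumerate(preds):
            if prec != trec:
                continue
            roa = region_overlap_agreement((t0, t1), (p0, p1))
            if roa >= roa_threshold and roa > 0:
                pairs.append((roa, ti, pi))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches = 0
    for roa, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches += 1
    recall = matches / len(truths)
    precision = matches / len(preds) if preds else 1.0
    return BenchmarkResult(recall=recall, precision=precision,
                           false_positive_rate=None,
                           positive_likelihood_ratio=None,
                           roa_threshold=roa_threshold)


def positive_likelihood_ratio(recall: float, fpr: float) -> float:
    """Recall divided by false positive rate; infinity when FPR is zero."""
    if fpr < 0 or recall < 0:
        raise ValidationError("rates must be non-negative")
    if fpr == 0:
        return math.inf
    return recall / fpr


def filter_by_maxruspp(proteins: Iterable[tuple[str, float]],
                       expected_unit: float,
                       tolerance: float = 5.0) -> list[tuple[str, float]]:
    """Keep proteins whose maximum repeat unit size is within ±tolerance.

    ``proteins`` are ``(id, maxRUSPP)`` pairs, where maxRUSPP is the
    largest mapped unit size among all repeats of one protein (aa).
    """
    return [(pid, size) for pid, size in proteins
            if abs(size - expected_unit) <= tolerance]


def max_unit_size_per_protein(descriptors: Iterable[RepeatDescriptor]) -> dict[str, float]:
    """maxRUSPP per protein id, from that protein's repeat descriptors."""
    out: dict[str, float] = {}
    for desc in descriptors:
        pid = desc.prr_id.rsplit(":", 1)[0]
        out[pid] = max(out.get(pid, 0.0), desc.unit_size)
    return out


def read_intervals(path) -> list[tuple[str, int, int]]:
    """Read intervals from BED or 3-column TSV (record, start, end)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed interval line: {line!r}")
        rows.append((fields[0], int(fields[1]), int(fields[2])))
    return rows


def benchmark_curve(pred: Iterable, truth: Iterable,
                    thresholds: Sequence[float]) -> pd.DataFrame:
    """Recall/precision across ROA thresholds, as a tidy table."""
    preds = list(pred)
    truths = list(truth)
    records = []
    for thr in thresholds:
        res = evaluate_predictions(preds, truths, thr)
        records.append({"roa_threshold": thr, "recall": res.recall,
                        "precision": res.precision})
    return pd.DataFrame(records)
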