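"""Synthetic repeat generator and the noise-tolerance experiment.

Emits sequences of the form ``flank + (unit [+ spacer]) × copies + flank``
with per-position substitution noise applied independently to every unit
copy, alongside the exact ground truth (repeat region, true period, unit
intervals, clean unit).  Spacers are random-content with fixed or uniform
random sizes, emulating CRISPR-like interspaced arrays; flanks are random
letters so that scan windows overlap non-repetitive context.

The sweep harness runs the detection pipeline across a grid of unit sizes,
spacer laws and noise levels and reports the fraction of replicates whose
true period is recovered, plus the largest noise level still recovered in
at least 90% of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .seqio import Alphabet, ParameterSet, SequenceRecord

_DNA = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

# Spacer laws: None (tandem), ("fixed", size), or ("uniform", lo, hi).
SpacerLaw = Optional[tuple]

DEFAULT_FLANK = {Alphabet.NUCLEOTIDE: 2000, Alphabet.AMINO_ACID: 300}


@dataclass(frozen=True)
class SyntheticRepeatSpec:
    """Recipe for one synthetic repeat sequence."""

    alphabet: Alphabet
    unit: Union[str, int]           # explicit unit string, or a size to randomise
    copies: int
    spacer_law: SpacerLaw = None
    noise_rate: float = 0.0
    flank_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        usize = len(self.unit) if isinstance(self.unit, str) else int(self.unit)
        if usize < 1:
            raise ValidationError("unit size must be at least 1")
        if self.copies < 2:
            raise ValidationError("need at least 2 copies")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValidationError("noise_rate must be in [0, 1]")
        if self.spacer_law is not None:
            kind = self.spacer_law[0]
            if kind == "fixed":
                if self.spacer_law[1] < 0:
                    raise ValidationError("spacer size must be non-negative")
            elif kind == "uniform":
                lo, hi = self.spacer_law[1], self.spacer_law[2]
                if not 0 <= lo <= hi:
                    raise ValidationError("invalid uniform spacer bounds")
            else:
                raise ValidationError(f"unknown spacer law {kind!r}")

    @property
    def letters(self) -> str:
        return _DNA if self.alphabet is Alphabet.NUCLEOTIDE else _AA

    @property
    def unit_size(self) -> int:
        return len(self.unit) if isinstance(self.unit, str) else int(self.unit)

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticRepeatSpec":
        """Build a spec from a plain key-value mapping (config file)."""
        alphabet = Alphabet(data["alphabet"])
        law = data.get("spacer_law")
        if isinstance(law, (list, tuple)):
            law = tuple(law)
        return cls(alphabet=alphabet, unit=data["unit"],
                   copies=int(data["copies"]), spacer_law=law,
                   noise_rate=float(data.get("noise_rate", 0.0)),
                   flank_size=data.get("flank_size"),
                   seed=int(data.get("seed", 0)))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually wrote, for scoring detections against."""

    region: tuple[int, int]            # repeat array, half-open
    period: int                        # nominal true period (unit + mean spacer)
    period_support: tuple[int, int]    # attainable consecutive-unit distances
    unit_intervals: tuple[tuple[int, int], ...]
    unit_consensus: str


def _random_letters(rng: np.random.Generator, letters: str, n: int) -> str:
    return "".join(rng.choice(list(letters), size=n)) if n > 0 else ""


def _mutate(rng: np.random.Generator, text: str, letters: str,
            rate: float) -> str:
    if rate == 0.0 or not text:
        return text
    chars = list(text)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [ch for ch in letters if ch != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def generate(spec: SyntheticRepeatSpec) -> tuple[SequenceRecord, GroundTruth]:
    """Emit one synthetic sequence and its ground truth, reproducibly.

    Every position of every unit copy is substituted with probability
    ``noise_rate`` to a uniformly chosen *different* letter; spacers and
    flanks are untouched random context.
    """
    rng = np.random.default_rng(spec.seed)
    letters = spec.letters
    unit = spec.unit if isinstance(spec.unit, str) else _random_letters(
        rng, letters, spec.unit)
    flank = spec.flank_size
    if flank is None:
        flank = DEFAULT_FLANK[spec.alphabet]
    left = _random_letters(rng, letters, flank)
    right = _random_letters(rng, letters, flank)

    parts: list[str] = []
    unit_intervals: list[tuple[int, int]] = []
    pos = len(left)
    spacer_sizes: list[int] = []
    for c in range(spec.copies):
        noisy = _mutate(rng, unit, letters, spec.noise_rate)
        parts.append(noisy)
        unit_intervals.append((pos, pos + len(noisy)))
        pos += len(noisy)
        if spec.spacer_law is not None and c < spec.copies - 1:
            if spec.spacer_law[0] == "fixed":
                size = int(spec.spacer_law[1])
            else:
                lo, hi = int(spec.spacer_law[1]), int(spec.spacer_law[2])
                size = int(rng.integers(lo, hi + 1))
            spacer_sizes.append(size)
            parts.append(_random_letters(rng, letters, size))
            pos += size

    core = "".join(parts)
    sequence = left + core + right
    u = len(unit)
    if spec.spacer_law is None:
        period, support = u, (u, u)
    elif spec.spacer_law[0] == "fixed":
        s = int(spec.spacer_law[1])
        period, support = u + s, (u + s, u + s)
    else:
        lo, hi = int(spec.spacer_law[1]), int(spec.spacer_law[2])
        period = u + round((lo + hi) / 2)
        support = (u + lo, u + hi)
    truth = GroundTruth(
        region=(len(left), len(left) + len(core)),
        period=period,
        period_support=support,
        unit_intervals=tuple(unit_intervals),
        unit_consensus=unit,
    )
    record = SequenceRecord(
        id=f"sim_{spec.alphabet.value}_u{u}x{spec.copies}_n{spec.noise_rate:g}_s{spec.seed}",
        sequence=sequence, alphabet=spec.alphabet)
    return record, truth


def write_truth_bed(truths: Iterable[tuple[str, GroundTruth]], path) -> None:
    """Ground-truth repeat regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for record_id, truth in truths:
            a, b = truth.region
            fh.write(f"{record_id}\t{a}\t{b}\tperiod={truth.period}\n")


def _recovered(hits, truth: GroundTruth, tolerance: int = 1) -> bool:
    """A detection recovers the truth when a PRR overlapping the planted
    region carries a period within the truth's attainable distance support
    (±tolerance); for tandem arrays the support collapses to the unit size.
    """
    lo = truth.period_support[0] - tolerance
    hi = truth.period_support[1] + tolerance
    t0, t1 = truth.region
    for hit in hits:
        if hit.end <= t0 or hit.start >= t1:
            continue
        if lo <= hit.period <= hi:
            return True
    return False


def noise_tolerance_sweep(
    alphabet: Alphabet,
    unit_sizes: Sequence[int],
    spacer_laws: Sequence[SpacerLaw],
    noise_grid: Sequence[float],
    replicates: int,
    seed: int,
    copies: int = 10,
    params: Optional[ParameterSet] = None,
    stop_when_failed: bool = False,
) -> pd.DataFrame:
    """Recovery fraction per (unit size, spacer law, noise) grid cell.

    One master seed streams per-replicate seeds, shared across noise levels
    so the recovery curve is paired in noise.  With ``stop_when_failed``
    the (ascending) noise grid is abandoned once a level fails the 90%
    criterion in some cell — enough to locate the tolerance boundary.
    Returns a tidy table with one row per cell.
    """
    from .pipeline import detect_repeats

    if params is None:
        params = ParameterSet.for_alphabet(alphabet)
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=replicates)
    rows = []
    for noise in noise_grid:
        level_ok = True
        for u in unit_sizes:
            for law in spacer_laws:
                recovered = 0
                for r in range(replicates):
                    spec = SyntheticRepeatSpec(
                        alphabet=alphabet, unit=u, copies=copies,
                        spacer_law=law, noise_rate=noise,
                        seed=int(rep_seeds[r]))
                    record, truth = generate(spec)
                    hits = detect_repeats(record.sequence, params,
                                          source_record=record.id,
                                          run_phase3=False)
                    if _recovered(hits, truth):
                        recovered += 1
                frac = recovered / replicates
                rows.append({
                    "alphabet": alphabet.value, "unit_size": u,
                    "spacer_law": "tandem" if law is None else
                                  ":".join(str(x) for x in law),
                    "noise": noise, "replicates": replicates,
                    "copies": copies, "master_seed": seed,
                    "recovery": frac,
                })
                level_ok = level_ok and frac >= 0.9
        if stop_when_failed and not level_ok:
            break
    return pd.DataFrame(rows)


def max_tolerated_noise(sweep: pd.DataFrame, min_recovery: float = 0.9) -> float:
    """Largest noise level whose recovery reaches ``min_recovery`` in every cell."""
    ok_levels = [
        noise for noise, group in sweep.groupby("noise")
        if (group["recovery"] >= min_recovery).all()
    ]
    return max(ok_levels) if ok_levels else float("nan")
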