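"""Phase 3: repeat motif extraction, circular punctuation and unit mapping.

The k-mer contributing the most periodicity mass (the seed) anchors
period-sized unit fragments; the fragments are multiply aligned, gap-rich
columns are dropped, and the alignment is treated as a ring so that the
longest run of low-consistency columns (typically the spacers of an
interspaced array) can be cut out and the motif rotated to start right
after it.  The columnwise consensus is then mapped back onto the region —
by exact scanning for motifs shorter than the k-mer size, otherwise by
repeated local alignment with short-query scoring — and the mapped units
yield a per-position letter-frequency profile whose consensus letters are
masked with ``*`` wherever the top letter frequency drops below 60%.

Multiple alignment and local search default to deterministic internal
backends (biotite's progressive aligner and Smith–Waterman); external
``mafft`` / ``blastn``-style executables can be configured instead.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .errors import (
    AlignmentError,
    DegenerateMotifError,
    InsufficientUnitsError,
    MappingError,
    SeedNotFoundError,
    ValidationError,
)
from .ppm import PeriodicRepeatRegion, period_band
from .seqio import Alphabet, ParameterSet

GAP = "-"
MASK = "*"


@dataclass(frozen=True)
class UnitAlignment:
    """Gapped unit fragments of equal length."""

    rows: tuple[str, ...]
    source_prr: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("an alignment needs at least two rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValidationError("alignment rows must have equal length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column statistics of a unit alignment.

    ``info_bits`` is log2(alphabet size) minus the Shannon entropy of the
    non-gap letter distribution; ``consistency`` scales it by the aligned
    (non-gap) fraction, so gap-rich columns cannot masquerade as consensus.
    """

    letters: str
    counts: np.ndarray          # (ncol, len(letters)) letter counts
    gap_fraction: np.ndarray    # (ncol,)
    info_bits: np.ndarray       # (ncol,)
    consistency: np.ndarray     # (ncol,)
    alphabet: Alphabet

    @property
    def column_count(self) -> int:
        return len(self.gap_fraction)


@dataclass(frozen=True)
class RepeatMotif:
    """Mapped repeat motif: consensus, mask, logo counts and unit loci."""

    representative: str
    masked_motif: str
    logo_matrix: np.ndarray     # (len(representative), len(letters)+1); last col = gaps
    letters: str
    units: tuple[tuple[int, int], ...]

    @property
    def unit_count(self) -> int:
        return len(self.units)

    def logo_frequencies(self):
        """Per-position letter frequency table (rows sum to 1 incl. gaps)."""
        import pandas as pd

        totals = self.logo_matrix.sum(axis=1, keepdims=True)
        freqs = np.divide(self.logo_matrix, totals, where=totals > 0,
                          out=np.zeros_like(self.logo_matrix, dtype=float))
        return pd.DataFrame(freqs, columns=list(self.letters) + [GAP])


def find_kseed(seq: str, prr: PeriodicRepeatRegion, params: ParameterSet) -> str:
    """Seed k-mer: the one contributing most pair mass near the period.

    For every k-mer in the PRR, consecutive occurrences whose distance lies
    in the ±20% band around the period are pair votes; because the phase-2
    window equals the region size, the accumulated vote weight per in-band
    pair telescopes to the occurrence count, so the seed mass is simply
    ``n_occurrences × n_in_band_pairs``.  Ties break to the k-mer whose
    first occurrence is leftmost.
    """
    k = params.kmer_size
    region = seq[prr.start:prr.end]
    if len(region) < k:
        raise SeedNotFoundError("region shorter than k")
    lo, hi = period_band(prr.period)
    positions: dict[str, list[int]] = {}
    for i in range(len(region) - k + 1):
        positions.setdefault(region[i:i + k], []).append(i)
    best: Optional[tuple[int, int, str]] = None  # (-mass, first_pos, kmer)
    for kmer, occ in positions.items():
        if len(occ) < 2 or params.ambiguous_letter in kmer:
            continue
        in_band = sum(1 for a, b in zip(occ, occ[1:]) if lo <= b - a <= hi)
        if in_band == 0:
            continue
        mass = len(occ) * in_band
        key = (-mass, occ[0], kmer)
        if best is None or key < best:
            best = key
    if best is None:
        raise SeedNotFoundError(
            f"no k-mer recurs within distance band {lo}..{hi}")
    return best[2]


def extract_units(seq: str, prr: PeriodicRepeatRegion, k_seed: str,
                  d: Optional[int] = None) -> list[tuple[int, str]]:
    """Period-sized fragments starting at every seed occurrence.

    Returns ``(start, fragment)`` pairs in source coordinates; the last
    fragment may be truncated at the PRR end.  Occurrences may overlap when
    seeds recur at spacings below the period; fragments are kept as-is.
    """
    if d is None:
        d = prr.period
    region = seq[prr.start:prr.end]
    starts = []
    i = region.find(k_seed)
    while i != -1:
        starts.append(i)
        i = region.find(k_seed, i + 1)
    if len(starts) < 2:
        raise InsufficientUnitsError(
            f"seed occurs {len(starts)} time(s); at least 2 required")
    fragments = []
    for s in starts:
        frag = region[s:s + d]
        if frag:
            fragments.append((prr.start + s, frag))
    return fragments


# ---------------------------------------------------------------------------
# Alignment backends
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _dna_matrix() -> balign.SubstitutionMatrix:
    alph = bseq.NucleotideSequence("A", ambiguous=True).alphabet
    n = len(alph)
    mat = np.full((n, n), -1, dtype=np.int32)
    np.fill_diagonal(mat, 1)
    # Ambiguity codes never reward a match; N repels (used as search mask).
    symbols = alph.get_symbols()
    for i, sym in enumerate(symbols):
        if sym not in "ACGT":
            mat[i, :] = -2
            mat[:, i] = -2
    ni = alph.encode("N")
    mat[ni, :] = -4
    mat[:, ni] = -4
    return balign.SubstitutionMatrix(alph, alph, mat)


@lru_cache(maxsize=None)
def _protein_matrix() -> balign.SubstitutionMatrix:
    return balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


def _to_biotite(seq: str, alphabet: Alphabet):
    if alphabet is Alphabet.NUCLEOTIDE:
        clean = "".join(
            ch if ch in "ACGTRYWSMKHBVDN" else "N" for ch in seq.upper().replace("U", "T")
        )
        return bseq.NucleotideSequence(clean, ambiguous=True)
    clean = "".join(
        ch if ch in "ACDEFGHIKLMNPQRSTVWYBZX" else "X" for ch in seq.upper()
    )
    return bseq.ProteinSequence(clean)


def _matrix_for(alphabet: Alphabet) -> balign.SubstitutionMatrix:
    return _dna_matrix() if alphabet is Alphabet.NUCLEOTIDE else _protein_matrix()


def _align_internal(fragments: Sequence[str], alphabet: Alphabet) -> list[str]:
    seqs = [_to_biotite(f, alphabet) for f in fragments]
    matrix = _matrix_for(alphabet)
    # Stiff gap opening: cheap gaps let the optimiser manufacture spurious
    # consensus columns out of random spacer content, which would defeat
    # the circular punctuation.
    result = balign.align_multiple(seqs, matrix, gap_penalty=(-10, -1))
    alignment = result[0] if isinstance(result, (tuple, list)) else result
    rows = []
    for symbols in balign.get_symbols(alignment):
        rows.append("".join(GAP if s is None else str(s) for s in symbols))
    return rows


def _align_mafft(fragments: Sequence[str], executable: str) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "units.fa"
        fasta.write_text(
            "".join(f">u{i}\n{frag}\n" for i, frag in enumerate(fragments)))
        try:
            proc = subprocess.run(
                [executable, "--auto", "--quiet", str(fasta)],
                capture_output=True, text=True, check=True)
        except (OSError, subprocess.CalledProcessError) as exc:
            raise AlignmentError(
                f"external aligner failed: {exc}; fragments={list(fragments)}"
            ) from exc
    rows, current = [], []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
            current = []
        else:
            current.append(line.strip().upper())
    if current:
        rows.append("".join(current))
    return rows


def align_units(fragments: Sequence[tuple[int, str]] | Sequence[str],
                alphabet: Alphabet,
                backend: str = "internal",
                source_prr: Optional[str] = None) -> UnitAlignment:
    """Multiple alignment of unit fragments.

    ``backend`` is ``"internal"`` (deterministic progressive aligner,
    match/mismatch +1/−1 for DNA, BLOSUM62 for protein, affine gaps −4/−1)
    or ``"external:<path-to-mafft>"``.
    """
    texts = [f[1] if isinstance(f, tuple) else f for f in fragments]
    texts = [t for t in texts if t]
    if len(texts) < 2:
        raise InsufficientUnitsError("need at least two non-empty fragments")
    if len(set(texts)) == 1:
        rows = list(texts)  # identical fragments align trivially, no gaps
    elif backend == "internal":
        rows = _align_internal(texts, alphabet)
    elif backend.startswith("external"):
        executable = backend.split(":", 1)[1] if ":" in backend else "mafft"
        if shutil.which(executable) is None:
            raise AlignmentError(f"external aligner {executable!r} not found")
        rows = _align_mafft(texts, executable)
    else:
        raise ValidationError(f"unknown alignment backend {backend!r}")
    if len(rows) != len(texts):
        raise AlignmentError("alignment backend returned wrong row count")
    return UnitAlignment(rows=tuple(rows), source_prr=source_prr)


# ---------------------------------------------------------------------------
# Column statistics and circular punctuation
# ---------------------------------------------------------------------------

_DNA_LETTERS = "ACGT"
_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def column_profile(alignment: UnitAlignment, alphabet: Alphabet) -> ColumnProfile:
    """Letter counts, information content and consistency per column.

    ``info_bits = log2(|A|) − H(letters)`` over the non-gap letters of the
    column (0 for an all-gap column); ``consistency = info_bits × (1 − gap
    fraction)``.
    """
    letters = _DNA_LETTERS if alphabet is Alphabet.NUCLEOTIDE else _AA_LETTERS
    lut = {ch: i for i, ch in enumerate(letters)}
    ncol = alignment.column_count
    nrow = len(alignment.rows)
    counts = np.zeros((ncol, len(letters)), dtype=np.int64)
    gaps = np.zeros(ncol, dtype=np.int64)
    for row in alignment.rows:
        for j, ch in enumerate(row):
            if ch == GAP:
                gaps[j] += 1
            else:
                idx = lut.get(ch)
                if idx is not None:
                    counts[j, idx] += 1
    gap_fraction = gaps / nrow
    info = np.zeros(ncol)
    max_bits = math.log2(len(letters))
    for j in range(ncol):
        total = counts[j].sum()
        if total == 0:
            continue
        freqs = counts[j][counts[j] > 0] / total
        entropy = -(freqs * np.log2(freqs)).sum()
        info[j] = max_bits - entropy
    consistency = info * (1.0 - gap_fraction)
    return ColumnProfile(letters=letters, counts=counts,
                         gap_fraction=gap_fraction, info_bits=info,
                         consistency=consistency, alphabet=alphabet)


def longest_circular_run(flags: Sequence[bool]) -> tuple[int, int]:
    """Longest run of True values on a ring, as (start, length).

    Scans the doubled array with the run length capped at the ring size;
    ties keep the earliest start.  Returns (0, 0) when no flag is set.
    """
    n = len(flags)
    if n == 0 or not any(flags):
        return 0, 0
    if all(flags):
        return 0, n
    best_start, best_len = 0, 0
    run = 0
    for i in range(2 * n):
        if flags[i % n]:
            run = min(run + 1, n)
            start = i - run + 1
            if run > best_len and start < n:
                best_start, best_len = start, run
        else:
            run = 0
    return best_start, best_len


def punctuate_circular(alignment: UnitAlignment, profile: ColumnProfile,
                       params: ParameterSet) -> tuple[UnitAlignment, ColumnProfile]:
    """Drop gap-rich columns, then cut the ring at the nonconsensus run.

    Columns with a gap fraction above ``q`` are removed.  The remaining
    columns are treated as circular; when the longest circular run of
    columns with consistency below ``u`` exceeds ``r`` columns, that run is
    removed and the alignment is rotated to begin just after it (this is
    what trims the spacers out of an interspaced array).  Otherwise the
    original linear order is kept.
    """
    keep = np.flatnonzero(profile.gap_fraction <= params.max_gap_fraction)
    if keep.size == 0:
        raise DegenerateMotifError("every column exceeded the gap threshold")
    flags = (profile.consistency[keep] < params.consistency_threshold).tolist()
    start, length = longest_circular_run(flags)
    n = len(keep)
    if 0 < length < n and length > params.min_punctuation_run:
        order = [(start + length + j) % n for j in range(n - length)]
    elif length == n:
        raise DegenerateMotifError("every column is below the consistency threshold")
    else:
        order = list(range(n))
    cols = keep[order]
    rows = tuple("".join(row[j] for j in cols) for row in alignment.rows)
    new_alignment = UnitAlignment(rows=rows, source_prr=alignment.source_prr)
    new_profile = ColumnProfile(
        letters=profile.letters,
        counts=profile.counts[cols],
        gap_fraction=profile.gap_fraction[cols],
        info_bits=profile.info_bits[cols],
        consistency=profile.consistency[cols],
        alphabet=profile.alphabet,
    )
    return new_alignment, new_profile


def representative_sequence(profile: ColumnProfile) -> str:
    """Columnwise most frequent letter; ties break alphabetically."""
    out = []
    for j in range(profile.column_count):
        row = profile.counts[j]
        if row.sum() == 0:
            continue
        out.append(profile.letters[int(np.argmax(row))])
    return "".join(out)


# ---------------------------------------------------------------------------
# Mapping the representative back onto the region
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _karlin_altschul_lambda(alphabet: Alphabet) -> float:
    """Ungapped Karlin–Altschul lambda for the internal scoring system.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with uniform background
    letter frequencies.  For the DNA +1/−1 system this is ln 3 exactly.
    """
    if alphabet is Alphabet.NUCLEOTIDE:
        return math.log(3.0)
    from scipy.optimize import brentq

    matrix = _protein_matrix()
    letters = _AA_LETTERS
    scores = np.array([[matrix.get_score(a, b) for b in letters] for a in letters],
                      dtype=float)
    p = 1.0 / len(letters)

    def f(lam: float) -> float:
        return float((p * p * np.exp(lam * scores)).sum() - 1.0)

    return float(brentq(f, 1e-4, 2.0))


_KA_K = 0.1  # crude but standard-order constant; the length criterion dominates


def _evalue(score: float, qlen: int, tlen: int, alphabet: Alphabet) -> float:
    lam = _karlin_altschul_lambda(alphabet)
    return _KA_K * qlen * tlen * math.exp(-lam * score)


def _iterative_local_search(rep: str, region: str, alphabet: Alphabet):
    """Repeated masked Smith–Waterman of the representative vs the region.

    Yields ``(tstart, tend, trace)`` per accepted hit; a hit is accepted
    when its aligned column count reaches 50% of the query length or its
    E-value is at most 0.01 (a disjunction).  Accepted hit spans are masked
    with the repelling letter before the next round.
    """
    matrix = _matrix_for(alphabet)
    query = _to_biotite(rep, alphabet)
    mask_letter = "N" if alphabet is Alphabet.NUCLEOTIDE else "*"
    target_chars = list(str(_to_biotite(region, alphabet)))
    qlen = len(rep)
    min_cols = math.ceil(0.5 * qlen)
    max_hits = 4 * len(region) // max(1, qlen) + 16
    hits = []
    for _ in range(max_hits):
        if alphabet is Alphabet.NUCLEOTIDE:
            target = bseq.NucleotideSequence("".join(target_chars), ambiguous=True)
        else:
            target = bseq.ProteinSequence("".join(target_chars))
        alns = balign.align_optimal(query, target, matrix,
                                    gap_penalty=(-4, -1), local=True,
                                    max_number=1)
        if not alns:
            break
        aln = alns[0]
        if aln.score <= 0 or len(aln.trace) == 0:
            break
        tcols = aln.trace[:, 1]
        tcols = tcols[tcols >= 0]
        if tcols.size == 0:
            break
        tstart, tend = int(tcols.min()), int(tcols.max()) + 1
        accepted = (len(aln.trace) >= min_cols
                    or _evalue(aln.score, qlen, len(region), alphabet) <= 0.01)
        if not accepted:
            break
        hits.append((tstart, tend, np.array(aln.trace)))
        for j in range(tstart, tend):
            target_chars[j] = mask_letter
    return hits


def _blast_local_search(rep: str, region: str, alphabet: Alphabet,
                        executable: Optional[str]):
    """Short-query BLAST+ of the representative against the region.

    Runs ``blastn -task blastn-short`` / ``blastp -task blastp-short`` with
    the region as the subject, applies the same 50%-length-or-E≤0.01
    acceptance, keeps hits greedily by score without subject overlap, and
    rebuilds each hit's column trace with the internal pairwise aligner so
    the downstream logo construction is backend-independent.
    """
    program = executable or ("blastn" if alphabet is Alphabet.NUCLEOTIDE
                             else "blastp")
    if shutil.which(program) is None:
        raise MappingError(f"external search tool {program!r} not found")
    task = ("blastn-short" if alphabet is Alphabet.NUCLEOTIDE
            else "blastp-short")
    qlen = len(rep)
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text(f">q\n{rep}\n")
        spath.write_text(f">s\n{region}\n")
        try:
            proc = subprocess.run(
                [program, "-task", task, "-query", str(qpath),
                 "-subject", str(spath), "-evalue", "1000",
                 "-outfmt", "6 sstart send length evalue bitscore sstrand"
                 if alphabet is Alphabet.NUCLEOTIDE else
                 "6 sstart send length evalue bitscore"],
                capture_output=True, text=True, check=True)
        except (OSError, subprocess.CalledProcessError) as exc:
            raise MappingError(f"external search failed: {exc}") from exc
    candidates = []
    for line in proc.stdout.splitlines():
        fields = line.split("\t")
        sstart, send = int(fields[0]), int(fields[1])
        length, evalue, score = int(fields[2]), float(fields[3]), float(fields[4])
        if sstart > send:
            continue  # representative maps on the forward orientation only
        if length >= math.ceil(0.5 * qlen) or evalue <= 0.01:
            candidates.append((score, sstart - 1, send))
    candidates.sort(key=lambda x: (-x[0], x[1]))
    taken: list[tuple[int, int]] = []
    hits = []
    query = _to_biotite(rep, alphabet)
    matrix = _matrix_for(alphabet)
    for score, tstart, tend in candidates:
        if any(tstart < b and a < tend for a, b in taken):
            continue
        taken.append((tstart, tend))
        fragment = _to_biotite(region[tstart:tend], alphabet)
        aln = balign.align_optimal(query, fragment, matrix,
                                   gap_penalty=(-4, -1), local=False,
                                   terminal_penalty=False, max_number=1)[0]
        trace = np.array(aln.trace)
        keep = trace[:, 1] >= 0
        trace = trace[keep]
        trace[:, 1] += tstart
        hits.append((tstart, tend, trace))
    hits.sort(key=lambda h: h[0])
    return hits


def representative_and_map(alignment: UnitAlignment, seq: str,
                           prr: PeriodicRepeatRegion, params: ParameterSet,
                           profile: Optional[ColumnProfile] = None,
                           search: str = "internal") -> RepeatMotif:
    """Build the representative motif, map it, and derive the masked motif.

    Representatives shorter than the k-mer size are located by greedy
    non-overlapping exact scanning; longer ones by iterative local
    alignment (50%-length or E ≤ 0.01 acceptance).  The mapped units build
    the letter-frequency logo, and logo positions whose top letter
    frequency is below 0.60 are masked with ``*``.
    """
    if profile is None:
        profile = column_profile(alignment, params.alphabet)
    rep = representative_sequence(profile)
    if not rep:
        raise DegenerateMotifError("representative sequence is empty")
    letters = profile.letters
    lut = {ch: i for i, ch in enumerate(letters)}
    region = seq[prr.start:prr.end]
    qlen = len(rep)
    logo = np.zeros((qlen, len(letters) + 1), dtype=np.int64)
    units: list[tuple[int, int]] = []

    if qlen < params.kmer_size:
        # Greedy non-overlapping exact scan.
        i = region.find(rep)
        while i != -1:
            units.append((prr.start + i, prr.start + i + qlen))
            i = region.find(rep, i + qlen)
        for _ in units:
            for j, ch in enumerate(rep):
                idx = lut.get(ch)
                if idx is not None:
                    logo[j, idx] += 1
    else:
        if search == "internal":
            found = _iterative_local_search(rep, region, params.alphabet)
        elif search.startswith("external"):
            executable = search.split(":", 1)[1] if ":" in search else None
            found = _blast_local_search(rep, region, params.alphabet,
                                        executable)
        else:
            raise ValidationError(f"unknown search backend {search!r}")
        for tstart, tend, trace in found:
            units.append((prr.start + tstart, prr.start + tend))
            for qcol, tcol in trace:
                if qcol < 0:
                    continue
                if tcol < 0:
                    logo[qcol, -1] += 1  # gap in the unit
                else:
                    idx = lut.get(region[tcol])
                    if idx is not None:
                        logo[qcol, idx] += 1

    if not units:
        raise MappingError("representative mapped to zero units")
    units.sort()
    n_units = len(units)
    masked = []
    for j in range(qlen):
        letter_counts = logo[j, :-1]
        if letter_counts.sum() == 0:
            masked.append(MASK)
            continue
        top = int(np.argmax(letter_counts))
        freq = letter_counts[top] / n_units
        masked.append(letters[top] if freq >= 0.6 else MASK)
    return RepeatMotif(representative=rep, masked_motif="".join(masked),
                       logo_matrix=logo, letters=letters, units=tuple(units))


def identify_motif(seq: str, prr: PeriodicRepeatRegion, params: ParameterSet,
                   aligner: str = "internal",
                   search: str = "internal") -> tuple[RepeatMotif, str]:
    """Run the complete phase 3 for one PRR; returns (motif, seed k-mer)."""
    k_seed = find_kseed(seq, prr, params)
    fragments = extract_units(seq, prr, k_seed)
    alignment = align_units(fragments, params.alphabet, backend=aligner,
                            source_prr=prr.source_record)
    profile = column_profile(alignment, params.alphabet)
    punct, punct_profile = punctuate_circular(alignment, profile, params)
    motif = representative_and_map(punct, seq, prr, params, punct_profile,
                                   search=search)
    return motif, k_seed
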