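"""Sequence input/output and run parameters.

Reads multi-entry FASTA or GenBank files, classifies each entry as DNA or
protein, pulls CDS translations out of annotated nucleotide entries so they
can be screened as proteins, and writes detection results back out as
annotated GenBank plus a tabular summary.

Coordinates are 0-based half-open everywhere inside the package; conversion
to GenBank's 1-based inclusive convention happens only at output time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import EmptyInputError, InputError, ValidationError

_DNA_LETTERS = frozenset("ACGTUN")


class Alphabet(enum.Enum):
    """Sequence type of an entry."""

    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"

    @property
    def size(self) -> int:
        """Number of canonical letters (4 for DNA/RNA, 20 for protein)."""
        return 4 if self is Alphabet.NUCLEOTIDE else 20


@dataclass(frozen=True)
class Provenance:
    """Origin of a protein record derived from a CDS feature.

    ``start``/``end`` are 0-based half-open genomic coordinates of the CDS on
    the parent nucleotide record; ``strand`` is +1 or -1.
    """

    parent_id: str
    locus_tag: str
    start: int
    end: int
    strand: int


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA or protein sequence with optional CDS provenance."""

    id: str
    sequence: str
    alphabet: Alphabet
    provenance: Optional[Provenance] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ParameterSet:
    """Screening parameters for one alphabet.

    window_size
        Sliding-window size *w* of the repetitive-region scan (positions).
    kmer_size
        k-mer size *k* used in both scan phases.
    peak_threshold
        Minimum cumulative k-mer peak height *s* for a peak area to count.
    merge_gap
        Maximum zero-score gap *g* (positions) bridged when merging peak
        areas into highly repetitive regions.
    flank
        Flank size *m* added on each side of a region before the
        position-period matrix is built.
    score_threshold
        Minimum periodicity score *P* for promotion to a periodic repeat
        region.
    max_gap_fraction
        Alignment columns with a gap fraction above *q* are discarded.
    consistency_threshold
        Columns with letter consistency below *u* (bits scaled by the
        aligned-letter fraction) count as nonconsensus during punctuation.
    min_punctuation_run
        A circular nonconsensus run must be longer than *r* columns to be
        cut out.
    """

    window_size: int
    kmer_size: int
    peak_threshold: int
    merge_gap: int
    flank: int
    score_threshold: float
    max_gap_fraction: float = 0.5
    consistency_threshold: float = 0.8
    min_punctuation_run: int = 5
    alphabet: Alphabet = Alphabet.NUCLEOTIDE

    def __post_init__(self) -> None:
        if min(self.window_size, self.kmer_size, self.peak_threshold,
               self.merge_gap, self.flank, self.min_punctuation_run) <= 0:
            raise ValidationError("all parameters must be positive")
        if self.kmer_size >= self.window_size:
            raise ValidationError("kmer_size must be smaller than window_size")
        if not 0.0 < self.score_threshold <= 1.0:
            raise ValidationError("score_threshold must be in (0, 1]")
        if not (0.0 < self.max_gap_fraction <= 1.0
                and 0.0 < self.consistency_threshold <= 1.0):
            raise ValidationError("gap/consistency thresholds must be in (0, 1]")

    @classmethod
    def dna(cls, **overrides) -> "ParameterSet":
        """Default nucleotide parameters: w=1000, k=10, s=20, g=300, m=1000, P=0.5."""
        base = cls(window_size=1000, kmer_size=10, peak_threshold=20,
                   merge_gap=300, flank=1000, score_threshold=0.5,
                   alphabet=Alphabet.NUCLEOTIDE)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def protein(cls, **overrides) -> "ParameterSet":
        """Default protein parameters: w=300, k=3, s=6, g=50, m=300, P=0.3."""
        base = cls(window_size=300, kmer_size=3, peak_threshold=6,
                   merge_gap=50, flank=300, score_threshold=0.3,
                   alphabet=Alphabet.AMINO_ACID)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def for_alphabet(cls, alphabet: Alphabet, **overrides) -> "ParameterSet":
        if alphabet is Alphabet.NUCLEOTIDE:
            return cls.dna(**overrides)
        return cls.protein(**overrides)

    @property
    def ambiguous_letter(self) -> str:
        """Letter treated as ambiguous when choosing window seeds."""
        return "N" if self.alphabet is Alphabet.NUCLEOTIDE else "X"


def detect_alphabet(sequence: str) -> Alphabet:
    """Classify a letter string as nucleotide or amino acid.

    A sequence is called nucleotide when at least 95% of its letters fall in
    ``{A, C, G, T, U, N}``; the margin tolerates rare ambiguity codes in
    genomic records while short peptides rich in Ala/Gly/Thr still classify
    as protein only if they carry other residues.
    """
    if not sequence:
        raise ValidationError("cannot classify an empty sequence")
    seq = sequence.upper()
    hits = sum(1 for ch in seq if ch in _DNA_LETTERS)
    return Alphabet.NUCLEOTIDE if hits / len(seq) >= 0.95 else Alphabet.AMINO_ACID


def _sniff_format(path: Path) -> str:
    try:
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    return "fasta" if line.lstrip().startswith(">") else "genbank"
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    raise EmptyInputError(f"{path} contains no sequence entries")


def _cds_translation(feature: SeqFeature, parent_seq: Seq) -> Optional[str]:
    quals = feature.qualifiers
    if "translation" in quals:
        return str(quals["translation"][0]).upper().rstrip("*")
    # No translation qualifier: translate in frame from the nucleotide
    # sequence, dropping any trailing partial codon.
    try:
        nt = feature.extract(parent_seq)
    except Exception:
        return None
    nt = nt[: len(nt) - len(nt) % 3]
    if len(nt) < 3:
        return None
    aa = str(nt.translate()).rstrip("*")
    return aa.upper() or None


def load_records(path, format_hint: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA or GenBank file into :class:`SequenceRecord` objects.

    The format is auto-detected unless ``format_hint`` (``"fasta"`` or
    ``"genbank"``) is given.  Letters are uppercased and each entry's
    alphabet is detected from its content.  For GenBank nucleotide entries,
    every CDS feature additionally yields an amino-acid record (translation
    qualifier verbatim when present, in-frame translation otherwise) whose
    provenance points back to the genomic interval and strand.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file {path} does not exist")
    fmt = format_hint or _sniff_format(path)
    if fmt not in ("fasta", "genbank"):
        raise InputError(f"unsupported format {fmt!r}")
    try:
        bio_records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:
        raise InputError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not bio_records:
        raise EmptyInputError(f"{path} contains no sequence entries")

    records: list[SequenceRecord] = []
    for rec in bio_records:
        seq = str(rec.seq).upper()
        if not seq:
            continue
        alphabet = detect_alphabet(seq)
        records.append(SequenceRecord(id=rec.id, sequence=seq, alphabet=alphabet))
        if fmt == "genbank" and alphabet is Alphabet.NUCLEOTIDE:
            cds_index = 0
            for feature in rec.features:
                if feature.type != "CDS" or feature.location is None:
                    continue
                cds_index += 1
                aa = _cds_translation(feature, rec.seq)
                if not aa:
                    continue
                tag = feature.qualifiers.get(
                    "locus_tag", feature.qualifiers.get("protein_id", [f"CDS_{cds_index}"])
                )[0]
                prov = Provenance(
                    parent_id=rec.id,
                    locus_tag=str(tag),
                    start=int(feature.location.start),
                    end=int(feature.location.end),
                    strand=int(feature.location.strand or 1),
                )
                records.append(
                    SequenceRecord(
                        id=f"{rec.id}|{tag}",
                        sequence=aa,
                        alphabet=Alphabet.AMINO_ACID,
                        provenance=prov,
                    )
                )
    if not records:
        raise EmptyInputError(f"{path} contains only empty sequences")
    return records


def protein_interval_to_genomic(prov: Provenance, start_aa: int, end_aa: int) -> tuple[int, int]:
    """Map a half-open amino-acid interval of a CDS product onto the genome.

    On the minus strand the protein N-terminus corresponds to the CDS end.
    """
    g_lo, g_hi = prov.start, prov.end
    if prov.strand >= 0:
        return g_lo + 3 * start_aa, min(g_hi, g_lo + 3 * end_aa)
    return max(g_lo, g_hi - 3 * end_aa), g_hi - 3 * start_aa


def _region_feature(start: int, end: int, qualifiers: dict, strand: int = 1,
                    kind: str = "repeat_region") -> SeqFeature:
    return SeqFeature(FeatureLocation(start, end, strand=strand),
                      type=kind, qualifiers=qualifiers)


def annotated_biorecord(record: SequenceRecord, regions: Sequence) -> _BioRecord:
    """Biopython record with one ``repeat_region`` feature per detection.

    ``regions`` holds periodic repeat regions (anything exposing ``start``,
    ``end``, ``period``, ``periodicity_score`` and optionally ``units`` and a
    ``motif`` with a ``masked_motif`` string).  Each repeat unit is emitted
    as a ``repeat_unit`` sub-feature.  Biopython's writer performs the
    0-based half-open to 1-based inclusive conversion.
    """
    for region in regions:
        if not (0 <= region.start < region.end <= len(record.sequence)):
            raise ValidationError(
                f"region [{region.start}, {region.end}) outside record "
                f"{record.id!r} of length {len(record.sequence)}"
            )
    molecule = "DNA" if record.alphabet is Alphabet.NUCLEOTIDE else "protein"
    bio = _BioRecord(
        Seq(record.sequence),
        id=record.id[:40],
        name=record.id.split("|")[0][:16] or "sequence",
        description="periscan periodic repeat annotation",
        annotations={"molecule_type": molecule},
    )
    for idx, region in enumerate(regions, start=1):
        quals = {
            "note": [f"periodic repeat {idx}"],
            "rpt_period": [str(region.period)],
            "periodicity_score": [f"{region.periodicity_score:.4f}"],
        }
        motif = getattr(region, "motif", None)
        if motif is not None:
            quals["rpt_unit_seq"] = [motif.masked_motif]
        bio.features.append(_region_feature(region.start, region.end, quals))
        for ustart, uend in getattr(region, "units", None) or []:
            bio.features.append(
                _region_feature(ustart, uend, {"note": [f"repeat unit of repeat {idx}"]},
                                kind="repeat_unit")
            )
    return bio


def write_annotated_genbank(record: SequenceRecord, regions: Sequence, path) -> None:
    """Write one record as annotated GenBank (see :func:`annotated_biorecord`)."""
    SeqIO.write([annotated_biorecord(record, regions)], str(path), "genbank")


SUMMARY_COLUMNS = [
    "record_id", "alphabet", "start", "end", "period", "periodicity_score",
    "unit_count", "median_unit_size", "median_interspace", "motif",
]


def summary_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble the one-row-per-repeat summary table."""
    df = pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS)
    return df


def write_summary_tsv(rows: Iterable[dict], path) -> None:
    summary_table(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")
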