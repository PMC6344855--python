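"""End-to-end orchestration of the three screening phases.

``detect_repeats`` runs one sequence through phase 1 (highly repetitive
regions), phase 2 (position-period matrix, periodicity score) and phase 3
(motif extraction and unit mapping); ``run_pipeline`` iterates over every
entry of an input file — including CDS translations of GenBank genomes,
which are screened as proteins — and writes annotated GenBank plus tabular
summaries.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classify, kscan, motif as motif_mod, ppm as ppm_mod, seqio
from .errors import PeriscanError, RegionError
from .kscan import HighlyRepetitiveRegion
from .motif import RepeatMotif
from .ppm import PeriodicRepeatRegion
from .seqio import Alphabet, ParameterSet, SequenceRecord

logger = logging.getLogger("periscan")


@dataclass(frozen=True)
class RepeatHit:
    """One detected periodic repeat with its motif and unit annotation."""

    record_id: str
    alphabet: Alphabet
    start: int
    end: int
    period: int
    periodicity_score: float
    k_seed: Optional[str] = None
    motif: Optional[RepeatMotif] = None

    @property
    def units(self) -> tuple[tuple[int, int], ...]:
        return self.motif.units if self.motif is not None else ()

    @property
    def unit_count(self) -> int:
        return len(self.units)

    def descriptor(self) -> classify.RepeatDescriptor:
        return classify.describe(
            prr_id=f"{self.record_id}:{self.start}-{self.end}",
            alphabet=self.alphabet, period=self.period, units=self.units)

    def summary_row(self) -> dict:
        units = self.units
        sizes = [b - a for a, b in units]
        gaps = [max(0, n[0] - c[1]) for c, n in zip(units, units[1:])]
        return {
            "record_id": self.record_id,
            "alphabet": self.alphabet.value,
            "start": self.start,
            "end": self.end,
            "period": self.period,
            "periodicity_score": round(self.periodicity_score, 4),
            "unit_count": len(units),
            "median_unit_size": statistics.median(sizes) if sizes else "",
            "median_interspace": statistics.median(gaps) if gaps else "",
            "motif": self.motif.masked_motif if self.motif else "",
        }


def detect_repeats(seq: str, params: ParameterSet,
                   source_record: Optional[str] = None,
                   run_phase3: bool = True,
                   aligner: str = "internal",
                   search: str = "internal") -> list[RepeatHit]:
    """Scan one sequence; returns hits sorted by position.

    Phase-3 failures on a single region (seed not found, degenerate motif,
    zero mapped units) demote that region: it is logged and skipped rather
    than aborting the scan.  With ``run_phase3=False`` the hits stop at the
    phase-2 level (period and score, no motif), which is all that period
    recovery experiments need.
    """
    seq = seq.upper()
    if len(seq) < params.kmer_size:
        return []
    hrrs = kscan.find_hrrs(seq, params, source_record=source_record)
    hits: list[RepeatHit] = []
    for hrr in hrrs:
        try:
            matrix = ppm_mod.build_ppm(seq, hrr, params)
            prr = ppm_mod.promote_to_prr(hrr, matrix, params)
        except RegionError as exc:
            logger.debug("region %s:[%d,%d) not periodic: %s",
                         source_record, hrr.start, hrr.end, exc)
            continue
        if prr is None:
            continue
        if not run_phase3:
            hits.append(RepeatHit(
                record_id=source_record or "", alphabet=params.alphabet,
                start=prr.start, end=prr.end, period=prr.period,
                periodicity_score=prr.periodicity_score))
            continue
        try:
            repeat_motif, k_seed = motif_mod.identify_motif(
                seq, prr, params, aligner=aligner, search=search)
        except RegionError as exc:
            logger.info("PRR %s:[%d,%d) demoted in phase 3: %s",
                        source_record, prr.start, prr.end, exc)
            continue
        if repeat_motif.unit_count < 2:
            logger.info("PRR %s:[%d,%d) demoted: fewer than two mapped units",
                        source_record, prr.start, prr.end)
            continue
        hits.append(RepeatHit(
            record_id=source_record or "", alphabet=params.alphabet,
            start=prr.start, end=prr.end, period=prr.period,
            periodicity_score=prr.periodicity_score,
            k_seed=k_seed, motif=repeat_motif))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults match the screening
    defaults for each alphabet."""

    input_path: str
    output_prefix: str
    dna_params: ParameterSet = field(default_factory=ParameterSet.dna)
    protein_params: ParameterSet = field(default_factory=ParameterSet.protein)
    aligner: str = "internal"
    search: str = "internal"
    crispr_filter: bool = True
    min_period: int = classify.CRISPR_PERIOD_RANGE[0]
    max_period: int = classify.CRISPR_PERIOD_RANGE[1]
    min_interspace: int = classify.CRISPR_INTERSPACE_RANGE[0]
    max_interspace: int = classify.CRISPR_INTERSPACE_RANGE[1]
    format_hint: Optional[str] = None


@dataclass(frozen=True)
class RunSummary:
    records_scanned: int
    dna_repeats: int
    protein_repeats: int
    crispr_candidates: int
    outputs: tuple[str, ...]


def _crispr_rows(hits: list[RepeatHit], config: RunConfig) -> list[dict]:
    rows = []
    for hit in hits:
        if hit.alphabet is not Alphabet.NUCLEOTIDE or hit.unit_count < 2:
            continue
        desc = hit.descriptor()
        if (config.min_period <= desc.period <= config.max_period
                and config.min_interspace <= desc.interspace <= config.max_interspace):
            rows.append({
                "record_id": hit.record_id, "start": hit.start, "end": hit.end,
                "period": desc.period, "interspace": desc.interspace,
                "unit_count": desc.unit_count,
                "motif": hit.motif.masked_motif if hit.motif else "",
            })
    return rows


def run_pipeline(config: RunConfig) -> RunSummary:
    """Screen every entry of the input file and write all outputs.

    Per nucleotide record, detections on the record itself and on its
    CDS-derived proteins are written as features of one annotated GenBank
    file (protein hits mapped back to genomic coordinates); all hits land
    in a TSV summary and nucleotide hits passing the period/interspace
    filter in a CRISPR-candidate TSV.  Entry-level failures are logged and
    skipped; only I/O and configuration errors abort the run.
    """
    records = seqio.load_records(config.input_path, config.format_hint)
    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    all_hits: list[RepeatHit] = []
    genbank_features: dict[str, list] = {}
    n_dna = n_protein = 0
    for record in records:
        params = (config.dna_params if record.alphabet is Alphabet.NUCLEOTIDE
                  else config.protein_params)
        try:
            hits = detect_repeats(record.sequence, params,
                                  source_record=record.id,
                                  aligner=config.aligner,
                                  search=config.search)
        except PeriscanError as exc:
            logger.warning("record %s skipped: %s", record.id, exc)
            continue
        logger.info("record %s (%s): %d periodic repeat(s)",
                    record.id, record.alphabet.value, len(hits))
        all_hits.extend(hits)
        if record.alphabet is Alphabet.NUCLEOTIDE:
            n_dna += len(hits)
            genbank_features.setdefault(record.id, []).append((record, hits, None))
        else:
            n_protein += len(hits)
            if record.provenance is not None:
                genbank_features.setdefault(record.provenance.parent_id, [])
                genbank_features[record.provenance.parent_id].append(
                    (record, hits, record.provenance))

    outputs = []
    tsv_path = f"{config.output_prefix}.repeats.tsv"
    seqio.write_summary_tsv((h.summary_row() for h in all_hits), tsv_path)
    outputs.append(tsv_path)

    if config.crispr_filter:
        crispr_path = f"{config.output_prefix}.crispr.tsv"
        crispr_rows = _crispr_rows(all_hits, config)
        pd.DataFrame(
            crispr_rows,
            columns=["record_id", "start", "end", "period", "interspace",
                     "unit_count", "motif"],
        ).to_csv(crispr_path, sep="\t", index=False)
        outputs.append(crispr_path)
    else:
        crispr_rows = []

    by_parent = _assemble_genbank_regions(records, all_hits)
    gb_path = f"{config.output_prefix}.gb"
    _write_genbank(records, by_parent, gb_path)
    outputs.append(gb_path)

    return RunSummary(records_scanned=len(records), dna_repeats=n_dna,
                      protein_repeats=n_protein,
                      crispr_candidates=len(crispr_rows),
                      outputs=tuple(outputs))


@dataclass(frozen=True)
class _Region:
    start: int
    end: int
    period: int
    periodicity_score: float
    motif: Optional[RepeatMotif]
    units: tuple[tuple[int, int], ...]


def _assemble_genbank_regions(records, hits) -> dict[str, list[_Region]]:
    """Group hits per output record, mapping protein hits onto the parent
    nucleotide record through their CDS provenance."""
    by_id = {r.id: r for r in records}
    grouped: dict[str, list[_Region]] = {}
    for hit in hits:
        record = by_id.get(hit.record_id)
        if record is None:
            continue
        if record.provenance is None:
            grouped.setdefault(record.id, []).append(_Region(
                start=hit.start, end=hit.end, period=hit.period,
                periodicity_score=hit.periodicity_score,
                motif=hit.motif, units=hit.units))
        else:
            prov = record.provenance
            g0, g1 = seqio.protein_interval_to_genomic(prov, hit.start, hit.end)
            units = tuple(
                seqio.protein_interval_to_genomic(prov, a, b)
                for a, b in hit.units)
            grouped.setdefault(prov.parent_id, []).append(_Region(
                start=g0, end=g1, period=hit.period,
                periodicity_score=hit.periodicity_score,
                motif=hit.motif, units=units))
    return grouped


def _write_genbank(records, grouped: dict[str, list[_Region]], path) -> None:
    from Bio import SeqIO as _SeqIO

    out_records = []
    for record in records:
        if record.provenance is not None:
            continue  # CDS products are annotated on their parent
        regions = sorted(grouped.get(record.id, []), key=lambda r: r.start)
        out_records.append(seqio.annotated_biorecord(record, regions))
    _SeqIO.write(out_records, str(path), "genbank")
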