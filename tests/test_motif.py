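"""Phase 3: seed k-mer, unit extraction, alignment, punctuation, mapping."""

import math

import numpy as np
import pytest

from oracles import circular_longest_true_run
from conftest import clean_tandem_fixture, random_seq
from periscan.errors import (
    DegenerateMotifError,
    InsufficientUnitsError,
    SeedNotFoundError,
)
from periscan.kscan import find_hrrs
from periscan.motif import (
    ColumnProfile,
    UnitAlignment,
    align_units,
    column_profile,
    extract_units,
    find_kseed,
    identify_motif,
    longest_circular_run,
    punctuate_circular,
    representative_and_map,
    representative_sequence,
)
from periscan.ppm import PeriodicRepeatRegion, build_ppm, promote_to_prr
from periscan.seqio import Alphabet, ParameterSet
from periscan.simrep import SyntheticRepeatSpec, generate


def _prr(start, end, period):
    return PeriodicRepeatRegion(start=start, end=end, peak_height=50,
                                period=period, periodicity_score=0.9)


class TestFindKseed:
    def test_perfect_tandem_leftmost_rotation_wins(self, dna_params):
        rng = np.random.default_rng(4)
        unit = random_seq(rng, Alphabet.NUCLEOTIDE, 36)
        seq = unit * 10
        seed = find_kseed(seq, _prr(0, len(seq), 36), dna_params)
        assert seed == unit[: dna_params.kmer_size]

    def test_crispr_seed_lies_in_repeat_not_spacer(self, dna_params):
        rng = np.random.default_rng(9)
        repeat = random_seq(rng, Alphabet.NUCLEOTIDE, 31)
        parts = []
        for _ in range(8):
            parts.append(repeat)
            parts.append(random_seq(rng, Alphabet.NUCLEOTIDE, 34))
        seq = "".join(parts)
        seed = find_kseed(seq, _prr(0, len(seq), 65), dna_params)
        assert seed in repeat

    def test_two_families_seed_from_heavier_one(self, dna_params):
        rng = np.random.default_rng(12)
        a = random_seq(rng, Alphabet.NUCLEOTIDE, 36)
        b = random_seq(rng, Alphabet.NUCLEOTIDE, 36)
        seq = a * 8 + b * 3
        seed = find_kseed(seq, _prr(0, len(seq), 36), dna_params)
        assert seed in a and seed not in b

    def test_no_recurring_kmer_raises(self, dna_params):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, Alphabet.NUCLEOTIDE, 120)
        k = dna_params.kmer_size
        assert len({seq[i:i + k] for i in range(len(seq) - k + 1)}) == len(seq) - k + 1
        with pytest.raises(SeedNotFoundError):
            find_kseed(seq, _prr(0, len(seq), 30), dna_params)


class TestExtractUnits:
    def test_one_fragment_per_occurrence_last_truncated(self, dna_params):
        rng = np.random.default_rng(6)
        unit = random_seq(rng, Alphabet.NUCLEOTIDE, 72)
        seq = unit * 6
        prr = _prr(0, len(seq) - 10, 72)  # truncate the last unit
        seed = unit[:10]
        fragments = extract_units(seq, prr, seed)
        assert len(fragments) == 6
        assert [len(f) for _, f in fragments[:-1]] == [72] * 5
        assert len(fragments[-1][1]) == 62
        assert [pos for pos, _ in fragments] == [72 * i for i in range(6)]

    def test_irregular_spacing_keeps_overlapping_fragments(self, dna_params):
        rng = np.random.default_rng(7)
        seed = random_seq(rng, Alphabet.NUCLEOTIDE, 10)
        filler = lambda n: random_seq(rng, Alphabet.NUCLEOTIDE, n)
        seq = seed + filler(62) + seed + filler(18) + seed + filler(62)
        fragments = extract_units(seq, _prr(0, len(seq), 72), seed, d=72)
        assert [pos for pos, _ in fragments] == [0, 72, 100]
        assert all(len(f) == 72 for _, f in fragments[:2])

    def test_single_occurrence_raises(self, dna_params):
        rng = np.random.default_rng(11)
        seq = random_seq(rng, Alphabet.NUCLEOTIDE, 200)
        with pytest.raises(InsufficientUnitsError):
            extract_units(seq, _prr(0, 200, 50), seq[:10])


class TestAlignUnits:
    def test_identical_fragments_align_without_gaps(self):
        fragments = ["ACGTACGTAATT"] * 6
        aln = align_units(fragments, Alphabet.NUCLEOTIDE)
        assert aln.column_count == 12
        assert all(row == fragments[0] for row in aln.rows)

    def test_single_insertion_creates_one_gap_column(self):
        base = "ACGTTGCAACGGTTAACCGT"
        with_ins = base[:10] + "T" + base[10:]
        fragments = [base, base, with_ins, base]
        aln = align_units(fragments, Alphabet.NUCLEOTIDE)
        assert aln.column_count == 21
        for i, row in enumerate(aln.rows):
            assert row.count("-") == (0 if i == 2 else 1)
            assert row.replace("-", "") == fragments[i]

    def test_conserved_anchor_columns_stay_aligned(self):
        """Degenerate 28-aa zinc-finger-like units keep C2H2 anchors."""
        rng = np.random.default_rng(20)
        unit = list(random_seq(rng, Alphabet.AMINO_ACID, 28))
        anchors = {3: "C", 6: "C", 19: "H", 23: "H"}
        for pos, aa in anchors.items():
            unit[pos] = aa
        fragments = []
        for _ in range(20):
            row = list(unit)
            for j in range(28):
                if j not in anchors and rng.random() < 0.25:
                    row[j] = random_seq(rng, Alphabet.AMINO_ACID, 1)
            fragments.append("".join(row))
        aln = align_units(fragments, Alphabet.AMINO_ACID)
        profile = column_profile(aln, Alphabet.AMINO_ACID)
        for pos, aa in anchors.items():
            # Find alignment columns where the anchor letter dominates.
            letter_idx = profile.letters.index(aa)
            freqs = profile.counts[:, letter_idx] / len(fragments)
            assert (freqs >= 0.95).sum() >= 1
        # Most columns carry all 20 rows without gaps.
        assert (profile.gap_fraction == 0).mean() > 0.8


class TestColumnProfile:
    def _aln(self, *rows):
        return UnitAlignment(rows=tuple(rows))

    def test_conserved_protein_column(self):
        aln = self._aln(*["C"] * 20)
        profile = column_profile(aln, Alphabet.AMINO_ACID)
        assert profile.info_bits[0] == pytest.approx(math.log2(20))
        assert profile.consistency[0] == pytest.approx(math.log2(20))

    def test_uniform_dna_column_has_zero_information(self):
        aln = self._aln("A", "C", "G", "T")
        profile = column_profile(aln, Alphabet.NUCLEOTIDE)
        assert profile.info_bits[0] == pytest.approx(0.0)

    def test_half_gaps_halve_consistency(self):
        aln = self._aln("A", "A", "-", "-")
        profile = column_profile(aln, Alphabet.NUCLEOTIDE)
        assert profile.info_bits[0] == pytest.approx(2.0)
        assert profile.gap_fraction[0] == pytest.approx(0.5)
        assert profile.consistency[0] == pytest.approx(1.0)

    def test_all_gap_column_defined_as_zero(self):
        aln = self._aln("A-", "A-", "A-")
        profile = column_profile(aln, Alphabet.NUCLEOTIDE)
        assert profile.info_bits[1] == 0.0
        assert profile.consistency[1] == 0.0


def _profile_from(consistency, gap_fraction=None, alphabet=Alphabet.NUCLEOTIDE):
    n = len(consistency)
    gap = np.zeros(n) if gap_fraction is None else np.asarray(gap_fraction, float)
    cons = np.asarray(consistency, float)
    counts = np.zeros((n, 4), dtype=np.int64)
    counts[:, 0] = 4
    return ColumnProfile(letters="ACGT", counts=counts, gap_fraction=gap,
                         info_bits=cons.copy(), consistency=cons,
                         alphabet=alphabet)


class TestPunctuation:
    def _aln(self, ncol, nrow=4):
        letters = "ACGT"
        rows = tuple("".join(letters[(r + j) % 4] for j in range(ncol))
                     for r in range(nrow))
        return UnitAlignment(rows=rows)

    def test_all_consistent_stays_linear(self, dna_params):
        aln = self._aln(12)
        profile = _profile_from([2.0] * 12)
        out, _ = punctuate_circular(aln, profile, dna_params)
        assert out.rows == aln.rows

    def test_run_of_exactly_r_not_removed(self, dna_params):
        cons = [2.0] * 7 + [0.1] * 5  # run length == r == 5
        out, _ = punctuate_circular(self._aln(12), _profile_from(cons), dna_params)
        assert out.column_count == 12

    def test_run_longer_than_r_removed_and_rotated(self, dna_params):
        cons = [2.0] * 6 + [0.1] * 6
        aln = self._aln(12)
        out, _ = punctuate_circular(aln, _profile_from(cons), dna_params)
        assert out.column_count == 6
        assert out.rows[0] == aln.rows[0][:6]

    def test_wraparound_run_removed_as_one(self, dna_params):
        # Bad columns 9,10,11,0,1,2 wrap the ring boundary.
        cons = [0.1, 0.1, 0.1] + [2.0] * 6 + [0.1, 0.1, 0.1]
        aln = self._aln(12)
        out, _ = punctuate_circular(aln, _profile_from(cons), dna_params)
        assert out.column_count == 6
        # Output rotated to begin right after the removed run (column 3).
        assert out.rows[0] == aln.rows[0][3:9]

    def test_gap_rich_columns_removed_first(self, dna_params):
        cons = [2.0] * 12
        gaps = [0.0] * 10 + [0.6, 0.8]
        out, _ = punctuate_circular(self._aln(12), _profile_from(cons, gaps),
                                    dna_params)
        assert out.column_count == 10

    def test_everything_nonconsensus_is_degenerate(self, dna_params):
        with pytest.raises(DegenerateMotifError):
            punctuate_circular(self._aln(12), _profile_from([0.1] * 12),
                               dna_params)

    @pytest.mark.parametrize("seed", range(20))
    def test_circular_run_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        flags = (rng.random(int(rng.integers(1, 40))) < 0.5).tolist()
        got = longest_circular_run(flags)
        want = circular_longest_true_run(flags)
        assert got[1] == want[1]
        if 0 < got[1] < len(flags):
            assert got[0] == want[0]


class TestRepresentativeAndMap:
    def test_perfect_tandem_motif_equals_unit(self, dna_params):
        record, truth = clean_tandem_fixture(36, 8, seed_base=50)
        hits_prr = _run_to_prr(record.sequence, dna_params)
        motif, _ = identify_motif(record.sequence, hits_prr, dna_params)
        assert motif.representative == truth.unit_consensus
        assert motif.masked_motif == truth.unit_consensus  # no '*'
        assert motif.unit_count == 8

    def test_low_majority_position_masked(self, dna_params):
        rng = np.random.default_rng(30)
        unit = random_seq(rng, Alphabet.NUCLEOTIDE, 20)
        variants = []
        for i in range(20):
            row = list(unit)
            row[7] = "A" if i < 11 else "C"  # top letter frequency 0.55
            variants.append("".join(row))
        seq = "".join(variants)
        aln = UnitAlignment(rows=tuple(variants))
        motif = representative_and_map(aln, seq, _prr(0, len(seq), 20),
                                       dna_params)
        assert motif.unit_count == 20
        assert motif.masked_motif[7] == "*"
        assert "*" not in motif.masked_motif[:7] + motif.masked_motif[8:]

    def test_short_representative_uses_exact_scan(self, dna_params):
        record, truth = clean_tandem_fixture(6, 20, seed_base=60)
        prr = _run_to_prr(record.sequence, dna_params)
        motif, _ = identify_motif(record.sequence, prr, dna_params)
        assert len(motif.representative) == 6 < dna_params.kmer_size
        assert motif.unit_count == 20
        assert all(b - a == 6 for a, b in motif.units)

    def test_representative_tie_breaks_alphabetically(self):
        profile = column_profile(UnitAlignment(rows=("AT", "TA")),
                                 Alphabet.NUCLEOTIDE)
        assert representative_sequence(profile) == "AA"


def _run_to_prr(seq, params):
    hrrs = find_hrrs(seq, params)
    assert len(hrrs) == 1
    prr = promote_to_prr(hrrs[0], build_ppm(seq, hrrs[0], params), params)
    assert prr is not None
    return prr


def test_phase_rotation_invariance(dna_params):
    """Starting the array at another unit phase only rotates the motif."""
    rng = np.random.default_rng(77)
    unit = random_seq(rng, Alphabet.NUCLEOTIDE, 30)
    flank_l = random_seq(rng, Alphabet.NUCLEOTIDE, 1500)
    flank_r = random_seq(rng, Alphabet.NUCLEOTIDE, 1500)
    reps = {}
    for shift in (0, 11):
        rotated = unit[shift:] + unit[:shift]
        seq = flank_l + rotated * 8 + flank_r
        prr = _run_to_prr(seq, dna_params)
        motif, _ = identify_motif(seq, prr, dna_params)
        reps[shift] = motif
    r0, r11 = reps[0].representative, reps[11].representative
    assert len(r0) == len(r11) == 30
    assert r11 in r0 + r0  # rotation of one another
    starts0 = {a for a, _ in reps[0].units}
    starts11 = {a for a, _ in reps[11].units}
    assert len(starts0.symmetric_difference(starts11)) <= 4


def test_masking_monotone_in_noise(protein_params):
    """Raising unit noise never (statistically) unmasks positions."""
    from conftest import AA

    masked_counts = []
    for noise in (0.0, 0.15, 0.35):
        total = 0
        for seed in range(6):
            rng = np.random.default_rng(900 + seed)
            unit = random_seq(rng, Alphabet.AMINO_ACID, 28)
            variants = []
            for _ in range(12):
                row = list(unit)
                for j in np.flatnonzero(rng.random(28) < noise):
                    row[j] = rng.choice([c for c in AA if c != row[j]])
                variants.append("".join(row))
            seq = "".join(variants)
            aln = UnitAlignment(rows=tuple(variants))
            motif = representative_and_map(aln, seq, _prr(0, len(seq), 28),
                                           protein_params)
            total += motif.masked_motif.count("*")
        masked_counts.append(total)
    assert masked_counts[0] == 0
    assert masked_counts[0] <= masked_counts[1] <= masked_counts[2]


def test_blast_search_backend_maps_same_units(dna_params):
    """Internal Smith-Waterman and external short-query BLAST map the same
    unit set on a clean tandem array."""
    record, truth = clean_tandem_fixture(36, 8, seed_base=50)
    prr = _run_to_prr(record.sequence, dna_params)
    internal, _ = identify_motif(record.sequence, prr, dna_params)
    external, _ = identify_motif(record.sequence, prr, dna_params,
                                 search="external")
    assert external.unit_count == internal.unit_count == 8
    assert external.masked_motif == internal.masked_motif


def test_internal_and_external_backends_agree(dna_params):
    """Internal progressive aligner and MAFFT give the same masked motif on
    a low-noise tandem fixture."""
    rec, truth = generate(SyntheticRepeatSpec(
        alphabet=Alphabet.NUCLEOTIDE, unit=36, copies=10, noise_rate=0.04,
        seed=41))
    prr = _run_to_prr(rec.sequence, dna_params)
    motifs = {}
    for backend in ("internal", "external:mafft"):
        motif, _ = identify_motif(rec.sequence, prr, dna_params,
                                  aligner=backend)
        motifs[backend] = motif.masked_motif
    assert motifs["internal"] == motifs["external:mafft"]
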