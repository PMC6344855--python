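# Methods

## Model and procedure

periscan treats "repeat" operationally: sequence in which identical k-mers
recur at a consistent spacing. All three phases are built on that single
primitive, which is what lets one scan cover tandem repeats, degenerate
protein repeats and interspaced (CRISPR-like) arrays in both alphabets.

**Phase 1 — cumulative k-mer scoring.** A window of size *w* slides one
position at a time; only the k-mer at the window start ("leftmost") is
looked up, so each sequence position seeds exactly one window. A window
whose leftmost k-mer occurs *n* ≥ 2 times adds *n* over the seed's k
positions and 1 over every other occurrence's positions. Windows with a
unique seed contribute nothing. This makes the score baseline exactly zero
in non-repetitive sequence, which the merging step relies on: peak areas
are maximal runs of positive score, a run qualifies when its peak reaches
*s*, and runs separated by zero-score gaps of at most *g* chain into one
highly repetitive region (HRR) provided the chain contains at least one
qualifying peak. The per-chain (not per-run) height test deliberately lets
degenerate, sub-threshold shoulders extend a region ("broadest possible
region"); the flip side is that chance repeated k-mers within *g* of a real
repeat can extend an HRR into its flanks, which matters for the unit-count
caveats below.

**Phase 2 — position–period matrix (PPM).** The region [HRR − *m*,
HRR + *m*), clipped to the sequence, is rescanned with a window equal to
the HRR size. For each window seed with occurrences p₁ < … < pₙ, each
consecutive pair votes at row (distance), in the columns both k-mer spans
cover; the window's first pair votes with weight *n*, later pairs with 1.
Window starts run to the end of the region with the window extent clipped
there — with starts capped at region − window, every position in the last
window-size tail could never seed, and a repeat pushed against a clipped
region edge (e.g. near a sequence end) would be invisible to the matrix.
Rows are bounded by half the region size, matching the score denominator.
The dominant period *d* is the argmax of the row marginal (ties to the
smaller period; only exact k-mer matches vote, so substitution noise moves
mass to integer multiples of the period rather than smearing it). The
periodicity score divides the band mass (rows ⌊0.8 d⌋…⌈1.2 d⌉, floor/ceil
so the band always contains *d*) by the total mass; an HRR with score ≥ *P*
becomes a periodic repeat region (PRR).

**Phase 3 — motif.** Among all k-mers of the PRR, the seed is the one whose
consecutive-occurrence pairs at in-band distances carry the most PPM mass.
Because the phase-2 window spans the region, the accumulated weight per
in-band pair telescopes to the occurrence count, so seed mass reduces to
(occurrences × in-band pairs); ties break to the leftmost first occurrence.
Fragments of length *d* start at every seed occurrence (the last may be
truncated; overlapping fragments are kept). Fragments are multiply aligned;
per column we compute information content b = log₂|A| − H over the non-gap
letters and consistency l = b × (1 − gap fraction). Columns with gap
fraction > *q* are dropped; on the remaining ring, the longest circular run
with l < *u*, if longer than *r* columns, is removed and the alignment
rotated to start after it — for an interspaced array this cuts the random
spacers out of the motif. The columnwise majority letter (ties
alphabetical) forms the representative, which is mapped back over the PRR:
greedy non-overlapping exact scan when shorter than *k*, otherwise
iterated local alignment in which the best hit is accepted if its aligned
column count reaches half the query length or its E-value is ≤ 0.01, then
masked out before the next round. Mapped units rebuild a letter-frequency
logo; positions whose top letter falls below a 0.60 majority are masked
with `*`.

No small-sample correction is applied to b: with the shallow alignments
this tool routinely sees (2–8 rows for real arrays), the usual
(|A|−1)/(2 ln 2 · n) correction exceeds log₂ 20 for protein alignments of
up to three rows and would force every column nonconsensus, demoting
legitimate three-copy protein repeats.

## Parameters

| parameter | DNA | protein | meaning |
|---|---|---|---|
| w (window_size) | 1000 | 300 | phase-1 sliding window |
| k (kmer_size) | 10 | 3 | exact-match word size, both phases |
| s (peak_threshold) | 20 | 6 | minimum peak of a qualifying score run |
| g (merge_gap) | 300 | 50 | maximum zero-score gap merged into an HRR |
| m (flank) | 1000 | 300 | region padding for the PPM |
| P (score_threshold) | 0.5 | 0.3 | minimum periodicity score of a PRR |
| q (max_gap_fraction) | 0.5 | 0.5 | column gap-fraction cutoff |
| u (consistency_threshold) | 0.8 | 0.8 | consensus bar on the l scale (bits × aligned fraction) |
| r (min_punctuation_run) | 5 | 5 | circular nonconsensus run must exceed this |

u = 0.8 is interpreted on the l scale for both alphabets: a column must
carry at least 0.8 effective bits to count as consensus. k sets the
resolution/sensitivity trade-off: larger k gives specific seeds (few chance
matches) but loses noise tolerance exponentially, since a k-mer copy
survives per-position substitution noise ν with probability (1−ν)^k.

## Numerical and design choices

- Internal coordinates are 0-based half-open; GenBank output converts to
  1-based inclusive at the boundary (via biopython).
- Alphabet detection calls a sequence nucleotide when ≥95% of letters are
  in {A,C,G,T,U,N}; CDS features without a translation qualifier are
  translated in frame with the standard code; only the given strand is
  scanned.
- k-mers containing N (DNA) or X (protein) never seed a window but still
  count as occurrences when letter-identical.
- The multiple aligner is biotite's deterministic progressive aligner,
  match/mismatch +1/−1 (DNA) or BLOSUM62 (protein) with affine gaps
  −10/−1. The stiff gap opening is deliberate: with cheap gaps the
  optimiser aligns random spacer content into spurious consensus columns,
  which defeats the circular punctuation. MAFFT can be substituted
  (`external:mafft`) and produces the same motifs on low-noise fixtures.
- The mapping search is Smith–Waterman at −4/−1 gaps (short-query
  scoring); E-values use an ungapped Karlin–Altschul λ (exactly ln 3 for
  the DNA +1/−1 system, solved numerically for BLOSUM62) with K fixed at
  0.1. K is a crude constant; it only enters the E ≤ 0.01 arm of the
  acceptance disjunction, which in practice decides only short partial
  units — the 50%-length arm dominates.
- Punctuation removes exactly one (the longest) circular nonconsensus run;
  on ties the earliest start wins. Removing every long run would discard
  genuinely variable motif interiors (e.g. the hypervariable positions of
  zinc fingers).
- Representative-letter and dominant-period ties break deterministically
  (alphabetical / smaller period), so runs are byte-reproducible.

## Synthetic data: what it emulates, what it does not

`simrep.generate` writes flank + (unit [+ spacer]) × copies + flank with
i.i.d. per-position substitutions inside unit copies (each hit position is
redrawn uniformly from the *other* letters). Flanks are uniform random
letters, 2000 (DNA) / 300 (protein) by default, so scan windows always
overlap non-repeat context; spacers are random content with fixed or
uniform(lo, hi) sizes, covering CRISPR-like geometry (repeat 23–55 bp,
spacer 25–60 bp). Ground truth records the array interval, unit intervals,
the clean unit, and the attainable consecutive-unit distance support (for
uniform spacers the truth period is a distribution, so "recovered" means a
PRR overlapping the array with period inside that support ± 1).

Not emulated: insertions/deletions (noise is substitution-only), GC/
composition bias, low-complexity background, nested or mixed repeat
families, and real CRISPR leader/Cas context. Uniform random flanks are
*harder* than real intergenic background in one specific way: a 2-kb random
DNA flank contains a handful of chance repeated 10-mers, which the
broadest-possible-region rule happily chains into a detected region.
Passing tests therefore demonstrate the scanning and motif machinery, not
calibrated false-positive rates on real genomes.

Known honest caveats, visible in the test expectations:

- **Unit counts are exact only under clean conditions.** Edge partial
  units (when the seed phase is rotated by chance flank periodicity),
  HRR flank bleed, and — for protein, where k = 3 — background 3-mer
  matches inside the region all add legitimate-but-unplanted mapped units.
  The exactness tests pin fixture validity first (primitive unit,
  non-extending boundaries, flanks free of window-range repeated k-mers)
  and run on DNA; protein tests assert exact period and approximate counts.
- **The CRISPR-candidate property is statistical at 8 copies.** With 8
  alignment rows, random spacer columns clear the u = 0.8 consistency bar
  a few percent of the time, occasionally breaking the spacer run that
  punctuation would remove; the residual columns inflate mapped unit sizes
  and can push the median interspace out of 25–60. Measured pass rate is
  ≈97% at 0–2% noise. The same behaviour occurs with the MAFFT backend.
- **Noise tolerance is bounded by k-mer survival and the score gate.** At
  noise ν a k-mer copy survives with (1−ν)^k; consecutive surviving
  occurrences skip mutated copies, so with n copies the in-band mass
  fraction is ≈ (n−1)p²/E[#pairs] (p = survival). For DNA (k = 10,
  P = 0.5, n = 10) this crosses 0.5 near ν ≈ 0.08, and the ≥90%-of-
  replicates criterion lands at 4–6%; for protein (k = 3, P = 0.3) the
  gate passes at 30% and the limit (~28%) comes from argmax flips to the
  double period. Fewer copies tolerate more noise (the −1 in the pair
  count helps); `scripts/acceptance.py` measures the 10-copy condition.

## Problem sizes

The default test suite runs in well under a minute apart from the
noise-tolerance check (~10 s) and the oracle-equivalence sweep (200
sequences ≤ 2 kb, ~5 s). The acceptance script uses 50 replicates per grid
cell and ascends the noise grid until a level fails, finishing in a few
minutes on one core. Memory is bounded by the dense PPM,
(region/2) × region int64 — about 30 MB for the largest synthetic regions
here; genome-scale HRRs would warrant a sparse matrix behind the same
interface.

## Limitations

Single-strand scanning only (no reverse-complement pass); no indel noise
model; no masking of low-complexity sequence before scanning; dominant
period is a plain argmax (no sub-harmonic disambiguation); secondary
structure annotation and figure rendering are out of scope. Benchmarks
against external truth sets ingest interval files (BED/TSV); the package
does not rebuild reference repeat databases.
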