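# periscan

Unsupervised, global detection of periodically repeating DNA and protein
sequences — tandem, degenerate and interspaced repeats, including
CRISPR-like arrays — from plain FASTA or GenBank input.

Most repeat finders target one repeat class (CRISPR arrays, short tandem
repeats, or specific protein domains). periscan instead screens for the one
property they share: **k-mer periodicity**. It is aimed at microbial
genomics and protein-repeat work: annotating CRISPR candidates, spotting
phase-variable short tandem repeats, and recovering degenerate protein
repeat families (TALE-, zinc-finger-, TPR-, WD40-like) without motif
libraries.

## How it works

For each sequence entry (GenBank CDS translations are additionally screened
as proteins):

1. **Highly repetitive regions (HRRs).** A window of size *w* slides along
   the sequence. At window position *i*, when the window's leftmost k-mer
   occurs *n* ≥ 2 times inside the window, *n* is added to the cumulative
   score *c* of the leftmost occurrence's positions and 1 to those of every
   other occurrence. Maximal runs with *c* > 0 whose peak reaches *s*
   ("cumulative k-mer peak areas"), plus any positive runs within zero-score
   gaps of at most *g*, merge into HRRs.
2. **Periodicity.** Around each HRR (± *m* positions), consecutive
   occurrences of identical k-mers vote in a position–period matrix (PPM):
   row = pair distance, columns = the positions the two k-mers cover. The
   dominant period *d* is the distance with the largest row marginal, and
   the periodicity score is the matrix mass at distances in
   [0.8 *d*, 1.2 *d*] divided by the mass at all distances up to half the
   region size. Regions scoring at least *P* become periodic repeat regions
   (PRRs).
3. **Motif and units.** The k-mer contributing the most near-period pair
   mass seeds period-sized unit fragments, which are multiply aligned.
   Gap-rich columns (gap fraction > *q*) are dropped; treating the columns
   as a ring, the longest run of low-consistency columns
   (*l* = information content × aligned fraction < *u*, run longer than
   *r*) is cut out — this is what trims the spacers of an interspaced array
   — and the consensus of the remaining columns is mapped back onto the
   region (exact scan for motifs shorter than *k*, otherwise iterative
   Smith–Waterman with short-query scoring; hits accepted at ≥50% query
   length or E ≤ 0.01). Mapped units give the per-position letter
   frequencies; consensus letters below 60% majority are masked with `*`.

Defaults: DNA *w*=1000, *k*=10, *s*=20, *g*=300, *m*=1000, *P*=0.5;
protein *w*=300, *k*=3, *s*=6, *g*=50, *m*=300, *P*=0.3; shared *q*=0.5,
*u*=0.8, *r*=5.

Downstream helpers classify CRISPR candidates (period 58–81 bp and median
interspace 25–60 bp, inclusive), compute region overlap agreement
(ROA = |a∩b| / |a∪b|), recall/precision at an ROA threshold, the positive
likelihood ratio (recall / FPR), and the per-protein maximum repeat unit
size (maxRUSPP) filter. A synthetic-repeat generator (`periscan.simrep`)
produces ground-truthed tandem and CRISPR-like test sequences with
controlled substitution noise.

## Worked example

Simulate a CRISPR-like array (31-bp repeat, 8 copies, spacers 30–38 bp, 2%
substitution noise) and screen it:

```sh
$ periscan simulate --unit-size 31 --copies 8 --spacer uniform:30:38 \
      --noise 0.02 --seed 11 --out array
wrote array.fa and array.truth.bed (true period 65)

$ periscan run array.fa --out scan
scanned 1 record(s): 1 DNA repeat(s), 0 protein repeat(s), 1 CRISPR candidate(s)
wrote scan.repeats.tsv
wrote scan.crispr.tsv
wrote scan.gb
```

`scan.repeats.tsv` then contains:

```
record_id                       alphabet    start  end   period  periodicity_score  unit_count  median_unit_size  median_interspace  motif
sim_nucleotide_u31x8_n0.02_s11  nucleotide  1674   2488  67      0.8415             8           32.0000           33                 *******************AATCGGGACACTGAGATTTGTCAGCGTCTAC
```

Reading the row: the scan found one periodic DNA region with a dominant
period of 67 bp (repeat + spacer; the planted truth is 65 ± spacer jitter)
and 84% of its pair-distance mass near that period. Eight repeat units were
mapped, median 32 bp long and separated by a median 33-bp interspace —
inside the CRISPR candidate box, so the array also appears in
`scan.crispr.tsv`. The motif string is the mapped consensus; the leading
`*` run marks columns without a 60% majority (residual spacer columns), and
the unmasked tail is the recovered repeat. `scan.gb` carries the same
regions and units as `repeat_region`/`repeat_unit` GenBank features.

Library use mirrors the CLI:

```python
from periscan import ParameterSet, detect_repeats, load_records

records = load_records("array.fa")
hits = detect_repeats(records[0].sequence, ParameterSet.dna())
```

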