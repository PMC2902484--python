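# alignscan

Virtually every alignment tool optimises and reports *similarity*. But
when you need to tell closely related sequences apart — paralogous gene
family members, near-identical isoforms, strains of one species — the
biologically useful signal is the *divergent* part of the alignment:
the short variable stretches where a specific qPCR primer, a genotyping
probe or an isoform-specific antibody epitope can anchor. `alignscan`
mines a multiple sequence alignment (MSA) of conserved DNA or protein
sequences for exactly those regions, flags putative SNPs, and grades
candidate PCR primers drawn from them.

## Method

For an MSA of `nseq` sequences, gap-rich ends are sliced away (inward
from each end until two contiguous gap-free columns), per-column symbol
counts γ(i, b) are tabulated, and a reference symbol C(i) per column is
taken from the plurality consensus (or from a user-chosen *master*
sequence, to highlight what distinguishes that one sequence). Four
per-column scores X(i) are available, all oriented so conserved columns
score high and divergent ones low:

| method | definition | notes |
|---|---|---|
| Weighted | (1/nseq) Σ_b γ(i,b)·M(C(i), b) | M = identity (+5/−4), IUPAC-aware "simple", or BLOSUM62; gaps score the matrix minimum |
| DNAW | γ(i, C(i)) / nseq | DNA only; ∈ [0, 1] |
| Entropy | −H(i), Shannon entropy in bits of the column frequencies | 0 iff the column is uniform |
| Variability | 1 − D(i), D = number of distinct symbols | any change counts |

Cutoffs are robust: `median(X) ± 1.4826·MAD`, the classical
MAD-to-standard-deviation consistency factor (1/Φ⁻¹(3/4)). For very
similar sequences the MAD collapses to zero, and the spread falls back
to the mean absolute deviation about the mean — in that regime only the
low (divergent) cutoff is meaningful.

Columns whose **raw** score falls below the low cutoff are putative
SNPs, provided every non-reference base at the column occurs in at
least two sequences (so fewer than four sequences can never support a
SNP call). Regions come from a **smoothed** twin of the track — a hard
FFT low-pass that turns sharp per-column peaks into region-scale dips —
as maximal runs beyond a cutoff; DNA divergent regions must contain at
least two putative SNPs. Each region carries the arithmetic mean of the
raw scores it spans as its characteristic score.

Candidate primers are the divergent region plus five bases of flank on
the ungapped reference, graded against the usual oligo rules (GC%
40–60, Tm > 52 °C, 2–3 G/C at the 3' end, no repeats, self-dimer
ΔG > −4 and hairpin ΔG > −3 kcal/mol) with nearest-neighbor Tm and
stack-sum ΔG estimates.

## Worked example

Generate a synthetic alignment of 8 sequences with three planted
divergent blocks, scan it with the entropy score, and export GFF3:

```sh
alignscan simulate --nseq 8 --length 500 \
    --block 100:106:0.5:2 --block 240:250:0.5:2 --block 380:395:0.5:2 \
    --seed 11 --out demo.fasta --truth demo_truth.json
alignscan scan demo.fasta --method entropy --gff demo.gff3
```

```
ENTROPY: 3 divergent / 0 conserved regions, 18 putative SNPs, 10.6% of columns divergent
 method      kind  start  end  length   score  snp_count bucket
ENTROPY DIVERGENT     95  110      16 -0.2207          4   LONG
ENTROPY DIVERGENT    237  252      16 -0.2714          5   LONG
ENTROPY DIVERGENT    380  400      21 -0.3886          9   LONG
```

All three planted blocks (alignment columns 101–106, 241–250, 381–395)
are recovered, each inside one called region; the negative scores are
mean column entropies in bits (more negative = more variable), and
`bucket` classifies region length (<6 / 6–11 / >11 columns). The GFF3
file holds the same regions plus one `sequence_variant` line per
putative SNP, 1-based inclusive.

Grading primers:

```sh
alignscan primers GGTCTTTAGCAACCCTGA ACAGATGATCTAGGACATGC
```

```
            sequence  length  gc_pct  tm_c  gc3  repeats  dimer_dg  hairpin_dg grade_gc grade_tm grade_clamp grade_repeats grade_dimer grade_hairpin
  GGTCTTTAGCAACCCTGA      18      50  53.6    3    False     -3.28       -3.28     PASS     PASS        PASS          PASS        PASS          WARN
ACAGATGATCTAGGACATGC      20      45  53.6    3    False     -3.78       -2.58     PASS     PASS        PASS          PASS        PASS          PASS
```

Both primers pass the GC, Tm, clamp, repeat and dimer rules; the first
sits just inside the hairpin warning band (−3.28 vs the −3 kcal/mol
threshold).

The same pipeline is available as a library:

```python
from alignscan import read_alignment, run

bundle = run(read_alignment("family.aln"))
bundle.methods["ENTROPY"].regions     # called regions
bundle.summary("ENTROPY")             # counts, length buckets, coverage %
```

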