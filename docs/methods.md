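# Methods

## Problem and model

`alignscan` treats a multiple sequence alignment of closely related
sequences as a stack of independent columns and asks, per column, how
much the sequences disagree there. No phylogeny is modelled: the
working assumption is that the aligned sequences are similar enough
(paralogs within a genome, orthologs of close species, isoforms) that
column-wise frequency statistics carry the divergence signal, and that
divergence of interest is *localised* — short runs of variable columns
inside an otherwise conserved alignment. Under those assumptions a
per-column score plus a robust threshold plus a low-pass filter is the
whole machine; everything else is bookkeeping.

## Pipeline

1. **Load and normalise.** Format is identified from content
   signatures (FASTA `>`, Clustal header, `#NEXUS`, PHYLIP numeric
   header, MSF header), never from the file name; a format hint is
   consulted only when sniffing is inconclusive. Residues are
   upper-cased, `.` gaps become `-`, and the alphabet is called DNA
   when more than 90% of non-gap characters are IUPAC nucleotide
   symbols.
2. **End slicing.** Alignment ends are gap-rich and unreliable, so the
   analysed window starts at the first pair of contiguous entirely
   gap-free columns and ends after the last such pair (scanning inward
   from each end independently). Manual bounds override this after
   validation. Slicing is idempotent.
3. **Frequency table.** Per-column symbol counts γ(i, b), with the gap
   as its own symbol class. All four scores read only this table, so
   scoring cost per column is independent of nseq.
4. **Reference track.** C(i) is the plurality non-gap symbol (gap only
   for all-gap columns), ties broken lexicographically — the tie rule
   and the optional plurality threshold (default 0) are this package's
   documented choices, since plurality consensus has no canonical tie
   behaviour. A designated master sequence replaces the consensus,
   including its gaps, to surface differences specific to that row.

## Scores

With γ(i, b), D(i), nseq and reference C(i):

* **Weighted** `S(i) = (1/nseq) Σ_b γ(i,b) · M(C(i), b)`. Matrices:
  identity (+5 match / −4 mismatch; the conventional nucleotide scheme,
  configurable), "simple" (identity extended to IUPAC codes, an
  ambiguity scoring the mean over its expansion), BLOSUM62 for
  protein. Gaps on either side score the matrix minimum off-diagonal
  entry — a gap is treated as the lowest conservative substitution,
  since gap columns carry no reliable substitution model.
* **DNAW** `S(i) = γ(i, C(i)) / nseq`, the Weighted score with 1/0
  weights; DNA-only and bounded in [0, 1]. Note its cutoffs then sit
  near 1, so "most divergent" DNAW regions have the *lowest* scores in
  [0, 1] — values like 0.2 are strong divergence, not weak.
* **Entropy** `S(i) = −H(i)` with H the Shannon entropy of the column
  frequencies (gap included), in bits — the sequence-logo convention;
  the base is configurable and only rescales the track and its
  cutoffs.
* **Variability** `S(i) = 1 − D(i)`.

All four are invariant under sequence order, and higher always means
more conserved. They are *not* zero-centred — the robust cutoff step
absorbs that.

## Cutoffs and smoothing

`low, high = median(X) ∓ k·MAD` with `k = 1.4826 ≈ 1/Φ⁻¹(3/4)`, the
factor that makes k·MAD estimate one standard deviation under
normality. For very similar sequences most columns score identically
and the MAD is 0; the fallback spread is then the mean absolute
deviation about the mean, `MAD_mean`, still centred on the median for
continuity, and the high cutoff is disabled — only divergent regions
are callable in that regime. The same factor k margins both branches
for a single consistent definition (a mean-deviation-specific
consistency factor would be 1.2533; using k everywhere is deliberate
and configurable). Median of an even-length vector is the midpoint of
the central order statistics.

Smoothing is a hard low-pass in the Fourier domain: coefficients at
frequency index above `ceil(L / (2·window))` are zeroed and the inverse
transform's real part kept. The DC term always survives, so the mean is
preserved exactly and the filter is linear. `window` (default 10
columns, about the narrowest primer-scale feature worth calling) is the
approximate width of the smallest surviving feature. A hard truncation
rings near sharp edges; ringing dips cannot create spurious DNA
divergent regions because regions must also contain two putative SNPs,
but protein region boundaries can overshoot the raw signal by a few
columns.

## Calling rules

* **Putative SNP** (DNA only): raw score strictly below the low
  cutoff, at least one non-reference symbol, and *every* non-reference
  symbol present in ≥ 2 sequences — the strict reading that implies no
  SNP is callable with fewer than four sequences. Gap-only variation
  may qualify a column (configurable off). Synonymy and structural
  effect are out of scope.
* **Regions**: maximal runs of the *smoothed* track beyond a cutoff
  (below low → divergent; above high → conserved, when high exists);
  SNP status is decided on the *raw* track. DNA divergent runs with
  fewer than two SNPs are discarded; no further minimum length is
  imposed (configurable). The characteristic score is the mean raw
  score over the run. Lengths are bucketed <6 / 6–11 / >11 for
  reporting.

## Primer module

The default window is the divergent region plus 5 nt of flank, mapped
to ungapped reference coordinates and clamped to the sequence ends.
Measurements: length; GC% (full precision internally, integer-rounded
in reports); Tm by nearest-neighbor thermodynamics (unified parameter
set via Biopython, 50 mM Na⁺, 500 nM primer, no template excess), with
a Wallace-rule fallback; G/C count over the five 3'-terminal bases (the
common clamp convention — the clamp window length is a package choice);
repeats = any mononucleotide run ≥ 4 or dinucleotide motif ≥ 4 times;
self-dimer and hairpin ΔG as minimum nearest-neighbor stack sums
(SantaLucia 1998 ΔG°₃₇) over perfect complementary stretches — no
internal loops, bulges or initiation terms, so the values rank and
threshold candidates rather than predict structure. Grades: PASS at
40 ≤ GC% ≤ 60 (boundaries pass), Tm > 52 °C, clamp 2–3, dimer > −4 and
hairpin > −3 kcal/mol, no repeats; values just outside a threshold
(margins: 2 GC points, 1 °C, 0.5 kcal/mol, clamp off by one) grade
WARN, further out FAIL. Degenerate primers are deliberately not
designed. Published primer Tm values serve as order-of-magnitude
cross-checks only: the exact Tm formula behind them is not specified,
and our nearest-neighbor values land within ~1–2 °C.

## Synthetic data

The generator plants known structure: one random reference row, copied
to all sequences; inside designated blocks each column independently
(probability `variant_fraction`, default 0.5) receives one alternative
base in a uniformly sized subset of 2 to ⌊(nseq−1)/2⌋ non-reference
rows, so every planted column satisfies the two-copies SNP rule and the
reference stays the plurality symbol; optional terminal gap wedges
exercise end slicing. It emulates the frequency structure the caller
assumes — localised, multi-copy divergence on an otherwise identical
background — and deliberately **not** real evolution: no substitution
model, no rate heterogeneity, no indels inside the core, no
correlation between columns. Passing recovery tests therefore shows
the pipeline detects the signal class it defines, not that it is
calibrated for any particular gene family.

Test and acceptance runs use 8 sequences × 500 columns with three
planted blocks of lengths 6, 10 and 15 across 20 seeds — small enough
to run in seconds, large enough that the MAD fallback branch, the
smoothing bandwidth and the two-SNP rule are all genuinely exercised.

## Numerical and degenerate-input choices

* Cutoff degeneracy tolerance `tol = 1e-12` on the MAD decides the
  fallback branch; an all-constant track yields `low = high-less
  median` and calls nothing.
* Smoothing requires track length ≥ 4 and window ≥ 1.
* An all-gap column yields gap as consensus; gap reference columns in
  master mode score `gap_weight` under Weighted and the gap count
  fraction under DNAW.
* All floating-point output is serialised deterministically; the whole
  pipeline contains no randomness, so identical input and configuration
  give byte-identical JSON bundles.

## Known limitations

* Column independence: linked variation (haplotypes) is neither used
  nor reported.
* The hard spectral cutoff is one of many defensible smoothers; a
  tapered filter would trade edge ringing for wider transition bands.
* ΔG estimates ignore loop penalties and dangling ends; borderline
  dimer/hairpin grades deserve a dedicated thermodynamics tool.
* Protein conserved-region calling depends on the high cutoff existing,
  i.e. on the track having nonzero MAD.
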