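# Methods

## The question and the design

Reference-free transcriptome assembly has no ground truth, so the effect of
read pre-processing must be judged by comparing assemblies against each
other. `trimscope` implements that comparison as a pipeline of seven read
treatments over one read set, a reconstruction step per treatment, and a
panel of relative metrics: transfrag counts and N50, genomic
overlap/missing-annotation analysis, and the distribution of HSP ratios
compared across treatments with rank statistics.

## Read treatments

All treatments act per read, never reorder reads, and keep sequence and
quality strings in lockstep; paired-end inputs are re-synchronized
afterwards (a pair survives iff both mates survive; lone survivors become
singletons, which are kept in a separate stream so the retention accounting
stays exact).

| category  | treatment |
|-----------|-----------|
| untrimmed | identity |
| one       | 3′ quality trim, threshold Q20, min length 36 bp |
| two       | 3′ quality trim, threshold Q10, min length 36 bp |
| three     | adapter removal, then Q20 trim, min length 36 bp |
| four      | adapter removal, then Q10 trim, min length 36 bp |
| five      | adapter removal only, min length 36 bp |
| six       | discard reads with > 80 % of bases below Q10 |

Trimming semantics are deliberately simple and fully testable: bases are
removed from the 3′ end while the terminal base is *strictly below* the
threshold, stopping at the first base at or above it (internal low-quality
bases survive; the 5′ end is never touched). The whole-read filter of
category six follows the "discard if more than 80 % bad" reading rather
than a keep-if-≥p%-good convention; the minimum length applies after all
trimming in a category, and category six applies none. Adapter removal is
an ungapped scan for the leftmost position whose suffix matches an adapter
prefix (overlap ≥ 3, mismatch rate ≤ 0.1 — common adapter-trimmer
defaults, configurable).

## The synthetic experiment

The generator builds a toy genome (default 50 non-overlapping,
forward-strand genes on one contig; 1–4 exons; transcripts 0.5–3 kb, the
typical fungal mRNA range). Each transcript embeds one long open reading
frame flanked by 30–120 bp UTRs; the annotated protein is the conceptual
translation of the transcript's longest ORF (≥ 33 codons by construction).

Reads are 100 bp paired-end, 200,000 pairs. Per-base quality at read
position *i* is Normal(q5 − (q5 − q3)·i/(L−1), σ) rounded and clipped to
[2, 40], with q5 = 35, q3 = 12, σ = 1 — an early-Illumina profile whose
mean crosses Q20 around cycle 65, so Q20 trimming removes roughly the last
third of each read (the strict stop-at-first-good-base rule plus noise
leaves ~70 bp), while Q10 trimming removes only occasional terminal bases
(the 3′ mean of 12 sits above Q10). Each base is substituted with
probability 10^(−q/10), uniformly among the three alternatives — so the
realized error rate is exactly what the quality scores claim. Fragments
shorter than the read length run 3′ into the (TruSeq read-1) adapter.
Indels, quality miscalibration and strand-specific protocols are not
modeled.

Two generator choices deserve explanation:

**Expression** is log-normal (μ = 0, σ = 1.8), spanning roughly four
orders of magnitude — the dynamic range of bulk RNA-Seq — so a
low-expression tail of genes is genuinely undersampled.

**Finite library complexity.** Each transcript contributes a fixed pool of
distinct cDNA fragments (0.03 per bp — one distinct fragment start every
~33 bp; inserts Normal(200, 30)); sequencing resamples that pool. This
models the duplicate-heavy regime of deep, PCR-amplified early-Illumina
libraries: sequencing 200k pairs over a ~90 kb transcriptome yields
several-hundred-fold nominal coverage, but the *distinct-fragment* coverage
of a saturated gene is capped near 6× — the regime where reconstruction
contiguity is actually at stake. Without this cap, every moderately
expressed gene would be covered hundreds of times over and no trimming
treatment could possibly affect a coverage-based reconstruction; with it,
saturated genes sit just above the coverage-contiguity transition and
trimmed reads fall just below it, which is precisely the truncation and
fragmentation phenomenon the pipeline exists to measure. The insert mean of
2× the read length maximizes the contrast between an untrimmed pair
(~200 bp of contiguous coverage) and a Q20-trimmed pair (two ~70 bp pieces
with an interior gap).

## The oracle assembler

Because every simulated read knows its source transcript and interval,
assembly is replaced by interval arithmetic: each surviving (possibly
trimmed) read is projected onto the surviving portion of its true source
interval (bases read through into the adapter never map), and transfrags
are the maximal intervals with coverage ≥ 1 (gap closing 0 bp — the most
conservative mapping from coverage to transfrags; both configurable),
dropping intervals under 100 bp. A substitution error is retained in the
emitted sequence only where a single read covers the base; deeper positions
are taken as consensus-corrected. Genome alignments and protein HSPs are
then emitted directly from the truth: one alignment per transfrag at its
genomic span (identity reflecting retained errors, query coverage 100 %),
and one HSP per transfrag covering its transcript's coding region, with the
subject span in protein coordinates.

This oracle makes the consequence of every trimmed base exactly computable
and perfectly reproducible, which is what the evaluation needs. It is *not*
a de Bruijn graph assembler: it has no k-mer effects, no error-induced
bubbles, no benefit from read pairing across gaps, and no chimeras, so
passing results say that trimming removed coverage that the reconstruction
needed — they do not certify how any particular assembler's heuristics
respond to trimming. Real assemblies remain pluggable through the FASTA /
alignment-TSV / hit-table interfaces.

## Evaluation metrics

- **Deduplication** is exact, case-insensitive, full-sequence string
  identity, keeping the first representative; a transfrag and its reverse
  complement are *not* merged by default (a flag enables it), since
  collapsing them would silently change counts.
- **N50** is the standard descending-cumulative definition; ties resolve by
  the cumulative rule with no interpolation.
- **Alignment stringency** is ≥ 95 % identity *and* ≥ 95 % query coverage,
  both inclusive; one best location per transfrag (maximal score, ties by
  identity then smallest coordinate).
- **Overlap** between two assemblies requires the same target sequence and
  ≥ 1 bp intersection of half-open intervals, strand-agnostic by default
  (assemblers emit arbitrary strands). **Missing annotations** are the
  distinct CDS genes intersected by loci unique to the untrimmed assembly.
- **HSP ratio** = (subject span length) / (protein length), capped at 1.0.
  The numerator is the span on the protein rather than the alignment column
  count so the ratio reads directly as fraction of the protein recovered
  (a switch selects alignment length instead). The E-value cutoff is 1e-10
  inclusive. Unique-HSP counts use all distinct HSP tuples; the ratio
  distributions use the best HSP per (transfrag, protein) pair — maximal
  bitscore, ties by larger span — so one fragmented alignment cannot
  inflate n, while distinct transfrag pieces hitting the same protein each
  contribute their own (transfrag, protein) pair.

## Rank statistics

The Kruskal–Wallis statistic is computed with midrank ties and the tie
correction 1 − Σ(t³ − t)/(N³ − N); if all pooled values are identical the
statistic is defined as 0 with p = 1. The p-value is the χ²(k−1) upper
tail (via the regularized incomplete gamma function, as implemented in
scipy). Post hoc comparisons follow Conover's Fisher-LSD-on-ranks, the
procedure behind the common agricultural-statistics implementation: groups
*i*, *j* differ at level α iff

    |R̄ᵢ − R̄ⱼ| > t₍₁₋α/2, N−k₎ · sqrt(S² · (N−1−H)/(N−k) · (1/nᵢ + 1/nⱼ))

with S² the variance of the pooled ranks and H the tie-corrected
statistic; no multiple-testing adjustment is applied, matching that
procedure's default, with α = 0.01. Letters are assigned by
insert-and-absorb over groups ordered by descending mean rank (the best
group carries "a"); the display is verified against the significance
matrix by reconstruction, and (N−1−H) is clamped at zero in the degenerate
case where tie correction pushes H above N−1.

The optimal treatment is the one with the highest mean HSP ratio; among
treatments sharing a grouping letter with it (statistically
indistinguishable), the highest N50 wins.

## Problem sizes and determinism

The default experiment (50 genes, 200k pairs, three categories) runs in
well under a minute on one core; the test suite uses a 12-gene / 4k-pair
simulation for unit-level checks and runs the default experiment once for
the end-to-end assertions. All randomness flows from a single seed through
per-stage generators (genome and reads are independently reproducible);
identical seeds give byte-identical FASTQ/FASTA/GFF3/TSV outputs and
reports.

## Limitations

- The oracle's coverage model means trimming can only act through coverage
  loss; graph-level effects of errors and adapters on real assemblers
  (which can also *hurt* untrimmed assemblies) are out of scope, so the
  pipeline measures the cost of trimming, not its occasional benefit.
- Proteins are self-translations with no homology model: each transfrag
  maps to at most one protein, so unique-HSP counts scale with transfrag
  counts rather than database size.
- Genes are forward-strand and non-overlapping; no alternative splicing,
  no rRNA/intron contamination, no paralogy.
- The whole-read ConDeTri-style high-quality-stretch criterion is not
  reproduced; the implemented 3′ rule is the plain strict-threshold trim
  described above.
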