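# trimscope

**What does quality-score trimming cost a *de novo* transcriptome assembly?**

Quality trimming of Illumina RNA-Seq reads is routine before *de novo*
assembly, but the threshold choice is subjective and aggressive trimming
removes real coverage. `trimscope` measures that cost: it applies a panel of
read treatments (untrimmed, 3′ quality trimming at Q20/Q10, adapter removal,
whole-read quality filtering), reconstructs each treatment's transcriptome,
and scores the reconstructions against each other with the metrics a
reference-free study has to rely on:

- **unique transfrag counts and N50** after exact deduplication and a
  ≥ 100 bp length filter;
- **overlapping / unique genomic loci** between two assemblies (best
  alignments filtered at ≥ 95 % identity and ≥ 95 % query coverage), and
  **missing annotations** — annotated CDS genes covered only by the
  untrimmed assembly;
- the **HSP ratio**: for a high-scoring segment pair between a transfrag
  and an annotated protein, the protein span it covers divided by the full
  protein length. A ratio of 1.0 is a full-length reconstruction; the
  per-treatment distribution of ratios measures assembly completeness;
- a **tie-corrected Kruskal–Wallis** one-way analysis of variance across
  treatments, with **Conover rank-LSD** post hoc comparisons rendered as
  grouping letters at α = 0.01 (treatments sharing a letter are not
  statistically different).

Everything runs on synthetic data: the package simulates a toy genome with
spliced gene models, log-normally expressed transcripts, paired-end reads
with 3′-decaying quality, quality-driven substitution errors, adapter
read-through and finite library complexity. Because every read carries
exact provenance, assembly is replaced by a deterministic coverage-interval
oracle, so the effect of every trimmed base on the reconstruction is
exactly computable. Real assemblies, alignments and similarity-search hits
can be dropped in through the same file interfaces (FASTA, an 8-column
alignment TSV, 13-column BLAST-style tabular hits).

The audience is anyone planning read pre-processing for reference-free
transcriptomics: the pipeline's comparison of untrimmed against trimmed
subsets suggests a defensible threshold and identifies the optimal assembly
by mean HSP ratio with N50 as the tie-breaker.

## Worked example

```python
from trimscope import RunConfig, SimulationConfig, run_experiment

config = RunConfig(sim=SimulationConfig(seed=1))  # 50 genes, 200k read pairs
report = run_experiment(config)
print(report.to_tsv())
```

prints (seed 1):

```
# trimscope report (seed=1, config=3dff2bfc9fde)
# kruskal_wallis H=30.8472 df=2 p=2.00274e-07 alpha=0.01
category   reads_retained  unique_tf  n50   unique_hsp  ratio_n  median_hsp_ratio  mean_hsp_ratio  sd_hsp_ratio  group  missing_annotations
untrimmed  400000          61         1843  61          61       1.0000            0.8040          0.3256        a
one        400000          86         1443  86          86       0.5301            0.5585          0.3595        b      2
two        400000          61         1843  61          61       1.0000            0.8040          0.3256        a      0
```

Category *one* is Q20 trimming, *two* is Q10. Reading the table: Q20
trimming fragments the reconstruction (more, shorter transfrags: 86 vs 61,
N50 1443 vs 1843), halves the median protein recovery (0.53 vs 1.00), and
loses two annotated genes entirely (`missing_annotations`), while the mild
Q10 treatment is indistinguishable from untrimmed. The Kruskal–Wallis test
rejects equality of the three HSP-ratio distributions (p ≈ 2e-7) and the
letters separate Q20 (`b`) from untrimmed/Q10 (`a`) — quality trimming at
an aggressive threshold measurably degrades the assembly, and the
untrimmed assembly is selected as optimal.

The `examples/` directory holds short narrative scripts, one per
capability (simulation + treatments, assembly evaluation, post hoc
letters, the full experiment). A thin CLI mirrors the library:

```bash
trimscope simulate --out-dir data --seed 1
trimscope preprocess --category one --in1 data/reads_1.fastq --in2 data/reads_2.fastq --out-prefix q20
trimscope tf-stats --fasta transfrags.fasta
trimscope overlap --aln-a a.tsv --aln-b b.tsv --gff data/genes.gff3
trimscope hsp-ratio --hits hits.tsv
trimscope stats --ratios ratios.tsv --alpha 0.01
trimscope run --config run.yaml --out-dir results
```

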