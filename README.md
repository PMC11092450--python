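# isocell

Isoform-level analysis of long-read single-cell RNA-seq (Nanopore/PacBio):
assignment of tagged long reads to known and novel isoforms through a
sub-exon decomposition of each gene, per-cell gene- and transcript-level
count matrices, and a Dirichlet-multinomial test for differential transcript
usage (DTU) between cell populations. A ground-truth read simulator makes
the whole pipeline testable without external data.

Intended users: groups running long-read single-cell experiments who already
have barcode-tagged BAMs (e.g. from wf-single-cell, Iso-Seq, or Parse
pipelines) and want isoform-resolved quantification and population-level
transcript-usage statistics.

## Method in brief

**Sub-exon read assignment.** Each gene's exonic territory is partitioned at
every annotated exon boundary into non-overlapping sub-exons, so each
isoform is a binary vector over sub-exons. A read covers a sub-exon when it
overlaps > 60% of its length and skips it when it overlaps ≤ 20% while the
sub-exon lies inside the read's aligned span; truncated ends are neutral. An
isoform is compatible with a read unless the read covers a sub-exon the
isoform lacks or skips one it contains. Small sub-exons are excluded from
the decision with a gene-specific threshold escalated in 10 bp steps up to
min(80 bp, mean sub-exon length) until the mapping becomes unique. Read
coverage and observed splice junctions can refine the partition (enhanced
mode) or define it outright (annotation-free mode).

**Novel isoforms.** Reads incompatible with every known isoform are
clustered at pseudo-bulk level (batches of ≤ 1500; edge weight = agreement
fraction over jointly informative sub-exons; weighted Louvain communities);
each community's modal sub-exon pattern is a candidate isoform. After
remapping with a relaxed threshold and pruning redundant candidates,
isoforms with > 20 supporting reads are reported as novel.

**DTU statistics.** Per gene, transcript counts per cell follow
X_c ~ Multinomial(n_c, π_c) with π_c ~ Dirichlet(α); the population usage is
π̄_k = α_k / Σα and φ = 1/(1+Σα) is a mean-invariant over-dispersion.
Likelihood-ratio tests compare populations A and B at gene level
(H₀: π̄ᴬ = π̄ᴮ, χ² with K−1 df, group-specific φ) and per transcript (1 df),
after aggregating rare isoforms (pooled count ≤ 5% of the gene total) and
requiring > 20 reads per gene; p-values are Benjamini-Hochberg adjusted.
Isoform switching (different dominant isoform per population) is flagged
with effect size |π̄ᴬ_a − π̄ᴮ_a| + |π̄ᴬ_b − π̄ᴮ_b| for the two dominants.

## Worked example

Simulate two cell populations and run the pipeline end to end:

```bash
isocell simulate --genes 10 --cells 30 --seed 1 --out demo
isocell run --bam demo/reads.bam --gtf demo/known.gtf --mode enhanced --out demo/out
```

`run` prints the read-fate accounting (every input read is assigned to a
known isoform, a novel isoform, or the gene's uncategorized row — or dropped
with a reason; the categories always sum to the input):

```json
{
 "n_genes": 10,
 "n_novel_isoforms": 8,
 "read_fates": {
  "dropped": {},
  "known": 3316,
  "novel": 1237,
  "total": 4570,
  "uncategorized": 17
 }
}
```

Scoring against the simulation truth
(`isocell evaluate --truth demo --results demo/out --out demo/report.json`)
gives, for this seed:

```json
{
 "mapping_accuracy": 0.935,
 "novel_read_precision": 1.0,
 "novel_read_recall": 0.86,
 "novel_isoform_annotation_rate": 0.727,
 "gene_spearman": 1.0,
 "transcript_spearman": 0.831
}
```

i.e. 93.5% of reads land on their true isoform (a novel-read call counts as
correct only when the discovered isoform's sub-exon chain matches the
held-out truth isoform), every read flagged novel truly came from a held-out
isoform, and 8 of the 11 held-out isoforms were re-annotated (the rest were
too weakly expressed to clear the 20-read support rule). Pseudo-bulk gene
counts correlate perfectly with truth at this scale.

The DTU stage runs on the transcript matrix with a barcode→population map:

```bash
isocell dtu --counts demo/out --groups groups.tsv --out demo/dtu.csv --alpha 0.01
```

On the example above it reports 4 significant genes at adjusted p < 0.01,
all among the simulation's planted DTU genes (precision 1.0, recall 0.8 of
the 5 planted genes).

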