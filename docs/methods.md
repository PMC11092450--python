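# Methods

`isocell` quantifies isoform-level expression from long-read single-cell
RNA-seq and tests for differential transcript usage (DTU) between cell
populations. This note documents the models, the algorithmic decisions, and
the limits of what the test suite demonstrates.

## Sub-exon gene models

All isoforms of a gene are represented over one shared partition of the
gene's exonic territory into non-overlapping **sub-exons**: maximal intervals
bounded by any two adjacent exon boundaries across the gene's transcripts.
Each isoform is then a binary membership vector, and read-isoform
compatibility reduces to vector comparisons. Coordinates are 0-based
half-open internally; GTF's 1-based inclusive convention is converted only at
I/O boundaries.

Three construction modes:

* **annotation-only** — boundaries are exactly the union of annotated exon
  start/end positions.
* **enhanced** (default) — read evidence refines the annotated partition.
  New boundaries come from observed splice junctions supported by at least
  `junction_min_reads` reads (default 2) that are not annotated introns, and
  from sharp depth changes — a fold change of at least `fold_change`
  (default 5) between adjacent `window`-bp windows (default 10 bp), with the
  higher side above the coverage floor (default 5 reads). Unannotated
  regions above the floor become candidate novel sub-exons only when an edge
  is anchored by junction or depth-change evidence; uniform background
  coverage alone never creates exons. Every annotated boundary is retained,
  so enhancement is a strict refinement.
* **annotation-free** — above-floor coverage runs become exons, split by the
  same junction/depth-change boundaries, with one inferred transcript per
  expressed region.

The enhancement thresholds are package choices (exposed in the
configuration); sensible behavior, not optimality, is claimed for them.
Overlapping genes (strand ignored, since antisense overlaps still compete
for reads) are grouped into meta-genes so a read in a shared locus is scored
against every resident gene. The gene database serializes to versioned JSON
with sorted keys: identical inputs give byte-identical files.

## Read encoding and isoform assignment

For each primary alignment, reference-aligned blocks are taken from the
CIGAR; deletions of at most 30 bp are treated as aligned (nanopore
alignments are peppered with short deletions that should not erode exon
coverage). Each sub-exon gets a coverage fraction (overlapped bases /
length) and a state:

* **covered** — fraction > 0.6;
* **skipped** — fraction <= 0.2 *and* the sub-exon lies fully inside the
  read's aligned genomic span;
* **ambiguous** — in between, or a sub-exon only straddled by the span edge
  (where low coverage may be pure truncation);
* **unobserved** — outside the span.

5'/3' truncation therefore never counts as exon skipping. An isoform is
incompatible with a read iff the read covers a sub-exon the isoform lacks or
skips one it contains; ambiguous and unobserved states never veto.

Small sub-exons are noise-prone, so the minimum sub-exon length that enters
the compatibility decision is escalated per gene: starting at 0 bp and
rising in 10 bp steps up to min(80 bp, mean sub-exon length of the gene),
stopping at the first threshold that yields a unique isoform; failing
uniqueness, the first non-empty (multiple) mapping is kept, and the tie is
broken by fewest isoform sub-exons left uncovered by the read, then
lexicographic transcript id. A read incompatible with every annotated
isoform at every threshold is a **novel read**. Escalation deliberately
continues past empty sets: a read is declared novel only when no threshold
rescues it.

## Novel isoform discovery

Novel reads of a gene are clustered at pseudo-bulk level in batches of up to
1500 (ordered by aligned start). Edge weights between two reads are the
fraction of jointly informative sub-exons (covered or skipped in both) on
which their states agree; pairs with no jointly informative sub-exon get no
edge. Communities come from weighted-modularity Louvain at resolution 1.0
(igraph's multilevel implementation; igraph draws randomness from Python's
`random` module, which is seeded per call, so partitions are reproducible).
Each community's candidate isoform is the per-sub-exon mode of its reads'
states, with ties resolved toward inclusion — skips are more often
truncation or under-alignment artifacts than real exclusions. Candidates
identical to annotated isoforms are dropped. Reads still unexplained after a
batch form the next batch until no graph with edges can be built.

All novel reads are then remapped against candidates plus annotated isoforms
with the small-sub-exon threshold fixed at its cap (encouraging multiple
mappings), and candidates are scanned in ascending support order, removing
any whose reads all map to another retained candidate or annotated isoform.
A consequence worth knowing: two isoforms distinguishable only by sub-exons
shorter than the cap are merged at this step — the price of robustness to
truncation noise. A final isoform is reported as **novel** when more than 20
pseudo-bulk reads support it (evaluated after pruning); weaker candidates
stay **uncategorized** and their reads count toward the gene and its
"uncategorized" transcript row.

## Ambiguity across genes and counting

A read touching several genes receives one candidate per gene and the winner
is chosen by priority class — known isoform, then novel isoform, then mere
exon overlap — with ties broken by mapping score (fraction of the read's
aligned bases inside the isoform's exonic footprint), then lexicographic
gene id. Every processed read ends as exactly one assignment or a logged
drop (no exonic overlap, missing barcode), and the gene- and
transcript-level count matrices (MatrixMarket triplets keyed by cell
barcode) sum exactly to the number of resolved assignments. UMI
deduplication is off by default; enabling it collapses identical
(barcode, UMI, gene) triples. The local relative junction abundance
(LRJA) — reads supporting one junction over reads supporting any junction
involving the same upstream exon — is provided for junction-level follow-up.

## Dirichlet-multinomial DTU model

For a gene with K isoform columns, per-cell counts follow
X_c | pi_c ~ Multinomial(n_c, pi_c) with pi_c ~ Dirichlet(alpha), so X_c is
marginally Dirichlet-multinomial. The population usage is
pi_bar_k = alpha_k / sum(alpha) and phi = 1/(1 + sum(alpha)) is a
mean-invariant over-dispersion: phi near 0 means cells co-express isoforms
at similar proportions; large phi means each cell favors one isoform.

Isoform columns whose pooled count (over both populations) is at most 5% of
the gene's pooled total are aggregated into one "rare" column first, and
only genes with more than 20 pooled reads and at least two columns are
tested.

Maximum likelihood runs in log-alpha with analytic gradients (L-BFGS-B,
gradient tolerance 1e-6, 500 iterations, alpha clipped to [1e-8, 1e8] with a
boundary flag). The likelihood is extremely flat toward the multinomial
limit (sum(alpha) -> infinity) and a single line search can stall there, so
fits use a small multi-start around the moment estimate and keep the best
optimum; the constrained fits below do the same over five starting points.
This matters in practice: with single starts the gene-level test was
measurably anticonservative purely through under-converged null fits.

The gene-level test compares H1 (each population with free pi_bar and phi)
against H0 (shared pi_bar, population-specific phi via
alpha_g = pi_bar * (1/phi_g - 1)); twice the log-likelihood ratio is referred
to chi-square with K-1 degrees of freedom. The transcript-level test for
isoform k constrains only component k of pi_bar to be equal, leaving the
rest of the composition free per population (1 df); for K = 2 it coincides
with the gene test. The H0 parameterization and degrees of freedom are
package decisions — the hypotheses fix neither nuisance treatment nor df.
Benjamini-Hochberg adjustment is applied across tested genes at gene level
and across all gene x transcript tests at transcript level; the default call
threshold is adjusted p <= 0.01.

**Isoform switching** is flagged when the dominant non-rare isoform differs
between populations; its effect size is |pi_A(a) - pi_B(a)| +
|pi_A(b) - pi_B(b)| for the two dominant isoforms a and b (range [0, 2]),
reported only when a switch occurs. Optional nonparametric bootstrap over
cells (default 100 resamples where requested) supplies standard deviations
for the usage estimates.

## Simulator

The generator produces the study conditions end to end: synthetic multi-exon
genes (3–10 exons of 50–500 bp, introns 100–2000 bp, isoforms as distinct
exon subsets sharing first and last exon), per-gene concentrations
alpha_k ~ Gamma(shape 2, scale 2) — independent per population for planted
DTU genes (default half), shared otherwise — per-cell depth
lambda_c ~ Uniform(0, 15), n_c ~ Poisson(lambda_c), usage
pi_c ~ Dirichlet(alpha), counts Multinomial(n_c, pi_c). A configurable
fraction of isoforms (default 30%) is withheld from the emitted annotation
as ground-truth novel isoforms, with every gene keeping at least one known
isoform. Reads trace their transcript's exon chain, optionally 5'-truncated
(probability 0.3, exponential length with mean 200 bp) and perturbed by a
parametric indel model (deletions at a third of the ~1% total error rate;
substitutions and insertions do not move aligned blocks and are not modeled
explicitly), and are emitted as spliced BAM alignments with CB/UB tags plus
truth tags. Genes are simulated independently — no gene-gene correlation —
and error profiles are parametric rather than basecaller-derived, so
passing tests demonstrate correctness of the pipeline logic under the
generative model, not robustness to platform-specific artifacts such as
homopolymer errors or mapping ambiguity in repetitive genomes. A real GTF
can be substituted for the synthetic annotation.

## Problem sizes used in the checks

The scaled benchmark run (`scripts/acceptance.py`) uses 100 genes and 150
cells per population (~220k reads, a few minutes on one CPU) in place of the
full-scale design (1080 genes, 1000 cells per population, ~15M reads); the
in-suite variant uses 40 genes and 100 cells per population. Type-I error
of the gene-level test is measured over 1000 null replicates at 200 cells
per group. Because the parametric error model is cleaner than a basecaller
error profile, benchmark metrics here sit above the levels reported for
error-profile simulations; the test suite asserts them one-sidedly against
those levels.

## Known limitations

* Chimeric reads are assigned whole to a single gene; no split assignment.
* Secondary and supplementary alignments are ignored.
* Ambiguous-state sub-exons never veto compatibility at any threshold.
* No covariate adjustment in the DTU model (no Dirichlet regression).
* Novel isoforms distinguishable only below the relaxed sub-exon cap merge.
* Quality weighting of reads is not implemented.
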