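"""Ground-truth simulator for long-read single-cell RNA-seq.

Generates synthetic multi-isoform gene models, per-cell transcript usage and
sequencing depth, and nanopore-like aligned reads with cell barcode / UMI
tags, so every pipeline stage can be exercised against a known truth.

The generative model per gene and cell population:

* concentrations alpha_k ~ Gamma(shape 2, scale 2) for each of the gene's K
  isoforms; genes planted as differential-transcript-usage (DTU) genes draw
  independent alpha per population, the rest share one alpha;
* per cell, depth lambda_c ~ Uniform(0, 15), gene count n_c ~ Poisson(lambda_c),
  usage pi_c ~ Dirichlet(alpha), isoform counts x_c ~ Multinomial(n_c, pi_c);
* each count becomes one read tracing the isoform's exon chain, optionally
  5'-truncated and perturbed by a parametric substitution/indel error model
  (total rate ~1%, matching recent nanopore chemistry); reads are emitted as
  spliced BAM alignments with CB/UB tags plus truth tags.

A configurable fraction of isoforms (default 30%) is withheld from the
emitted "known" annotation and designated ground-truth novel isoforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .gtf import GeneModel, TranscriptModel, write_gtf

CHROM = "chrS"

DEFAULT_ERROR_RATE = 0.01  # total substitution+indel rate
DEFAULT_TRUNCATION_PROB = 0.3
DEFAULT_TRUNCATION_MEAN = 200.0  # bp, exponential
LAMBDA_MAX = 15.0
GAMMA_SHAPE = 2.0
GAMMA_SCALE = 2.0


@dataclass
class SimulationTruth:
    genes: dict[str, GeneModel]  # full annotation incl. held-out isoforms
    known: dict[str, GeneModel]  # emitted annotation
    held_out: set[tuple[str, str]]  # (gene_id, transcript_id)
    alpha: dict[tuple[str, str], np.ndarray]  # (gene, population) -> alpha
    dtu_genes: set[str]
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: read_id, cell_barcode, population, gene_id, transcript_id
    chrom_length: int = 0

    @property
    def barcodes(self) -> list[str]:
        return sorted(self.reads["cell_barcode"].unique())


def _random_gene(
    gene_id: str, start: int, rng: np.random.Generator,
    n_isoforms: int, n_exons_range=(3, 10),
    exon_len_range=(50, 500), intron_len_range=(100, 2000),
) -> GeneModel:
    """One synthetic gene: a chain of exons with isoforms as distinct exon
    subsets that always keep the first and last exon (shared TSS/TES keeps
    the isoforms distinguishable by internal structure, the common case for
    alternative splicing)."""
    n_exons = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    # enough internal exons that n_isoforms distinct subsets exist
    n_exons = max(n_exons, 3, int(np.ceil(np.log2(max(n_isoforms, 2)))) + 2)
    pos = start
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(gene_id, CHROM, strand)
    seen: set[tuple[int, ...]] = set()
    full = tuple(range(n_exons))
    patterns = [full]
    seen.add(full)
    attempts = 0
    while len(patterns) < n_isoforms and attempts < 1000:
        attempts += 1
        keep = [0] + [i for i in range(1, n_exons - 1) if rng.random() < 0.6] + [
            n_exons - 1
        ]
        key = tuple(keep)
        if len(keep) >= 2 and key not in seen:
            seen.add(key)
            patterns.append(key)
    for i, pat in enumerate(patterns):
        tid = f"{gene_id}-t{i + 1}"
        gene.transcripts[tid] = TranscriptModel(tid, [exons[j] for j in pat])
    return gene


def simulate_annotation(
    n_genes: int,
    seed: int,
    isoforms_per_gene: tuple[int, int] = (2, 5),
    holdout_fraction: float = 0.3,
    gene_gap: int = 5000,
) -> tuple[dict[str, GeneModel], dict[str, GeneModel], set[tuple[str, str]], int]:
    """Synthetic annotation plus a random held-out ("novel") isoform subset.

    Returns (full annotation, known annotation, held-out (gene, transcript)
    pairs, chromosome length).  The held-out count is
    round(holdout_fraction * total isoforms) subject to every gene retaining
    at least one known isoform.
    """
    rng = np.random.default_rng(seed)
    genes: dict[str, GeneModel] = {}
    pos = 1000
    for i in range(n_genes):
        gid = f"gene{i + 1:04d}"
        k = int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
        gene = _random_gene(gid, pos, rng, k)
        genes[gid] = gene
        pos = gene.span[1] + gene_gap
    all_pairs = [
        (gid, tid) for gid, g in sorted(genes.items()) for tid in sorted(g.transcripts)
    ]
    n_holdout = int(round(holdout_fraction * len(all_pairs)))
    held_out: set[tuple[str, str]] = set()
    order = rng.permutation(len(all_pairs))
    remaining = {gid: len(g.transcripts) for gid, g in genes.items()}
    for idx in order:
        if len(held_out) >= n_holdout:
            break
        gid, tid = all_pairs[idx]
        if remaining[gid] > 1:  # every gene keeps >= 1 known isoform
            held_out.add((gid, tid))
            remaining[gid] -= 1
    known = {}
    for gid, g in genes.items():
        kg = GeneModel(gid, g.chrom, g.strand)
        for tid, tr in g.transcripts.items():
            if (gid, tid) not in held_out:
                kg.transcripts[tid] = tr
        known[gid] = kg
    return genes, known, held_out, pos + 1000


def simulate_cell_counts(
    alpha: np.ndarray, n_cells: int, rng: np.random.Generator,
    lambda_max: float = LAMBDA_MAX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell totals, usages, and isoform counts for one gene.

    n_c ~ Poisson(U(0, lambda_max)), pi_c ~ Dirichlet(alpha),
    x_c ~ Multinomial(n_c, pi_c).  Returns (n, pi, x) with shapes
    (cells,), (cells, K), (cells, K).
    """
    lam = rng.uniform(0, lambda_max, n_cells)
    n = rng.poisson(lam)
    pi = rng.dirichlet(alpha, size=n_cells)
    x = np.array([rng.multinomial(nc, pc) for nc, pc in zip(n, pi)])
    return n, pi, x


def _truncate_exons(
    exons: list[tuple[int, int]], strand: str, cut: int
) -> list[tuple[int, int]]:
    """Remove ``cut`` exonic bases from the transcript's 5' end."""
    out = []
    remaining = cut
    order = exons if strand == "-" else exons[::-1]
    # walk from the 3' end keeping bases, trimming the 5'-most ones
    total = sum(e - s for s, e in exons)
    keep = max(total - cut, 0)
    if keep == 0:
        return []
    acc = 0
    for s, e in order:
        if acc >= keep:
            break
        take = min(e - s, keep - acc)
        if strand == "-":
            out.append((s, s + take))
        else:
            out.append((e - take, e))
        acc += take
    out.sort()
    del remaining
    return out


def _apply_indels(
    blocks: list[tuple[int, int]], rng: np.random.Generator, del_rate: float,
    max_del: int = 8,
) -> list[tuple[int, int]]:
    """Split blocks with short deletions at the given per-base rate."""
    if del_rate <= 0:
        return blocks
    out = []
    for s, e in blocks:
        n_del = rng.poisson(del_rate * (e - s))
        if n_del == 0:
            out.append((s, e))
            continue
        cuts = np.sort(rng.integers(s + 1, max(e - 1, s + 2), size=n_del))
        pos = s
        for c in cuts:
            dlen = int(rng.integers(1, max_del + 1))
            if c <= pos or c + dlen >= e:
                continue
            out.append((pos, int(c)))
            pos = int(c) + dlen
        if pos < e:
            out.append((pos, e))
    return [b for b in out if b[1] > b[0]]


def simulate_reads(
    truth_annotation: dict[str, GeneModel],
    known: dict[str, GeneModel],
    held_out: set[tuple[str, str]],
    n_cells: int,
    seed: int,
    dtu_fraction: float = 0.5,
    error_rate: float = DEFAULT_ERROR_RATE,
    truncation_prob: float = DEFAULT_TRUNCATION_PROB,
    truncation_mean: float = DEFAULT_TRUNCATION_MEAN,
    lambda_max: float = LAMBDA_MAX,
    gamma_shape: float = GAMMA_SHAPE,
    gamma_scale: float = GAMMA_SCALE,
    chrom_length: int = 0,
) -> tuple[SimulationTruth, list[dict]]:
    """Simulate reads for two cell populations.

    Returns the truth object and a list of per-read records (dicts with
    blocks and tags) ready for BAM emission.  Deletion events consume a third
    of the total error rate; substitutions and insertions do not move aligned
    blocks and are not modeled explicitly.
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(truth_annotation)
    n_dtu = int(round(dtu_fraction * len(gene_ids)))
    dtu_genes = set(
        np.array(gene_ids)[rng.permutation(len(gene_ids))[:n_dtu]].tolist()
    )
    alpha_map: dict[tuple[str, str], np.ndarray] = {}
    read_rows = []
    records = []
    read_counter = 0
    for pop in ("A", "B"):
        for gid in gene_ids:
            gene = truth_annotation[gid]
            tids = sorted(gene.transcripts)
            K = len(tids)
            if pop == "A" or gid in dtu_genes:
                alpha = rng.gamma(gamma_shape, gamma_scale, K)
                alpha = np.clip(alpha, 0.05, None)
            else:
                alpha = alpha_map[(gid, "A")]
            alpha_map[(gid, pop)] = alpha
            _, _, x = simulate_cell_counts(alpha, n_cells, rng, lambda_max)
            cells, isos = np.nonzero(x)
            for ci, ki in zip(cells, isos):
                bc = f"{pop}BC{ci + 1:04d}"
                tid = tids[ki]
                exons = gene.transcripts[tid].exons
                for _ in range(int(x[ci, ki])):
                    read_counter += 1
                    rid = f"read{read_counter:08d}"
                    blocks = list(exons)
                    if rng.random() < truncation_prob:
                        cut = int(rng.exponential(truncation_mean))
                        blocks = _truncate_exons(blocks, gene.strand, cut)
                    if not blocks:
                        continue  # fully degraded molecule, never sequenced
                    blocks = _apply_indels(blocks, rng, error_rate / 3.0)
                    if not blocks:
                        continue
                    umi = f"UMI{read_counter:08d}"
                    records.append({
                        "read_id": rid, "blocks": blocks, "cell_barcode": bc,
                        "umi": umi, "gene_id": gid, "transcript_id": tid,
                    })
                    read_rows.append((rid, bc, pop, gid, tid))
    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "cell_barcode", "population", "gene_id", "transcript_id"],
    )
    truth = SimulationTruth(
        genes=truth_annotation, known=known, held_out=held_out,
        alpha=alpha_map, dtu_genes=dtu_genes, reads=reads,
        chrom_length=chrom_length,
    )
    return truth, records


def write_bam(records: list[dict], path: str, chrom_length: int) -> None:
    """Emit read records as a coordinate-sorted, indexed BAM with CB/UB tags
    plus tg/tt truth tags."""
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": CHROM, "LN": int(chrom_length)}]}
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in records:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = rec["read_id"]
            a.reference_id = 0
            a.reference_start = rec["blocks"][0][0]
            a.mapping_quality = 60
            a.flag = 0
            cigar = []
            prev_end = None
            for s, e in rec["blocks"]:
                if prev_end is not None:
                    gap = s - prev_end
                    op = 3 if gap > 30 else 2  # N for introns, D for small dels
                    cigar.append((op, gap))
                cigar.append((0, e - s))
                prev_end = e
            a.cigartuples = cigar
            a.query_sequence = None
            a.set_tag("CB", rec["cell_barcode"])
            a.set_tag("UB", rec["umi"])
            a.set_tag("tg", rec["gene_id"])
            a.set_tag("tt", rec["transcript_id"])
            bam.write(a)
    pysam.sort("-o", path, unsorted)
    os.remove(unsorted)
    pysam.index(path)


def simulate_dataset(
    out_dir: str,
    n_genes: int = 100,
    n_cells: int = 150,
    seed: int = 1,
    isoforms_per_gene: tuple[int, int] = (2, 5),
    holdout_fraction: float = 0.3,
    dtu_fraction: float = 0.5,
    error_rate: float = DEFAULT_ERROR_RATE,
    truncation_prob: float = DEFAULT_TRUNCATION_PROB,
) -> SimulationTruth:
    """Full simulation: annotation, truth, tagged BAM and truth tables on
    disk (known.gtf, heldout.gtf, reads.bam, truth_reads.tsv,
    truth_dtu.tsv)."""
    os.makedirs(out_dir, exist_ok=True)
    full, known, held_out, chrom_len = simulate_annotation(
        n_genes, seed, isoforms_per_gene, holdout_fraction
    )
    truth, records = simulate_reads(
        full, known, held_out, n_cells, seed + 1,
        dtu_fraction=dtu_fraction, error_rate=error_rate,
        truncation_prob=truncation_prob, chrom_length=chrom_len,
    )
    write_gtf(os.path.join(out_dir, "known.gtf"), known.values())
    held_models = []
    for gid, g in sorted(full.items()):
        hm = GeneModel(gid, g.chrom, g.strand)
        for tid, tr in g.transcripts.items():
            if (gid, tid) in held_out:
                hm.transcripts[tid] = tr
        if hm.transcripts:
            held_models.append(hm)
    write_gtf(os.path.join(out_dir, "heldout.gtf"), held_models)
    write_bam(records, os.path.join(out_dir, "reads.bam"), chrom_len)
    truth.reads.to_csv(os.path.join(out_dir, "truth_reads.tsv"), sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(truth.dtu_genes)}).to_csv(
        os.path.join(out_dir, "truth_dtu.tsv"), sep="\t", index=False
    )
    return truth
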