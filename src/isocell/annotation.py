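"""Sub-exon gene models.

A gene's isoforms are represented over a shared partition of its exonic
territory into non-overlapping *sub-exons*: maximal intervals bounded by any
two adjacent exon boundaries across all of the gene's transcripts.  Every
isoform is then a binary membership vector over the sub-exons, which turns
read-to-isoform compatibility into vector comparisons.

Three construction modes are supported:

* annotation-only  — boundaries come solely from the GTF;
* enhanced         — read coverage and observed splice junctions refine the
                     annotated partition with novel boundaries and candidate
                     novel exons;
* annotation-free  — gene and exon structure inferred from coverage alone.

Overlapping genes are grouped into *meta-genes* so that reads falling in a
shared locus can be scored against every resident gene before assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .gtf import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1

DEFAULT_COVERAGE_FLOOR = 5
DEFAULT_FOLD_CHANGE = 5.0
DEFAULT_WINDOW = 10
DEFAULT_JUNCTION_MIN_READS = 2


class AnnotationError(ValueError):
    """Structured error for malformed or empty gene annotation input."""


@dataclass
class SubExonPartition:
    """Non-overlapping sub-exon intervals of one gene plus per-transcript
    binary membership vectors.

    Intervals are 0-based half-open, pairwise disjoint, sorted by start.
    ``transcripts[tid][j]`` is True iff sub-exon ``j`` lies inside one of
    transcript ``tid``'s exons.
    """

    gene_id: str
    chrom: str
    strand: str
    sub_exons: list[tuple[int, int]]
    transcripts: dict[str, np.ndarray]
    source: str = "annotation_only"

    @property
    def n_sub_exons(self) -> int:
        return len(self.sub_exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.sub_exons[0][0], self.sub_exons[-1][1])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.sub_exons], dtype=float)

    def transcript_footprint(self, tid: str) -> list[tuple[int, int]]:
        """Merged exonic intervals of one transcript, reconstructed from the
        membership vector."""
        ivs = [se for se, m in zip(self.sub_exons, self.transcripts[tid]) if m]
        return merge_intervals(ivs)

    def validate(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.sub_exons, self.sub_exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise AnnotationError(
                    f"{self.gene_id}: sub-exons not disjoint/sorted: "
                    f"({s1},{e1}) vs ({s2},{e2})"
                )
        for tid, vec in self.transcripts.items():
            if len(vec) != self.n_sub_exons:
                raise AnnotationError(f"{self.gene_id}/{tid}: vector length mismatch")


@dataclass
class MetaGene:
    """A maximal group of genomically overlapping genes treated as one unit."""

    meta_id: str
    gene_ids: list[str]
    chrom: str
    span: tuple[int, int]


@dataclass
class GeneDatabase:
    partitions: dict[str, SubExonPartition]
    meta_genes: list[MetaGene]
    build_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": SERIALIZATION_VERSION,
            "build_params": self.build_params,
            "partitions": {
                gid: {
                    "gene_id": p.gene_id,
                    "chrom": p.chrom,
                    "strand": p.strand,
                    "sub_exons": [list(iv) for iv in p.sub_exons],
                    "transcripts": {
                        tid: [int(b) for b in vec] for tid, vec in p.transcripts.items()
                    },
                    "source": p.source,
                }
                for gid, p in self.partitions.items()
            },
            "meta_genes": [
                {
                    "meta_id": m.meta_id,
                    "gene_ids": m.gene_ids,
                    "chrom": m.chrom,
                    "span": list(m.span),
                }
                for m in self.meta_genes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneDatabase":
        if d.get("version") != SERIALIZATION_VERSION:
            raise AnnotationError(f"unsupported database version {d.get('version')}")
        partitions = {
            gid: SubExonPartition(
                gene_id=pd["gene_id"],
                chrom=pd["chrom"],
                strand=pd["strand"],
                sub_exons=[tuple(iv) for iv in pd["sub_exons"]],
                transcripts={
                    tid: np.array(vec, dtype=bool)
                    for tid, vec in pd["transcripts"].items()
                },
                source=pd["source"],
            )
            for gid, pd in d["partitions"].items()
        }
        meta_genes = [
            MetaGene(m["meta_id"], m["gene_ids"], m["chrom"], tuple(m["span"]))
            for m in d["meta_genes"]
        ]
        return cls(partitions, meta_genes, d.get("build_params", {}))

    def save(self, path: str) -> None:
        # sorted keys + fixed separators -> byte-identical on identical content
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def load(cls, path: str) -> "GeneDatabase":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals, sorted and merged (adjacent
    intervals coalesce)."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def _partition_from_boundaries(
    exonic: list[tuple[int, int]], boundaries: set[int]
) -> list[tuple[int, int]]:
    """Split merged exonic intervals at every interior boundary point."""
    sub = []
    for s, e in exonic:
        cuts = sorted({s, e} | {b for b in boundaries if s < b < e})
        sub.extend(zip(cuts, cuts[1:]))
    return sub


def _membership(
    sub_exons: list[tuple[int, int]], exons: list[tuple[int, int]]
) -> np.ndarray:
    merged = merge_intervals(exons)
    vec = np.zeros(len(sub_exons), dtype=bool)
    for j, (s, e) in enumerate(sub_exons):
        vec[j] = any(ms <= s and e <= me for ms, me in merged)
    return vec


def build_partition_annotation_only(gene: GeneModel) -> SubExonPartition:
    """Partition a gene's exonic territory at the union of all exon
    boundaries of its transcripts.

    Raises AnnotationError on a gene with no exons or a malformed interval.
    """
    all_exons = [iv for tr in gene.transcripts.values() for iv in tr.exons]
    if not all_exons:
        raise AnnotationError(f"{gene.gene_id}: gene has zero exon records")
    for s, e in all_exons:
        if e <= s:
            raise AnnotationError(f"{gene.gene_id}: malformed interval ({s},{e})")
    boundaries = {p for s, e in all_exons for p in (s, e)}
    exonic = merge_intervals(all_exons)
    sub_exons = _partition_from_boundaries(exonic, boundaries)
    transcripts = {
        tid: _membership(sub_exons, tr.exons) for tid, tr in gene.transcripts.items()
    }
    part = SubExonPartition(
        gene.gene_id, gene.chrom, gene.strand, sub_exons, transcripts,
        source="annotation_only",
    )
    part.validate()
    return part


def _annotated_introns(partition: SubExonPartition) -> set[tuple[int, int]]:
    """Intron intervals already implied by the annotated transcripts."""
    introns: set[tuple[int, int]] = set()
    for tid in partition.transcripts:
        foot = partition.transcript_footprint(tid)
        for (_, e1), (s2, _) in zip(foot, foot[1:]):
            introns.add((e1, s2))
    return introns


def _sharp_change_points(
    coverage: np.ndarray,
    offset: int,
    fold_change: float,
    window: int,
    floor: float,
) -> list[int]:
    """Positions where mean depth between adjacent windows jumps by at least
    ``fold_change`` and the higher side clears the coverage floor."""
    n = len(coverage)
    if n < 2 * window:
        return []
    nwin = n // window
    means = coverage[: nwin * window].reshape(nwin, window).mean(axis=1)
    points = []
    for i in range(nwin - 1):
        lo, hi = sorted((means[i], means[i + 1]))
        if hi < floor:
            continue
        if hi >= fold_change * max(lo, 0.5):  # pseudocount guards div-by-zero
            points.append(offset + (i + 1) * window)
    return points


def enhance_partition(
    partition: SubExonPartition,
    coverage: np.ndarray,
    coverage_start: int,
    junctions: list[tuple[int, int, int]] | None = None,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
    fold_change: float = DEFAULT_FOLD_CHANGE,
    window: int = DEFAULT_WINDOW,
    junction_min_reads: int = DEFAULT_JUNCTION_MIN_READS,
) -> SubExonPartition:
    """Refine an annotated partition with read evidence.

    ``coverage`` is per-base depth starting at genomic position
    ``coverage_start``; ``junctions`` are (donor, acceptor, n_reads) splice
    gaps observed in the reads (0-based half-open intron intervals).

    New boundaries come from (i) junction positions supported by at least
    ``junction_min_reads`` reads that are not annotation boundaries, and
    (ii) sharp depth changes (>= ``fold_change`` between adjacent
    ``window``-bp windows).  Unannotated regions whose depth clears
    ``coverage_floor`` become candidate novel sub-exons.  Every original
    boundary is retained, so the result is a strict refinement.
    """
    if coverage is None or len(coverage) == 0 or coverage.max() == 0:
        logger.info("%s: empty coverage track, partition unchanged", partition.gene_id)
        return partition
    junctions = junctions or []

    old_boundaries = {p for s, e in partition.sub_exons for p in (s, e)}
    evidence: set[int] = set()
    for donor, acceptor, n in junctions:
        if n >= junction_min_reads and (donor, acceptor) not in _annotated_introns(
            partition
        ):
            evidence.update((donor, acceptor))
    evidence.update(
        _sharp_change_points(coverage, coverage_start, fold_change, window,
                             coverage_floor)
    )
    new_boundaries = old_boundaries | evidence

    annotated = merge_intervals(partition.sub_exons)
    # candidate novel exons: above-floor runs outside the annotated footprint,
    # kept only when an edge is anchored by junction or depth-change evidence
    # (uniform background coverage alone never creates exons)
    covered_mask = coverage >= coverage_floor
    novel_regions = []
    for s, e in _runs(covered_mask, coverage_start):
        for ns, ne in _subtract(s, e, annotated):
            if ne - ns < 1:
                continue
            for ps, pe in _partition_from_boundaries([(ns, ne)], new_boundaries):
                if ps in evidence or pe in evidence:
                    novel_regions.append((ps, pe))

    exonic = merge_intervals(annotated + novel_regions)
    sub_exons = _partition_from_boundaries(exonic, new_boundaries)
    transcripts = {
        tid: _membership(sub_exons, partition.transcript_footprint(tid))
        for tid in partition.transcripts
    }
    out = SubExonPartition(
        partition.gene_id, partition.chrom, partition.strand, sub_exons, transcripts,
        source="enhanced",
    )
    out.validate()
    return out


def _runs(mask: np.ndarray, offset: int) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean array as genomic intervals."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [(offset + int(s), offset + int(e)) for s, e in zip(starts, ends)]


def _subtract(
    s: int, e: int, regions: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Parts of [s, e) not covered by any of the sorted disjoint regions."""
    out = []
    pos = s
    for rs, re_ in regions:
        if re_ <= pos:
            continue
        if rs >= e:
            break
        if rs > pos:
            out.append((pos, rs))
        pos = max(pos, re_)
    if pos < e:
        out.append((pos, e))
    return out


def build_partition_annotation_free(
    chrom: str,
    coverage: np.ndarray,
    coverage_start: int,
    junctions: list[tuple[int, int, int]] | None = None,
    gene_id: str | None = None,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
    fold_change: float = DEFAULT_FOLD_CHANGE,
    window: int = DEFAULT_WINDOW,
    junction_min_reads: int = DEFAULT_JUNCTION_MIN_READS,
) -> SubExonPartition:
    """Infer a gene model from coverage alone.

    Above-floor coverage runs become exons; junction ends and sharp depth
    changes split them into sub-exons.  A single inferred transcript spanning
    every sub-exon is attached, and a synthetic gene id is assigned when none
    is given.
    """
    if coverage is None or len(coverage) == 0 or coverage.max() == 0:
        raise AnnotationError("no expressed region: all-zero coverage")
    junctions = junctions or []
    blocks = _runs(coverage >= coverage_floor, coverage_start)
    if not blocks:
        raise AnnotationError("no expressed region: no base clears coverage floor")
    boundaries: set[int] = set()
    for donor, acceptor, n in junctions:
        if n >= junction_min_reads:
            boundaries.update((donor, acceptor))
    boundaries.update(
        _sharp_change_points(coverage, coverage_start, fold_change, window,
                             coverage_floor)
    )
    sub_exons = _partition_from_boundaries(blocks, boundaries)
    gid = gene_id or f"novelgene-{chrom}-{sub_exons[0][0]}"
    transcripts = {f"{gid}-t1": np.ones(len(sub_exons), dtype=bool)}
    part = SubExonPartition(gid, chrom, "+", sub_exons, transcripts,
                            source="annotation_free")
    part.validate()
    return part


def group_meta_genes(partitions: dict[str, SubExonPartition]) -> list[MetaGene]:
    """Group genes whose spans overlap (transitively) into meta-genes.

    Strand is ignored: antisense overlapping genes still compete for the same
    reads and must be resolved jointly downstream.
    """
    by_chrom: dict[str, list[SubExonPartition]] = {}
    for p in partitions.values():
        by_chrom.setdefault(p.chrom, []).append(p)
    metas = []
    for chrom in sorted(by_chrom):
        parts = sorted(by_chrom[chrom], key=lambda p: p.span)
        cluster: list[SubExonPartition] = []
        cluster_end = -1
        for p in parts:
            s, e = p.span
            if cluster and s >= cluster_end:
                metas.append(_make_meta(chrom, cluster, len(metas)))
                cluster = []
                cluster_end = -1
            cluster.append(p)
            cluster_end = max(cluster_end, e)
        if cluster:
            metas.append(_make_meta(chrom, cluster, len(metas)))
    return metas


def _make_meta(chrom: str, cluster: list[SubExonPartition], idx: int) -> MetaGene:
    gids = sorted(p.gene_id for p in cluster)
    span = (min(p.span[0] for p in cluster), max(p.span[1] for p in cluster))
    return MetaGene(f"meta-{idx}", gids, chrom, span)


def build_database(
    genes: dict[str, GeneModel],
    build_params: dict | None = None,
) -> GeneDatabase:
    """Annotation-only database over a parsed GTF."""
    partitions = {
        gid: build_partition_annotation_only(g) for gid, g in sorted(genes.items())
    }
    metas = group_meta_genes(partitions)
    return GeneDatabase(partitions, metas, build_params or {"mode": "annotation_only"})


def partition_to_gene_model(partition: SubExonPartition) -> GeneModel:
    """Back-convert a partition to exon chains (for GTF export)."""
    gm = GeneModel(partition.gene_id, partition.chrom, partition.strand)
    for tid in sorted(partition.transcripts):
        gm.transcripts[tid] = TranscriptModel(tid, partition.transcript_footprint(tid))
    return gm
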