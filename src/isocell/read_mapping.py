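"""Read encoding against sub-exons and assignment to known isoforms.

Each spliced read is encoded as a vector of per-sub-exon states derived from
coverage fractions: a sub-exon is *covered* when the read overlaps more than
60% of its length, *skipped* when it overlaps at most 20% while lying inside
the read's aligned genomic span, *ambiguous* in between, and *unobserved*
outside the span (so 5'/3' truncation never counts as skipping).

Compatibility filtering excludes an isoform when the read covers a sub-exon
the isoform lacks or skips one it contains; sub-exons shorter than a minimum
length are excluded from the decision, and that minimum is escalated
gene-specifically (0 bp upward in 10 bp steps, capped at min(80 bp, mean
sub-exon length)) until the mapping becomes unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import SubExonPartition

# per-sub-exon states
COVERED = 0
SKIPPED = 1
AMBIGUOUS = 2
UNOBSERVED = 3

COVER_FRACTION = 0.6
SKIP_FRACTION = 0.2
THRESHOLD_STEP = 10
THRESHOLD_CAP = 80
DELETION_TOLERANCE = 30


class NoOverlapError(ValueError):
    """Read alignment does not overlap the gene span."""


@dataclass
class ReadEncoding:
    read_id: str
    gene_id: str
    states: np.ndarray  # int vector over sub-exons
    coverage_fractions: np.ndarray
    aligned_span: tuple[int, int]
    aligned_bases: int
    cell_barcode: str = ""
    umi: str = ""


@dataclass
class CompatibilitySet:
    read_id: str
    compatible_isoforms: set[str]
    threshold_used: int
    unmapped_exon_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_novel(self) -> bool:
        return len(self.compatible_isoforms) == 0


def merge_close_blocks(
    blocks: list[tuple[int, int]], max_gap: int = DELETION_TOLERANCE
) -> list[tuple[int, int]]:
    """Coalesce alignment blocks separated by small gaps.

    Nanopore alignments are peppered with short deletions; gaps of at most
    ``max_gap`` bases are treated as aligned so they do not erode sub-exon
    coverage fractions.
    """
    if not blocks:
        return []
    out = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s - out[-1][1] <= max_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(b) for b in out]


def encode_read(
    alignment_blocks: list[tuple[int, int]],
    partition: SubExonPartition,
    read_id: str = "",
    cell_barcode: str = "",
    umi: str = "",
    merge_deletions: bool = True,
) -> ReadEncoding:
    """Encode one read's aligned blocks as sub-exon states.

    ``alignment_blocks`` are sorted 0-based half-open genomic intervals of
    aligned (match) bases.  Raises NoOverlapError when the read does not
    touch the gene span.
    """
    if not alignment_blocks:
        raise NoOverlapError(f"{read_id}: no aligned blocks")
    blocks = merge_close_blocks(alignment_blocks) if merge_deletions else alignment_blocks
    span = (blocks[0][0], blocks[-1][1])
    gs, ge = partition.span
    if span[1] <= gs or span[0] >= ge:
        raise NoOverlapError(f"{read_id}: alignment outside gene {partition.gene_id}")

    starts = np.array([s for s, _ in partition.sub_exons])
    ends = np.array([e for _, e in partition.sub_exons])
    overlap = np.zeros(len(starts), dtype=float)
    for bs, be in blocks:
        overlap += np.clip(np.minimum(ends, be) - np.maximum(starts, bs), 0, None)
    fractions = overlap / (ends - starts)

    touches = (starts < span[1]) & (ends > span[0])
    fully_inside = (starts >= span[0]) & (ends <= span[1])
    states = np.full(len(starts), UNOBSERVED, dtype=np.int8)
    # a sub-exon only straddled by the span edge can look under-covered purely
    # from truncation, so "skipped" requires full containment in the span
    states[touches] = AMBIGUOUS
    states[touches & (fractions > COVER_FRACTION)] = COVERED
    states[fully_inside & (fractions <= SKIP_FRACTION)] = SKIPPED

    aligned_bases = sum(e - s for s, e in blocks)
    return ReadEncoding(
        read_id=read_id,
        gene_id=partition.gene_id,
        states=states,
        coverage_fractions=fractions,
        aligned_span=span,
        aligned_bases=aligned_bases,
        cell_barcode=cell_barcode,
        umi=umi,
    )


def filter_compatible(
    encoding: ReadEncoding,
    partition: SubExonPartition,
    min_subexon_len: float = 0,
    isoforms: dict[str, np.ndarray] | None = None,
) -> set[str]:
    """Transcripts the read is compatible with, ignoring sub-exons shorter
    than ``min_subexon_len``.

    An isoform is excluded iff among informative (long-enough) sub-exons the
    read covers one absent from the isoform or skips one present in it.
    Ambiguous and unobserved sub-exons never exclude.
    """
    isoforms = isoforms if isoforms is not None else partition.transcripts
    long_enough = partition.lengths >= min_subexon_len
    covered = (encoding.states == COVERED) & long_enough
    skipped = (encoding.states == SKIPPED) & long_enough
    out = set()
    for tid, vec in isoforms.items():
        if np.any(covered & ~vec) or np.any(skipped & vec):
            continue
        out.add(tid)
    return out


def dynamic_threshold_cap(partition: SubExonPartition) -> float:
    return min(THRESHOLD_CAP, float(partition.lengths.mean()))


def _thresholds(partition: SubExonPartition) -> list[float]:
    cap = dynamic_threshold_cap(partition)
    ts: list[float] = [0.0]
    t = float(THRESHOLD_STEP)
    while t <= cap:
        ts.append(t)
        t += THRESHOLD_STEP
    if ts[-1] < cap:
        ts.append(cap)
    return ts


def assign_with_dynamic_threshold(
    encoding: ReadEncoding,
    partition: SubExonPartition,
    isoforms: dict[str, np.ndarray] | None = None,
) -> CompatibilitySet:
    """Escalate the small-sub-exon exclusion length until the read maps
    uniquely.

    The first threshold producing a unique mapping wins; failing that, the
    first non-empty (multiple) mapping encountered; an empty set at every
    threshold flags the read as novel.
    """
    iso = isoforms if isoforms is not None else partition.transcripts
    first_multiple: tuple[set[str], float] | None = None
    chosen: tuple[set[str], float] | None = None
    for t in _thresholds(partition):
        compat = filter_compatible(encoding, partition, t, iso)
        if len(compat) == 1:
            chosen = (compat, t)
            break
        if compat and first_multiple is None:
            first_multiple = (compat, t)
    if chosen is None:
        chosen = first_multiple if first_multiple is not None else (set(), 0.0)
    compat, used = chosen
    unmapped = {
        tid: int(np.sum(iso[tid] & (encoding.states != COVERED))) for tid in compat
    }
    return CompatibilitySet(
        read_id=encoding.read_id,
        compatible_isoforms=compat,
        threshold_used=int(used),
        unmapped_exon_counts=unmapped,
    )


def break_ties(
    compatible: CompatibilitySet,
    encoding: ReadEncoding,
    partition: SubExonPartition,
    isoforms: dict[str, np.ndarray] | None = None,
) -> str:
    """Among multiple compatible isoforms pick the one with the fewest member
    sub-exons not covered by the read; remaining ties go to the
    lexicographically smallest transcript id."""
    iso = isoforms if isoforms is not None else partition.transcripts
    best = None
    for tid in sorted(compatible.compatible_isoforms):
        n_unmapped = int(np.sum(iso[tid] & (encoding.states != COVERED)))
        if best is None or n_unmapped < best[1]:
            best = (tid, n_unmapped)
    assert best is not None
    return best[0]
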