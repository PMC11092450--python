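"""Minimal GTF reading and writing for gene/transcript/exon models.

Only the features and attributes this package consumes (``gene_id``,
``transcript_id`` on ``exon`` records) are parsed.  Coordinates are converted
between GTF's 1-based inclusive convention and the 0-based half-open intervals
used internally at this boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of 0-based half-open exon intervals."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for t in self.transcripts.values() for s, _ in t.exons]
        ends = [e for t in self.transcripts.values() for _, e in t.exons]
        return (min(starts), max(ends))


def parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str) -> dict[str, GeneModel]:
    """Parse exon records of a GTF file into GeneModel objects.

    Returns a dict keyed by gene_id.  Exons are sorted by start within each
    transcript.  Records without gene_id/transcript_id are skipped.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            a = parse_attributes(attrs)
            gid, tid = a.get("gene_id"), a.get("transcript_id")
            if gid is None or tid is None:
                continue
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            if e <= s:
                raise ValueError(f"malformed exon interval {start}-{end} for {gid}")
            gene = genes.setdefault(gid, GeneModel(gid, chrom, strand))
            tr = gene.transcripts.setdefault(tid, TranscriptModel(tid))
            tr.exons.append((s, e))
    for gene in genes.values():
        for tr in gene.transcripts.values():
            tr.exons.sort()
    return genes


def write_gtf(path: str, genes: Iterable[GeneModel], source: str = "isocell") -> None:
    """Write gene models as gene/transcript/exon GTF records (1-based)."""
    with open(path, "w") as fh:
        for gene in genes:
            gs, ge = gene.span
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gs + 1}\t{ge}\t.\t{gene.strand}\t.\t"
                f'gene_id "{gene.gene_id}";\n'
            )
            for tid in sorted(gene.transcripts):
                tr = gene.transcripts[tid]
                ts = min(s for s, _ in tr.exons)
                te = max(e for _, e in tr.exons)
                base = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{gene.strand}\t.\t{base}\n"
                )
                for s, e in tr.exons:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{base}\n"
                    )
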