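"""Ambiguity resolution across genes and per-cell count matrices.

A read overlapping several genes (overlapping loci or chimeric alignments)
gets one candidate per gene; the winner is chosen by priority class
(known isoform > novel isoform > exon-only) and, within a class, by mapping
score — the fraction of the read's aligned bases falling inside the
isoform's exonic footprint.  Resolved assignments are tallied into gene x
cell and transcript x cell sparse matrices; reads of under-supported novel
candidates count toward the gene and its "uncategorized" transcript row, so
read totals are conserved exactly.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

PRIORITY = {"known": 0, "novel": 1, "exon_only": 2}

UNCATEGORIZED = "uncategorized"


@dataclass
class IsoformAssignment:
    read_id: str
    cell_barcode: str
    gene_id: str
    isoform_id: str  # transcript id, novel id, or "uncategorized"
    mapping_score: float
    priority_class: str  # known | novel | exon_only
    umi: str = ""


@dataclass
class CountMatrices:
    gene_counts: sp.csr_matrix  # genes x cells
    transcript_counts: sp.csr_matrix  # transcripts x cells
    barcodes: list[str]
    genes: list[str]
    transcripts: pd.DataFrame  # columns: feature_id, gene_id, feature_type
    dropped: dict[str, int] = field(default_factory=dict)


def mapping_score(
    alignment_blocks: list[tuple[int, int]], footprint: list[tuple[int, int]]
) -> float:
    """Fraction of the read's aligned bases inside the isoform footprint."""
    total = sum(e - s for s, e in alignment_blocks)
    if total == 0:
        raise ValueError("read has zero aligned bases")
    inside = 0
    for bs, be in alignment_blocks:
        for fs, fe in footprint:
            inside += max(0, min(be, fe) - max(bs, fs))
    return inside / total


def resolve_multi_gene(candidates: list[IsoformAssignment]) -> IsoformAssignment:
    """Pick one assignment for a read seen in several genes.

    Highest priority class first (known > novel > exon-only), then highest
    mapping score, then lexicographically smallest gene id.
    """
    if not candidates:
        raise ValueError("no candidates to resolve")
    return min(
        candidates,
        key=lambda a: (PRIORITY[a.priority_class], -a.mapping_score, a.gene_id),
    )


def lrja(junction_reads: int, upstream_exon_junction_reads: int) -> float | None:
    """Local relative junction abundance: reads supporting one junction over
    reads supporting any junction involving the same upstream exon.

    Returns None for 0/0 (junction unobservable)."""
    if junction_reads < 0 or upstream_exon_junction_reads < junction_reads:
        raise ValueError(
            f"invalid junction counts {junction_reads}/{upstream_exon_junction_reads}"
        )
    if upstream_exon_junction_reads == 0:
        return None
    return junction_reads / upstream_exon_junction_reads


def build_matrices(
    assignments: list[IsoformAssignment],
    barcodes: list[str],
    genes: list[str] | None = None,
    dedup_umi: bool = False,
) -> CountMatrices:
    """Tally resolved assignments into gene- and transcript-level matrices.

    Every assignment increments exactly one gene cell and one transcript
    cell ("uncategorized" rows absorb exon-only reads and reads of
    under-supported novel candidates), so both matrices sum to the number of
    counted assignments.  Assignments with barcodes outside the whitelist
    are dropped and counted in ``dropped``.
    """
    bc_index = {b: i for i, b in enumerate(barcodes)}
    kept: list[IsoformAssignment] = []
    dropped = {"barcode_not_in_whitelist": 0, "duplicate_umi": 0}
    seen_umi: set[tuple[str, str, str]] = set()
    for a in assignments:
        if a.cell_barcode not in bc_index:
            dropped["barcode_not_in_whitelist"] += 1
            continue
        if dedup_umi and a.umi:
            key = (a.cell_barcode, a.umi, a.gene_id)
            if key in seen_umi:
                dropped["duplicate_umi"] += 1
                continue
            seen_umi.add(key)
        kept.append(a)

    gene_ids = sorted(set(genes or []) | {a.gene_id for a in kept})
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    tx_keys = sorted({(a.gene_id, a.isoform_id) for a in kept})
    tx_rows = []
    tx_index: dict[tuple[str, str], int] = {}
    for gid, iso in tx_keys:
        tx_index[(gid, iso)] = len(tx_rows)
        ftype = (
            "uncategorized" if iso == UNCATEGORIZED
            else ("novel_isoform" if "-novel-" in iso else "known_isoform")
        )
        tx_rows.append({"feature_id": f"{gid}:{iso}", "gene_id": gid,
                        "isoform_id": iso, "feature_type": ftype})
    tx_frame = pd.DataFrame(
        tx_rows, columns=["feature_id", "gene_id", "isoform_id", "feature_type"]
    )

    g_mat = sp.dok_matrix((len(gene_ids), len(barcodes)), dtype=np.int64)
    t_mat = sp.dok_matrix((len(tx_frame), len(barcodes)), dtype=np.int64)
    for a in kept:
        ci = bc_index[a.cell_barcode]
        g_mat[gene_index[a.gene_id], ci] += 1
        t_mat[tx_index[(a.gene_id, a.isoform_id)], ci] += 1

    return CountMatrices(
        gene_counts=g_mat.tocsr(),
        transcript_counts=t_mat.tocsr(),
        barcodes=list(barcodes),
        genes=gene_ids,
        transcripts=tx_frame,
        dropped=dropped,
    )


def write_matrices(cm: CountMatrices, out_dir: str) -> None:
    """Write 10x-style MatrixMarket triplets for both levels plus a per-read
    friendly features table."""
    for level, mat, feats in (
        ("gene", cm.gene_counts, pd.DataFrame({"feature_id": cm.genes})),
        ("transcript", cm.transcript_counts, cm.transcripts),
    ):
        d = os.path.join(out_dir, level)
        os.makedirs(d, exist_ok=True)
        with gzip.open(os.path.join(d, "matrix.mtx.gz"), "wb") as fh:
            scipy.io.mmwrite(fh, sp.coo_matrix(mat))
        with gzip.open(os.path.join(d, "barcodes.tsv.gz"), "wt") as fh:
            fh.write("\n".join(cm.barcodes) + "\n")
        feats.to_csv(
            os.path.join(d, "features.tsv.gz"),
            sep="\t", index=False, header=False, compression="gzip",
        )


def read_transcript_matrix(out_dir: str) -> tuple[pd.DataFrame, list[str]]:
    """Load the transcript-level triplet back as a dense counts frame
    (features x cells) plus the barcode list."""
    d = os.path.join(out_dir, "transcript")
    with gzip.open(os.path.join(d, "matrix.mtx.gz"), "rb") as fh:
        mat = scipy.io.mmread(fh).tocsr()
    with gzip.open(os.path.join(d, "barcodes.tsv.gz"), "rt") as fh:
        barcodes = fh.read().split()
    feats = pd.read_csv(
        os.path.join(d, "features.tsv.gz"), sep="\t", header=None,
        names=["feature_id", "gene_id", "isoform_id", "feature_type"],
    )
    frame = pd.DataFrame(mat.toarray(), index=feats["feature_id"], columns=barcodes)
    frame.index.name = None
    return pd.concat([feats.set_index("feature_id"), frame], axis=1), barcodes
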