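"""Evaluation of pipeline outputs against simulation ground truth.

Metrics mirror the standard benchmarks for long-read isoform pipelines:
per-read mapping accuracy over known and novel isoforms (a novel-read call
counts as correct when its discovered isoform's sub-exon chain matches the
held-out truth isoform), precision/recall/F1 of the per-read known-vs-novel
classification, the novel isoform annotation rate (reported novel isoforms
over ground-truth novel isoforms), pseudo-bulk quantification agreement
(Spearman correlation and median absolute percentage error at gene and
known-transcript level), and DTU precision/recall against the planted DTU
gene set at adjusted p < 0.01.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .annotation import GeneDatabase, _membership
from .simulate import SimulationTruth


def _f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(
    truth: SimulationTruth,
    out_dir: str,
    dtu_gene_table: pd.DataFrame | None = None,
    dtu_alpha: float = 0.01,
) -> dict:
    """Compare one pipeline run against its simulation truth."""
    assignments = pd.read_csv(os.path.join(out_dir, "assignments.tsv"), sep="\t")
    novel_tab = pd.read_csv(
        os.path.join(out_dir, "novel_isoforms.tsv"), sep="\t",
        dtype={"membership": str},
    )
    db = GeneDatabase.load(os.path.join(out_dir, "genes.db.json"))

    tr = truth.reads
    if tr["read_id"].duplicated().any():
        raise ValueError("duplicated read ids in truth table")
    pred = assignments.set_index("read_id")
    missing = ~tr["read_id"].isin(pred.index)

    # truth membership vectors of held-out isoforms over each gene's partition
    truth_novel_membership: dict[tuple[str, str], str] = {}
    for gid, tid in truth.held_out:
        part = db.partitions.get(gid)
        if part is None:
            continue
        vec = _membership(part.sub_exons, truth.genes[gid].transcripts[tid].exons)
        truth_novel_membership[(gid, tid)] = "".join("1" if b else "0" for b in vec)
    discovered = {
        (r.gene_id, r.isoform_id): (r.membership, r.category)
        for r in novel_tab.itertuples()
    }

    is_truth_novel = tr.apply(
        lambda r: (r["gene_id"], r["transcript_id"]) in truth.held_out, axis=1
    ).to_numpy()

    correct = np.zeros(len(tr), dtype=bool)
    pred_novel = np.zeros(len(tr), dtype=bool)
    for i, row in enumerate(tr.itertuples()):
        if missing.iloc[i]:
            continue
        p = pred.loc[row.read_id]
        if p["priority_class"] != "known":
            pred_novel[i] = True
        if not is_truth_novel[i]:
            correct[i] = (
                p["priority_class"] == "known"
                and p["gene_id"] == row.gene_id
                and p["isoform_id"] == row.transcript_id
            )
        else:
            if p["priority_class"] == "novel" and p["gene_id"] == row.gene_id:
                mem, _cat = discovered.get((p["gene_id"], p["isoform_id"]), ("", ""))
                correct[i] = mem == truth_novel_membership.get(
                    (row.gene_id, row.transcript_id)
                )

    tp = int(np.sum(pred_novel & is_truth_novel))
    fp = int(np.sum(pred_novel & ~is_truth_novel))
    fn = int(np.sum(~pred_novel & is_truth_novel))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0

    n_reported_novel = int((novel_tab["category"] == "novel").sum())
    annotation_rate = (
        n_reported_novel / len(truth.held_out) if truth.held_out else np.nan
    )

    # pseudo-bulk quantification
    truth_gene = tr.groupby("gene_id").size()
    pred_gene = assignments.groupby("gene_id").size()
    genes = sorted(set(truth_gene.index) | set(pred_gene.index))
    tg = truth_gene.reindex(genes, fill_value=0).to_numpy(dtype=float)
    pg = pred_gene.reindex(genes, fill_value=0).to_numpy(dtype=float)
    gene_spearman = float(spearmanr(tg, pg).statistic)
    nz = tg > 0
    gene_mape = float(np.median(np.abs(pg[nz] - tg[nz]) / tg[nz]))

    known_pairs = sorted(
        (gid, tid) for gid, g in truth.known.items() for tid in g.transcripts
    )
    truth_tx = tr[~is_truth_novel].groupby(["gene_id", "transcript_id"]).size()
    known_assign = assignments[assignments["priority_class"] == "known"]
    pred_tx = known_assign.groupby(["gene_id", "isoform_id"]).size()
    tt = np.array([truth_tx.get(p, 0) for p in known_pairs], dtype=float)
    pt = np.array([pred_tx.get(p, 0) for p in known_pairs], dtype=float)
    tx_spearman = float(spearmanr(tt, pt).statistic)
    nz = tt > 0
    tx_mape = float(np.median(np.abs(pt[nz] - tt[nz]) / tt[nz]))

    report = {
        "n_truth_reads": int(len(tr)),
        "n_assigned_reads": int(len(assignments)),
        "mapping_accuracy": float(np.mean(correct)),
        "novel_read_precision": precision,
        "novel_read_recall": recall,
        "novel_read_f1": _f1(precision, recall),
        "novel_isoform_annotation_rate": float(annotation_rate),
        "gene_spearman": gene_spearman,
        "gene_mape": gene_mape,
        "transcript_spearman": tx_spearman,
        "transcript_mape": tx_mape,
    }

    if dtu_gene_table is not None and len(dtu_gene_table):
        called = set(
            dtu_gene_table.loc[dtu_gene_table["padj"] < dtu_alpha, "gene_id"]
        )
        truth_dtu = truth.dtu_genes
        tp_d = len(called & truth_dtu)
        prec_d = tp_d / len(called) if called else 0.0
        rec_d = tp_d / len(truth_dtu) if truth_dtu else 0.0
        report.update({
            "dtu_precision": prec_d,
            "dtu_recall": rec_d,
            "dtu_f1": _f1(prec_d, rec_d),
            "n_dtu_called": len(called),
        })
    return report
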