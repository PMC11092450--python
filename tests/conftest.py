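import numpy as np
import pytest

from isocell.annotation import SubExonPartition, build_partition_annotation_only
from isocell.gtf import GeneModel, TranscriptModel


def make_gene(gene_id: str, transcripts: dict[str, list[tuple[int, int]]],
              chrom: str = "chr1", strand: str = "+") -> GeneModel:
    g = GeneModel(gene_id, chrom, strand)
    for tid, exons in transcripts.items():
        g.transcripts[tid] = TranscriptModel(tid, sorted(exons))
    return g


def random_toy_gene(rng: np.random.Generator, max_subexons: int = 6,
                    max_isoforms: int = 5) -> SubExonPartition:
    """A random small gene: a chain of exons and isoforms as random distinct
    exon subsets."""
    n_exons = int(rng.integers(2, max_subexons + 1))
    pos = int(rng.integers(0, 1000))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(5, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(50, 500))
    n_iso = int(rng.integers(1, max_isoforms + 1))
    seen = set()
    txs = {}
    for i in range(n_iso):
        keep = tuple(sorted(rng.choice(n_exons, size=int(rng.integers(1, n_exons + 1)),
                                       replace=False).tolist()))
        if keep in seen:
            continue
        seen.add(keep)
        txs[f"t{i + 1}"] = [exons[j] for j in keep]
    return build_partition_annotation_only(make_gene("toy", txs))


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small simulated dataset with one enhanced-mode pipeline run,
    shared across tests that only inspect the outputs."""
    from isocell.pipeline import PipelineConfig, run_pipeline
    from isocell.simulate import simulate_dataset

    out = tmp_path_factory.mktemp("smallrun")
    truth = simulate_dataset(str(out / "sim"), n_genes=12, n_cells=40, seed=11)
    summary = run_pipeline(
        str(out / "sim" / "reads.bam"), str(out / "sim" / "known.gtf"),
        str(out / "pipe"), PipelineConfig(mode="enhanced"),
    )
    return {"truth": truth, "sim_dir": out / "sim", "out_dir": out / "pipe",
            "summary": summary}
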