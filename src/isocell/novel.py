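"""Novel isoform discovery from reads unmappable to known isoforms.

Novel reads of a gene are clustered at pseudo-bulk level: a read-read graph
is built in batches (default 1500 reads) with edge weights equal to the
fraction of jointly informative sub-exons (covered or skipped in both reads)
on which the two reads agree; Louvain communities of that graph are candidate
novel isoforms, each annotated by the per-sub-exon mode of its reads'
encodings.  Candidates duplicating annotated isoforms are dropped, reads are
remapped with the relaxed small-sub-exon threshold, and redundant candidates
(whose reads all map elsewhere too) are pruned.  Final isoforms supported by
more than 20 pseudo-bulk reads are reported as novel; weaker ones stay
uncategorized.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .annotation import SubExonPartition
from .read_mapping import (
    COVERED,
    SKIPPED,
    CompatibilitySet,
    ReadEncoding,
    break_ties,
    dynamic_threshold_cap,
    filter_compatible,
)

DEFAULT_BATCH_SIZE = 1500
NOVEL_SUPPORT_MIN = 20  # strictly more than this many reads -> "novel"
DEFAULT_SEED = 42


@dataclass
class NovelIsoform:
    isoform_id: str
    membership: np.ndarray  # bool over sub-exons
    support_reads: int = 0
    category: str = "uncategorized"  # "novel" | "uncategorized"


@dataclass
class NovelReadGraph:
    """Weighted read-similarity graph stored as flat edge arrays.

    Kept deliberately lean: batches of up to 1500 reads produce near-complete
    graphs (~10^6 edges), so adjacency dictionaries are avoided.
    """

    read_ids: list[str] = field(default_factory=list)
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int32))
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nodes(self) -> int:
        return len(self.read_ids)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight(self, a: str, b: str) -> float | None:
        ia, ib = self.read_ids.index(a), self.read_ids.index(b)
        key = (min(ia, ib), max(ia, ib))
        for (i, j), w in zip(self.edges, self.weights):
            if (i, j) == key:
                return float(w)
        return None


def _informative_matrices(encodings: list[ReadEncoding]) -> tuple[np.ndarray, np.ndarray]:
    states = np.stack([e.states for e in encodings])
    return states == COVERED, states == SKIPPED


def build_read_graph(
    encodings: list[ReadEncoding], batch_size: int = DEFAULT_BATCH_SIZE
) -> NovelReadGraph:
    """Weighted read-similarity graph over the first ``batch_size`` novel
    reads (ordered by aligned start).

    Edge weight = agreeing jointly-informative sub-exons / jointly-informative
    sub-exons, where informative means covered or skipped; pairs with no
    jointly informative sub-exon get no edge.
    """
    if len(encodings) < 2:
        return NovelReadGraph()
    batch = sorted(encodings, key=lambda e: (e.aligned_span, e.read_id))[:batch_size]
    cov, skp = _informative_matrices(batch)
    c = cov.astype(np.float64)
    k = skp.astype(np.float64)
    agree = c @ c.T + k @ k.T
    joint = (c + k) @ (c + k).T
    n = len(batch)
    iu, ju = np.triu_indices(n, k=1)
    mask = joint[iu, ju] > 0
    edges = np.column_stack([iu[mask], ju[mask]]).astype(np.int32)
    weights = agree[iu[mask], ju[mask]] / joint[iu[mask], ju[mask]]
    return NovelReadGraph([e.read_id for e in batch], edges, weights)


def detect_communities(
    graph: NovelReadGraph, seed: int = DEFAULT_SEED
) -> list[set[str]]:
    """Weighted-modularity Louvain partition (resolution 1.0, seeded).

    Runs igraph's multilevel (Louvain) implementation; igraph draws its
    random numbers from Python's ``random`` module, which is seeded here so
    the partition is deterministic given (graph, seed)."""
    if graph.n_nodes == 0:
        return []
    if graph.n_edges == 0:
        comms = [{rid} for rid in graph.read_ids]
        return sorted(comms, key=min)
    g = ig.Graph(graph.n_nodes, [tuple(e) for e in graph.edges])
    state = random.getstate()
    try:
        random.seed(seed)
        clustering = g.community_multilevel(
            weights=graph.weights.tolist(), resolution=1.0
        )
    finally:
        random.setstate(state)
    comms = [
        {graph.read_ids[i] for i in members}
        for members in clustering
        if members
    ]
    return sorted(comms, key=min)


def consensus_annotation(community: list[ReadEncoding]) -> np.ndarray:
    """Per-sub-exon mode of the community's informative states.

    Membership is 1 where covered is at least as frequent as skipped among
    informative reads (ties favor inclusion: skips are more often truncation
    artifacts than real exclusions); sub-exons informative in no read get 0.
    """
    cov, skp = _informative_matrices(community)
    n_cov = cov.sum(axis=0)
    n_skp = skp.sum(axis=0)
    membership = (n_cov >= n_skp) & (n_cov + n_skp > 0)
    return membership


def categorize_support(isoform: NovelIsoform,
                       support_min: int = NOVEL_SUPPORT_MIN) -> str:
    return "novel" if isoform.support_reads > support_min else "uncategorized"


def _dedupe_candidates(
    candidates: list[np.ndarray], partition: SubExonPartition
) -> list[np.ndarray]:
    annotated = {tuple(int(b) for b in v) for v in partition.transcripts.values()}
    seen: set[tuple[int, ...]] = set()
    out = []
    for vec in candidates:
        key = tuple(int(b) for b in vec)
        if key in annotated or key in seen or not any(key):
            continue
        seen.add(key)
        out.append(vec)
    return out


def discover_novel_isoforms(
    encodings: list[ReadEncoding],
    partition: SubExonPartition,
    batch_size: int = DEFAULT_BATCH_SIZE,
    seed: int = DEFAULT_SEED,
    support_min: int = NOVEL_SUPPORT_MIN,
) -> tuple[list[NovelIsoform], dict[str, str]]:
    """Full novel-isoform stage for one gene.

    Returns the final isoform list (novel + uncategorized) and a read_id ->
    isoform_id map for every novel read that found a home; reads mapping to
    no retained candidate are absent from the map (they stay uncategorized at
    the counting stage).
    """
    candidates: list[np.ndarray] = []
    remaining = list(encodings)
    relaxed = dynamic_threshold_cap(partition)

    # batched community detection; after each batch, reads compatible with an
    # existing candidate are pulled out and the rest form the next batch
    while len(remaining) >= 2:
        graph = build_read_graph(remaining, batch_size)
        if graph.n_edges == 0:
            break
        in_batch = set(graph.read_ids)
        by_id = {e.read_id: e for e in remaining}
        new_any = False
        for comm in detect_communities(graph, seed):
            vec = consensus_annotation([by_id[r] for r in comm])
            if vec.any():
                candidates.append(vec)
                new_any = True
        candidates = _dedupe_candidates(candidates, partition)
        if not new_any:
            break
        cand_iso = {f"c{i}": v for i, v in enumerate(candidates)}
        still = []
        for e in remaining:
            if e.read_id in in_batch:
                continue
            if not filter_compatible(e, partition, relaxed, cand_iso):
                still.append(e)
        if not still:
            break
        remaining = still

    candidates = _dedupe_candidates(candidates, partition)
    if not candidates:
        return [], {}
    return remap_and_prune(encodings, candidates, partition, support_min)


def remap_and_prune(
    encodings: list[ReadEncoding],
    candidates: list[np.ndarray],
    partition: SubExonPartition,
    support_min: int = NOVEL_SUPPORT_MIN,
) -> tuple[list[NovelIsoform], dict[str, str]]:
    """Remap novel reads at the relaxed threshold and drop redundant
    candidates.

    Reads are remapped against candidates plus annotated isoforms with the
    small-sub-exon threshold at its cap, min(80 bp, mean sub-exon length),
    which encourages multiple mappings; candidates are then scanned in
    ascending support order and removed when every read mapping to them also
    maps to another retained candidate or an annotated isoform.
    """
    relaxed = dynamic_threshold_cap(partition)
    names = [f"{partition.gene_id}-novel-{i + 1}" for i in range(len(candidates))]
    cand_iso = dict(zip(names, candidates))
    all_iso = {**cand_iso, **partition.transcripts}
    read_compat: dict[str, set[str]] = {}
    for e in encodings:
        read_compat[e.read_id] = filter_compatible(e, partition, relaxed, all_iso)

    support = {
        name: sum(1 for c in read_compat.values() if name in c) for name in names
    }
    retained = set(names)
    for name in sorted(names, key=lambda n: (support[n], n)):
        others_ok = True
        supporters = [r for r, c in read_compat.items() if name in c]
        if not supporters:
            retained.discard(name)
            continue
        for r in supporters:
            alts = (read_compat[r] - {name}) & (
                retained | set(partition.transcripts)
            )
            if not alts:
                others_ok = False
                break
        if others_ok:
            retained.discard(name)

    # final read -> isoform assignment among retained candidates
    assignment: dict[str, str] = {}
    counts = {name: 0 for name in retained}
    for e in encodings:
        options = read_compat[e.read_id] & retained
        if not options:
            continue
        cs = CompatibilitySet(e.read_id, options, int(relaxed))
        chosen = break_ties(cs, e, partition, {n: cand_iso[n] for n in options})
        assignment[e.read_id] = chosen
        counts[chosen] += 1

    isoforms = []
    for name in names:
        if name not in retained:
            continue
        iso = NovelIsoform(name, cand_iso[name], support_reads=counts[name])
        iso.category = categorize_support(iso, support_min)
        isoforms.append(iso)
    return isoforms, assignment
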