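"""Sub-exon partition construction, refinement, meta-genes, serialization."""

import json

import numpy as np
import pytest

from isocell.annotation import (
    AnnotationError,
    GeneDatabase,
    build_database,
    build_partition_annotation_free,
    build_partition_annotation_only,
    enhance_partition,
    group_meta_genes,
    merge_intervals,
)
from isocell.gtf import GeneModel

from conftest import make_gene, random_toy_gene


def brute_force_partition(all_exons):
    """Oracle: enumerate every breakpoint pair and keep segments inside the
    exonic union."""
    points = sorted({p for s, e in all_exons for p in (s, e)})
    exonic = merge_intervals(all_exons)
    out = []
    for a, b in zip(points, points[1:]):
        if any(s <= a and b <= e for s, e in exonic):
            out.append((a, b))
    return out


def test_boundary_union_two_transcripts():
    """Exons [100,200) and [100,300) split at 200 into two sub-exons with
    vectors (1,0) and (1,1)."""
    part = build_partition_annotation_only(
        make_gene("g", {"t1": [(100, 200)], "t2": [(100, 300)]})
    )
    assert part.sub_exons == [(100, 200), (200, 300)]
    assert part.transcripts["t1"].tolist() == [True, False]
    assert part.transcripts["t2"].tolist() == [True, True]


def test_single_transcript_identity():
    part = build_partition_annotation_only(
        make_gene("g", {"t1": [(0, 50), (80, 120)]})
    )
    assert part.sub_exons == [(0, 50), (80, 120)]
    assert part.transcripts["t1"].tolist() == [True, True]


@pytest.mark.parametrize("seed", range(25))
def test_partition_matches_breakpoint_oracle(seed):
    """Partition of overlapping-exon toy genes equals brute-force interval
    arithmetic over all breakpoints; membership footprints reconstruct each
    transcript exactly."""
    rng = np.random.default_rng(seed)
    # overlapping exon structures: perturb a base exon chain per transcript
    base = [(i * 400, i * 400 + int(rng.integers(50, 350))) for i in range(4)]
    txs = {}
    for t in range(3):
        exons = []
        for s, e in base:
            if rng.random() < 0.3:
                continue
            ds = int(rng.integers(0, 40)) if rng.random() < 0.5 else 0
            de = int(rng.integers(0, 40)) if rng.random() < 0.5 else 0
            if e - de > s + ds:
                exons.append((s + ds, e - de))
        if exons:
            txs[f"t{t}"] = exons
    if not txs:
        pytest.skip("degenerate draw")
    gene = make_gene("g", txs)
    part = build_partition_annotation_only(gene)
    all_exons = [iv for tr in gene.transcripts.values() for iv in tr.exons]
    assert part.sub_exons == brute_force_partition(all_exons)
    # disjoint cover + per-transcript reconstruction
    for (s1, e1), (s2, e2) in zip(part.sub_exons, part.sub_exons[1:]):
        assert e1 <= s2
    for tid, tr in gene.transcripts.items():
        assert part.transcript_footprint(tid) == merge_intervals(tr.exons)


def test_empty_and_malformed_genes_raise():
    with pytest.raises(AnnotationError):
        build_partition_annotation_only(GeneModel("g", "chr1", "+"))
    with pytest.raises(AnnotationError):
        build_partition_annotation_only(make_gene("g", {"t1": [(100, 100)]}))


class TestEnhancement:
    def _part(self):
        return build_partition_annotation_only(
            make_gene("g", {"t1": [(100, 200), (500, 700)],
                            "t2": [(100, 200)]})
        )

    def test_no_signal_is_identity(self):
        part = self._part()
        cov = np.full(800, 20)
        out = enhance_partition(part, cov, 0, [])
        assert out.sub_exons == part.sub_exons

    def test_empty_coverage_returns_input(self):
        part = self._part()
        assert enhance_partition(part, np.zeros(10), 0, []) is part

    def test_sharp_depth_step_in_intron_creates_boundary(self):
        """A 100x -> 5x step at p=300 inside the intron, above the fold
        threshold, produces a novel candidate sub-exon edge within 1 bp."""
        part = self._part()
        cov = np.zeros(800, dtype=float)
        cov[100:200] = 50
        cov[500:700] = 50
        cov[250:300] = 100  # novel expressed region with an internal step
        cov[300:380] = 5
        out = enhance_partition(part, cov, 0, [], coverage_floor=5, fold_change=5)
        boundaries = {p for s, e in out.sub_exons for p in (s, e)}
        assert any(abs(b - 300) <= 1 for b in boundaries)
        # the whole above-floor intronic run became candidate sub-exons
        assert any(s >= 250 and e <= 380 for s, e in out.sub_exons)

    def test_novel_junction_splits_annotated_exon(self):
        part = self._part()
        cov = np.full(800, 30.0)
        out = enhance_partition(part, cov, 0, [(550, 600, 5)])
        boundaries = {p for s, e in out.sub_exons for p in (s, e)}
        assert {550, 600} <= boundaries

    def test_weak_junction_ignored(self):
        part = self._part()
        cov = np.full(800, 30.0)
        out = enhance_partition(part, cov, 0, [(550, 600, 1)],
                                junction_min_reads=2)
        boundaries = {p for s, e in out.sub_exons for p in (s, e)}
        assert 550 not in boundaries

    def test_refinement_retains_all_original_boundaries(self):
        part = self._part()
        rng = np.random.default_rng(3)
        cov = rng.integers(0, 120, 900).astype(float)
        out = enhance_partition(part, cov, 0, [(220, 450, 4)])
        old = {p for s, e in part.sub_exons for p in (s, e)}
        new = {p for s, e in out.sub_exons for p in (s, e)}
        assert old <= new


class TestAnnotationFree:
    def test_single_block(self):
        cov = np.zeros(500)
        cov[100:300] = 10
        part = build_partition_annotation_free("chr1", cov, 0)
        assert part.sub_exons == [(100, 300)]
        assert len(part.transcripts) == 1

    def test_two_blocks_with_junction(self):
        cov = np.zeros(800)
        cov[100:300] = 10
        cov[500:700] = 10
        part = build_partition_annotation_free("chr1", cov, 0, [(300, 500, 5)])
        assert part.sub_exons == [(100, 300), (500, 700)]
        (vec,) = part.transcripts.values()
        assert vec.tolist() == [True, True]

    def test_internal_depth_step_splits_block(self):
        cov = np.zeros(400)
        cov[100:200] = 100
        cov[200:300] = 6
        part = build_partition_annotation_free("chr1", cov, 0)
        assert (100, 200) in part.sub_exons and (200, 300) in part.sub_exons

    def test_all_zero_coverage_raises(self):
        with pytest.raises(AnnotationError):
            build_partition_annotation_free("chr1", np.zeros(100), 0)


class TestMetaGenes:
    @staticmethod
    def _parts(spans):
        parts = {}
        for i, (s, e) in enumerate(spans):
            gid = f"g{i}"
            parts[gid] = build_partition_annotation_only(
                make_gene(gid, {"t": [(s, e)]})
            )
        return parts

    def test_overlap_and_disjoint(self):
        metas = group_meta_genes(self._parts([(0, 100), (50, 150), (500, 600)]))
        groups = sorted(tuple(m.gene_ids) for m in metas)
        assert groups == [("g0", "g1"), ("g2",)]

    def test_transitive_chain(self):
        metas = group_meta_genes(self._parts([(0, 100), (90, 200), (190, 300)]))
        assert len(metas) == 1 and sorted(metas[0].gene_ids) == ["g0", "g1", "g2"]

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        spans = []
        for _ in range(50):
            s = int(rng.integers(0, 5000))
            spans.append((s, s + int(rng.integers(10, 400))))
        parts = self._parts(spans)
        metas = group_meta_genes(parts)
        # oracle: union-find over all overlapping pairs
        parent = {g: g for g in parts}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        gids = sorted(parts)
        for i, a in enumerate(gids):
            for b in gids[i + 1:]:
                (s1, e1), (s2, e2) = parts[a].span, parts[b].span
                if s1 < e2 and s2 < e1:
                    parent[find(a)] = find(b)
        oracle = {}
        for g in gids:
            oracle.setdefault(find(g), set()).add(g)
        got = sorted(tuple(sorted(m.gene_ids)) for m in metas)
        want = sorted(tuple(sorted(v)) for v in oracle.values())
        assert got == want
        # meta spans on one chromosome do not overlap
        spans_sorted = sorted(m.span for m in metas)
        for (s1, e1), (s2, e2) in zip(spans_sorted, spans_sorted[1:]):
            assert e1 <= s2


def test_database_roundtrip_byte_identical(tmp_path):
    rng = np.random.default_rng(5)
    parts = {p.gene_id + str(i): p for i, p in
             enumerate(random_toy_gene(rng) for _ in range(5))}
    for gid, p in parts.items():
        p.gene_id = gid
    db = GeneDatabase(parts, group_meta_genes(parts), {"mode": "annotation_only"})
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    db.save(p1)
    GeneDatabase.load(p1).save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    reloaded = GeneDatabase.load(p2)
    assert json.dumps(reloaded.to_dict(), sort_keys=True) == json.dumps(
        db.to_dict(), sort_keys=True
    )


def test_build_database_membership_covers_every_subexon():
    """In annotation-only mode every sub-exon belongs to at least one
    transcript."""
    rng = np.random.default_rng(9)
    for _ in range(10):
        part = random_toy_gene(rng)
        members = np.zeros(part.n_sub_exons, dtype=bool)
        for vec in part.transcripts.values():
            members |= vec
        assert members.all()
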