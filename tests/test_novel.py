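import numpy as np
import pandas as pd
import pytest

from rpelinc.annotation import derive_junctions, gene_spans, load_gtf
from rpelinc.core import GenomicInterval, SpliceJunction, ValidationError
from rpelinc.novel import (
    JunctionCluster,
    NovelJunction,
    assemble_models,
    cluster_junctions,
    detection_by_condition,
    discover_novel_genes,
    find_novel_junctions,
    quantify_novel,
    summarize_novel,
    write_novel_gtf,
)
from rpelinc.quantify import ObservedJunctionTable, ReadTable

from conftest import build_annotation, make_isoform
from oracles import transitive_closure_clusters


def _nj(chrom, start, end, depth=5, strand="+"):
    return NovelJunction(SpliceJunction(chrom, start, end, strand), depth,
                         frozenset({"s1"}))


# -------------------------------------------------------------- filtering


def test_find_novel_junctions_classification():
    ann = build_annotation([
        make_isoform("t1", "gA", "chr1", "+", [(1000, 1100), (1500, 1600)]),
    ])
    jidx = derive_junctions(ann)
    spans = gene_spans(ann)
    depths = {
        SpliceJunction("chr1", 1100, 1500, "+"): 9,   # annotated
        SpliceJunction("chr1", 1050, 1550, "+"): 9,   # inside gene span
        SpliceJunction("chr1", 900, 1200, "+"): 9,    # overlaps span edge
        SpliceJunction("chr1", 10_000, 10_500, "+"): 9,   # clean
        SpliceJunction("chr1", 20_000, 20_400, "-"): 1,   # clean, depth 1
    }
    table = ObservedJunctionTable("s1", depths)
    novel = find_novel_junctions([table], jidx, spans, min_depth=1)
    got = {(n.junction.intron_start, n.junction.intron_end) for n in novel}
    assert got == {(10_000, 10_500), (20_000, 20_400)}
    novel2 = find_novel_junctions([table], jidx, spans, min_depth=2)
    assert {(n.junction.intron_start, n.junction.intron_end)
            for n in novel2} == {(10_000, 10_500)}


def test_novel_junction_depth_pools_across_samples():
    ann = build_annotation([
        make_isoform("t1", "gA", "chr9", "+", [(0, 10), (20, 30)]),
    ])
    jidx = derive_junctions(ann)
    j = SpliceJunction("chr1", 5000, 5400, "+")
    t1 = ObservedJunctionTable("s1", {j: 1})
    t2 = ObservedJunctionTable("s2", {j: 1})
    novel = find_novel_junctions([t1, t2], jidx, gene_spans(ann), min_depth=2)
    assert len(novel) == 1
    assert novel[0].depth == 2
    assert novel[0].sample_support == {"s1", "s2"}


# -------------------------------------------------------------- clustering


def test_cluster_gap_boundary_behaviour():
    near = [_nj("chr1", 1000, 2000), _nj("chr1", 3999, 5000)]  # gap 1999
    assert len(cluster_junctions(near, 2000)) == 1
    exact = [_nj("chr1", 1000, 2000), _nj("chr1", 4000, 5000)]  # gap 2000
    assert len(cluster_junctions(exact, 2000)) == 1
    far = [_nj("chr1", 1000, 2000), _nj("chr1", 4001, 5000)]  # gap 2001
    assert len(cluster_junctions(far, 2000)) == 2


def test_single_junction_forms_singleton_cluster():
    out = cluster_junctions([_nj("chr1", 10, 500)])
    assert len(out) == 1 and len(out[0].members) == 1


def test_opposite_strands_never_cluster():
    a = _nj("chr1", 1000, 2000, strand="+")
    b = _nj("chr1", 2100, 3000, strand="-")
    assert len(cluster_junctions([a, b], 2000)) == 2


def test_undefined_strand_joins_deeper_neighbouring_cluster():
    plus = _nj("chr1", 1000, 2000, depth=50, strand="+")
    minus = _nj("chr1", 6000, 7000, depth=5, strand="-")
    dot = _nj("chr1", 3000, 4000, depth=1, strand=".")
    out = cluster_junctions([plus, minus, dot], 3000)
    assert len(out) == 2
    by_strand = {c.strand: c for c in out}
    assert len(by_strand["+"].members) == 2  # '.' went with the deeper side
    assert len(by_strand["-"].members) == 1


def test_clustering_matches_transitive_closure_oracle():
    rng = np.random.default_rng(55)
    for _ in range(5):
        juncs = []
        for _ in range(50):
            chrom = f"chr{int(rng.integers(1, 3))}"
            start = int(rng.integers(0, 200_000))
            end = start + int(rng.integers(100, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            depth = int(rng.integers(1, 40))
            juncs.append(_nj(chrom, start, end, depth, strand))
        got = cluster_junctions(juncs, 2000)
        key = {
            (n.junction.chrom, n.junction.intron_start,
             n.junction.intron_end, n.junction.strand): i
            for i, n in enumerate(juncs)
        }
        got_sets = {
            frozenset(
                key[(m.junction.chrom, m.junction.intron_start,
                     m.junction.intron_end, m.junction.strand)]
                for m in c.members
            )
            for c in got
        }
        oracle = transitive_closure_clusters([n.junction for n in juncs], 2000)
        assert got_sets == oracle


# -------------------------------------------------------------- assembly


def test_two_junction_assembly_arithmetic():
    cluster = JunctionCluster([
        _nj("chr1", 1000, 1200, depth=8),
        _nj("chr1", 1500, 1800, depth=6),
    ])
    model = assemble_models(cluster, "NOVELG0001", terminal_bp=500)
    assert model is not None
    iso = model.isoforms[0]
    assert [(e.start, e.end) for e in iso.exons] == [
        (500, 1000), (1200, 1500), (1800, 2300),
    ]
    assert model.primary_isoform == iso.isoform_id
    assert model.supporting_depths[iso.isoform_id] == (8, 6)


def test_single_junction_cluster_yields_no_model():
    cluster = JunctionCluster([_nj("chr1", 1000, 1200)])
    assert assemble_models(cluster, "N") is None


def test_overlapping_introns_with_no_chain_yield_no_model():
    cluster = JunctionCluster([
        _nj("chr1", 1000, 2000), _nj("chr1", 1500, 2500),
    ])
    assert assemble_models(cluster, "N") is None


def test_branching_cluster_prefers_deeper_junction_for_primary():
    a = _nj("chr1", 1000, 1200, depth=20)
    b = _nj("chr1", 1500, 1800, depth=15)  # deeper branch
    c = _nj("chr1", 1450, 1800, depth=3)   # alternative acceptor, shallower
    model = assemble_models(JunctionCluster([a, b, c]), "N")
    primary = next(i for i in model.isoforms
                   if i.isoform_id == model.primary_isoform)
    assert model.supporting_depths[primary.isoform_id] == (20, 15)
    # the shallower branch still yields a second isoform
    assert len(model.isoforms) == 2
    chains = {tuple((e.start, e.end) for e in i.exons)
              for i in model.isoforms}
    assert ((500, 1000), (1200, 1450), (1800, 2300)) in chains


def test_primary_chain_keeps_middle_junction():
    # greedy must extend through tight neighbours, not jump across
    a = _nj("chr1", 1000, 1200, depth=24)
    b = _nj("chr1", 1400, 1600, depth=2)
    c = _nj("chr1", 1800, 2000, depth=27)
    model = assemble_models(JunctionCluster([a, b, c]), "N")
    primary = next(i for i in model.isoforms
                   if i.isoform_id == model.primary_isoform)
    assert len(primary.exons) == 4


def test_terminal_exons_truncated_at_chromosome_bounds():
    cluster = JunctionCluster([
        _nj("chr1", 300, 600), _nj("chr1", 700, 900),
    ])
    model = assemble_models(cluster, "N", terminal_bp=500, chrom_size=1100)
    iso = model.isoforms[0]
    assert iso.exons[0].start == 0
    assert iso.exons[-1].end == 1100


def test_max_isoforms_caps_enumeration():
    juncs = [
        _nj("chr1", 1000 + 700 * k + d, 1300 + 700 * k, depth=10 - d // 100)
        for k in range(3) for d in (0, 100)
    ]
    model = assemble_models(JunctionCluster(juncs), "N", max_isoforms=2)
    assert len(model.isoforms) <= 2


# -------------------------------------------------------------- end to end


def _toy_discovery():
    ann = build_annotation([
        make_isoform("t1", "gA", "chr1", "+", [(0, 500), (900, 1400)]),
    ])
    jidx = derive_junctions(ann)
    spans = gene_spans(ann)
    j1 = SpliceJunction("chr1", 10_000, 10_400, "+")
    j2 = SpliceJunction("chr1", 10_550, 11_000, "+")
    single = SpliceJunction("chr1", 40_000, 40_500, "+")
    table = ObservedJunctionTable("s1", {j1: 10, j2: 8, single: 5})
    return ann, jidx, spans, table


def test_discover_returns_models_and_two_exon_count():
    ann, jidx, spans, table = _toy_discovery()
    models, n_two = discover_novel_genes([table], jidx, spans)
    assert len(models) == 1
    assert n_two == 1  # the lone junction is a 2-exon candidate
    assert models[0].gene_id == "NOVELG0001"
    iso = models[0].isoforms[0]
    assert [(e.start, e.end) for e in iso.exons] == [
        (9_500, 10_000), (10_400, 10_550), (11_000, 11_500),
    ]


def test_discover_rejects_min_exons_below_three():
    ann, jidx, spans, table = _toy_discovery()
    with pytest.raises(ValidationError):
        discover_novel_genes([table], jidx, spans, min_exons=2)


def test_quantify_novel_detection_without_rpkm_floor():
    ann, jidx, spans, table = _toy_discovery()
    models, _ = discover_novel_genes([table], jidx, spans)
    empty_reads = ReadTable.from_records([], "s1")
    empty_reads2 = ReadTable.from_records([], "s2")
    sj2 = ObservedJunctionTable("s2", {})
    mat, det = quantify_novel(
        models,
        {"s1": empty_reads, "s2": empty_reads2},
        {"s1": table, "s2": sj2},
        totals={"s1": 1000, "s2": 1000},
    )
    # no exon reads at all: RPKM 0 everywhere, yet junction evidence in s1
    assert float(mat.rpkm.to_numpy().sum()) == 0.0
    assert bool(det.loc["NOVELG0001", "s1"])
    assert not bool(det.loc["NOVELG0001", "s2"])
    from rpelinc.expression import ConditionDesign

    design = ConditionDesign({"s1": "X", "s2": "Y"})
    by_cond = detection_by_condition(det, design)
    assert bool(by_cond.loc["NOVELG0001", "X"])
    assert not bool(by_cond.loc["NOVELG0001", "Y"])


def test_summarize_novel_aggregates():
    ann, jidx, spans, table = _toy_discovery()
    models, _ = discover_novel_genes([table], jidx, spans)
    df, agg = summarize_novel(models)
    assert agg["n_genes"] == 1.0
    assert df.loc["NOVELG0001", "n_exons"] == 3
    assert df.loc["NOVELG0001", "internal_exon_mean_bp"] == 150.0
    assert df.loc["NOVELG0001", "transcript_length_internal_bp"] == 150


def test_novel_gtf_round_trips(tmp_path):
    ann, jidx, spans, table = _toy_discovery()
    models, _ = discover_novel_genes([table], jidx, spans)
    path = tmp_path / "novel.gtf"
    write_novel_gtf(models, path)
    back = load_gtf(path)
    assert back.n_genes == 1
    iso = back.isoforms["NOVELG0001.1"]
    assert [(e.start, e.end) for e in iso.exons] == [
        (9_500, 10_000), (10_400, 10_550), (11_000, 11_500),
    ]


def test_every_emitted_exon_is_intergenic():
    ann, jidx, spans, table = _toy_discovery()
    models, _ = discover_novel_genes([table], jidx, spans)
    for m in models:
        for iso in m.isoforms:
            for e in iso.exons:
                for sp in spans.values():
                    assert not (
                        sp.chrom == e.chrom
                        and e.start < sp.end and sp.start < e.end
                    )
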