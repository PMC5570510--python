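import numpy as np
import pytest

from rpelinc.annotation import (
    GTFParseError,
    derive_junctions,
    gene_spans,
    load_gtf,
    merge_nonredundant,
    write_gtf,
)
from rpelinc.core import (
    GenomicInterval,
    Isoform,
    SpliceJunction,
    ValidationError,
    merge_intervals,
    strands_compatible,
)

from conftest import build_annotation, make_isoform, random_overlapping_annotation
from oracles import brute_force_gene_spans, brute_force_unique_junctions


# ---------------------------------------------------------------- core types


def test_interval_invariants():
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 100, 100)
    with pytest.raises(ValidationError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValidationError):
        GenomicInterval("chr1", 5, 10, "x")
    assert len(GenomicInterval("chr1", 5, 10)) == 5


def test_isoform_invariants():
    with pytest.raises(ValidationError):
        make_isoform("t", "g", "chr1", "+", [(100, 200), (150, 300)])
    iso = make_isoform("t", "g", "chr1", "+", [(100, 200), (300, 500)])
    assert iso.length_bp == 300
    assert iso.junctions() == (SpliceJunction("chr1", 200, 300, "+"),)


def test_strand_compatibility_is_lenient_for_undefined():
    assert strands_compatible(".", "+")
    assert strands_compatible("-", ".")
    assert not strands_compatible("+", "-")


def test_merge_intervals_unions_overlaps():
    assert merge_intervals([(5, 10), (1, 6), (20, 30)]) == [(1, 10), (20, 30)]


# ---------------------------------------------------------------- GTF I/O


def _write(tmp_path, text, name="test.gtf"):
    p = tmp_path / name
    p.write_text(text)
    return p


GTF_ONE = (
    'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "t1"; '
    'gene_type "lincRNA";\n'
    'chr1\tx\texon\t301\t500\t.\t+\t.\tgene_id "gA"; transcript_id "t1"; '
    'gene_type "lincRNA";\n'
)


def test_load_gtf_single_transcript(tmp_path):
    ann = load_gtf(_write(tmp_path, GTF_ONE), "src")
    assert ann.n_genes == 1 and ann.n_isoforms == 1
    iso = ann.isoforms["t1"]
    # 1-based inclusive converted to 0-based half-open
    assert [(e.start, e.end) for e in iso.exons] == [(100, 200), (300, 500)]
    assert iso.biotype == "lincRNA"
    assert ann.source_labels["t1"] == ("src",)


def test_load_gtf_empty_is_empty(tmp_path):
    ann = load_gtf(_write(tmp_path, "# just a header\n"))
    assert ann.n_isoforms == 0


def test_load_gtf_gene_grouping(tmp_path):
    text = ""
    for tid, gid, lo in (("t1", "gA", 101), ("t2", "gA", 101), ("t3", "gB", 901)):
        text += (
            f'chr1\tx\texon\t{lo}\t{lo + 99}\t.\t+\t.\t'
            f'gene_id "{gid}"; transcript_id "{tid}";\n'
        )
    ann = load_gtf(_write(tmp_path, text))
    assert sorted(ann.genes) == ["gA", "gB"]
    assert sorted(ann.genes["gA"]) == ["t1", "t2"]
    assert ann.genes["gB"] == ["t3"]


def test_load_gtf_malformed_line_names_line_number(tmp_path):
    bad = GTF_ONE + "chr1\tonly\tthree\n"
    with pytest.raises(GTFParseError, match="line 3"):
        load_gtf(_write(tmp_path, bad))


def test_load_gtf_rejects_inverted_exon(tmp_path):
    bad = ('chr1\tx\texon\t500\t100\t.\t+\t.\t'
           'gene_id "g"; transcript_id "t";\n')
    with pytest.raises(ValidationError, match="line 1"):
        load_gtf(_write(tmp_path, bad))


def test_gtf_round_trip_preserves_exon_structure(tmp_path):
    ann = random_overlapping_annotation(np.random.default_rng(5))
    path = tmp_path / "rt.gtf"
    write_gtf(ann, path)
    back = load_gtf(path)
    assert back.content_equal(ann) or {
        i.chain_signature() for i in back.isoforms.values()
    } == {i.chain_signature() for i in ann.isoforms.values()}


# ---------------------------------------------------------------- merging


def _two_gene_set():
    return build_annotation([
        make_isoform("t1", "gA", "chr1", "+", [(100, 200), (300, 400)]),
        make_isoform("t2", "gA", "chr1", "+", [(100, 200), (350, 400)]),
        make_isoform("t3", "gB", "chr2", "-", [(0, 50), (80, 120)]),
    ])


def test_merge_is_idempotent():
    a = _two_gene_set()
    merged = merge_nonredundant([a, _two_gene_set()])
    assert merged.content_equal(a)
    # provenance keeps both labels
    assert merged.source_labels["t1"] == ("test",)


def test_merge_with_empty_is_identity():
    from rpelinc.annotation import AnnotationSet

    a = _two_gene_set()
    assert merge_nonredundant([a, AnnotationSet()]).content_equal(a)


def test_merge_collapses_identical_chains_across_sources():
    a = _two_gene_set()
    b = build_annotation([
        # same chain as t1, different ids -> must collapse
        make_isoform("x1", "gZ", "chr1", "+", [(100, 200), (300, 400)]),
        make_isoform("x2", "gZ", "chr1", "+", [(100, 210), (300, 400)]),
    ])
    merged = merge_nonredundant([a, b])
    assert merged.n_isoforms == 4  # 3 + 1 novel chain
    sigs = [i.chain_signature() for i in merged.isoforms.values()]
    assert len(sigs) == len(set(sigs))
    assert "t1" in merged.isoforms and "x1" not in merged.isoforms


def test_merge_renames_id_collisions_with_different_chains():
    a = _two_gene_set()
    b = build_annotation([
        make_isoform("t1", "gQ", "chr3", "+", [(10, 90)]),
    ])
    merged = merge_nonredundant([a, b])
    assert merged.n_isoforms == 4
    assert any(i.endswith(":t1") or i.startswith("test:")
               for i in merged.isoforms if i != "t1")


def test_merge_nonredundancy_invariant_random():
    rng = np.random.default_rng(17)
    for _ in range(10):
        sets = [random_overlapping_annotation(rng) for _ in range(2)]
        merged = merge_nonredundant(sets)
        sigs = [i.chain_signature() for i in merged.isoforms.values()]
        assert len(sigs) == len(set(sigs))


# ---------------------------------------------------------------- junctions


def test_sole_isoform_owns_all_junctions():
    ann = build_annotation([
        make_isoform("t1", "g", "chr1", "+",
                     [(0, 10), (20, 30), (40, 50)]),
    ])
    jidx = derive_junctions(ann)
    assert len(jidx.by_isoform["t1"]) == 2
    assert jidx.unique_by_isoform["t1"] == jidx.by_isoform["t1"]


def test_identical_junction_sets_have_no_unique_junctions():
    ann = build_annotation([
        make_isoform("t1", "g", "chr1", "+", [(0, 10), (20, 30)]),
        # same junction, longer first exon start
        make_isoform("t2", "g", "chr1", "+", [(2, 10), (20, 30)]),
    ])
    jidx = derive_junctions(ann)
    assert jidx.unique_by_isoform["t1"] == frozenset()
    assert jidx.unique_by_isoform["t2"] == frozenset()


def test_unique_junctions_match_brute_force_on_random_fixtures():
    rng = np.random.default_rng(23)
    for _ in range(20):
        ann = random_overlapping_annotation(rng)
        jidx = derive_junctions(ann)
        oracle = brute_force_unique_junctions(ann)
        for iid in ann.isoforms:
            assert set(jidx.unique_by_isoform[iid]) == oracle[iid], iid
            assert jidx.unique_by_isoform[iid] <= jidx.by_isoform[iid]


def test_within_gene_scope_is_weaker_than_database_scope():
    # junction shared by isoforms of two different genes: unique within the
    # gene but not database-wide
    ann = build_annotation([
        make_isoform("t1", "gA", "chr1", "+", [(0, 10), (20, 30)]),
        make_isoform("t2", "gB", "chr1", "+", [(0, 10), (20, 30), (40, 50)]),
    ])
    db = derive_junctions(ann, scope="database")
    gene = derive_junctions(ann, scope="gene")
    shared = SpliceJunction("chr1", 10, 20, "+")
    assert shared not in db.unique_by_isoform["t1"]
    assert shared in gene.unique_by_isoform["t1"]
    assert shared in gene.unique_by_isoform["t2"]


def test_undefined_strand_junction_matches_stranded_copy():
    ann = build_annotation([
        make_isoform("t1", "gA", "chr1", "+", [(0, 10), (20, 30)]),
        make_isoform("t2", "gB", "chr1", ".", [(5, 10), (20, 40)]),
    ])
    jidx = derive_junctions(ann)
    # the '.' copy of [10,20) matches the '+' copy: neither is unique
    assert jidx.unique_by_isoform["t1"] == frozenset()
    assert jidx.unique_by_isoform["t2"] == frozenset()
    assert jidx.contains(SpliceJunction("chr1", 10, 20, "-"))


def test_union_of_junction_sets_is_all_annotated():
    ann = random_overlapping_annotation(np.random.default_rng(3))
    jidx = derive_junctions(ann)
    union = set()
    for js in jidx.by_isoform.values():
        union |= js
    assert union == set(jidx.all_annotated)


# ---------------------------------------------------------------- gene spans


def test_gene_span_examples():
    ann = build_annotation([
        make_isoform("t1", "g1", "chr1", "+", [(100, 200)]),
        make_isoform("t2", "g2", "chr1", "+", [(100, 200)]),
        make_isoform("t3", "g2", "chr1", "+", [(500, 900)]),
    ])
    spans = gene_spans(ann)
    assert (spans["g1"].start, spans["g1"].end) == (100, 200)
    assert (spans["g2"].start, spans["g2"].end) == (100, 900)


def test_gene_spans_match_brute_force():
    rng = np.random.default_rng(41)
    for _ in range(10):
        ann = random_overlapping_annotation(rng)
        spans = gene_spans(ann)
        oracle = brute_force_gene_spans(ann)
        for gid, (chrom, lo, hi) in oracle.items():
            assert (spans[gid].chrom, spans[gid].start, spans[gid].end) == (
                chrom, lo, hi,
            )
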