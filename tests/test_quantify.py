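import numpy as np
import pandas as pd
import pytest

from rpelinc.annotation import derive_junctions
from rpelinc.core import GenomicInterval, ReadRecord, SpliceJunction, ValidationError
from rpelinc.quantify import (
    ObservedJunctionTable,
    ReadTable,
    apply_zero_rule,
    compute_rpkm,
    count_isoforms,
    exon_overlap_counts,
    read_sj_table,
    write_sj_table,
)

from conftest import (
    build_annotation,
    make_isoform,
    random_overlapping_annotation,
    random_reads,
    random_sj_depths,
)
from oracles import brute_force_exon_counts, brute_force_zero_rule


# ------------------------------------------------------------- SJ dialect


def test_sj_table_dialect_conversion(tmp_path):
    p = tmp_path / "SJ.out.tab"
    p.write_text("chr1\t1001\t1100\t1\t1\t0\t7\t3\t20\n")
    table = read_sj_table(p, "s1")
    j = SpliceJunction("chr1", 1000, 1100, "+")
    assert table.depths == {j: 7}  # multi-mapper column ignored
    assert table.depth_of(j) == 7
    assert table.depth_of(SpliceJunction("chr1", 1000, 1100, ".")) == 7
    assert table.depth_of(SpliceJunction("chr1", 1000, 1100, "-")) == 0


def test_sj_table_empty_and_errors(tmp_path):
    p = tmp_path / "empty.tab"
    p.write_text("")
    assert len(read_sj_table(p, "s")) == 0
    p.write_text("chr1\t10\t20\t1\t0\t0\n")
    with pytest.raises(ValueError, match="9 columns"):
        read_sj_table(p, "s")
    p.write_text("chr1\t10\t20\t1\t0\t0\t-3\t0\t0\n")
    with pytest.raises(ValidationError, match="negative"):
        read_sj_table(p, "s")


def test_sj_table_round_trip(tmp_path):
    depths = {
        SpliceJunction("chr1", 10, 50, "+"): 4,
        SpliceJunction("chr2", 5, 500, "."): 2,
    }
    p = tmp_path / "t.tab"
    write_sj_table(ObservedJunctionTable("s", depths), p)
    assert read_sj_table(p, "s").depths == depths


def test_sj_fixture_hand_parsed(tmp_path):
    rows = [
        ("chr1", 101, 200, 1, 9),
        ("chr1", 301, 450, 2, 1),
        ("chr2", 11, 90, 0, 3),
        ("chr2", 101, 220, 1, 0),
        ("chr3", 1, 50, 1, 12),
    ]
    p = tmp_path / "f.tab"
    p.write_text("".join(
        f"{c}\t{s}\t{e}\t{st}\t0\t0\t{u}\t5\t10\n" for c, s, e, st, u in rows
    ))
    t = read_sj_table(p, "s")
    assert t.depth_of(SpliceJunction("chr1", 100, 200, "+")) == 9
    assert t.depth_of(SpliceJunction("chr1", 300, 450, "-")) == 1
    assert t.depth_of(SpliceJunction("chr2", 10, 90, ".")) == 3
    assert t.depth_of(SpliceJunction("chr2", 100, 220, "+")) == 0
    assert t.depth_of(SpliceJunction("chr3", 0, 50, "+")) == 12


# ------------------------------------------------------------- counting


def _shared_exon_setup():
    """Two isoforms of one gene sharing their first exon."""
    ann = build_annotation([
        make_isoform("a", "g", "chr1", "+", [(0, 100), (200, 300)]),
        make_isoform("b", "g", "chr1", "+", [(0, 100), (400, 500)]),
    ])
    return ann, derive_junctions(ann)


def test_no_reads_gives_zero_counts():
    ann, jidx = _shared_exon_setup()
    sj = ObservedJunctionTable("s", {})
    counts = count_isoforms([], ann, jidx, sj)
    assert counts == {"a": 0, "b": 0}


def test_shared_exon_read_counts_toward_both_isoforms():
    ann, jidx = _shared_exon_setup()
    sj = ObservedJunctionTable("s", {
        SpliceJunction("chr1", 100, 200, "+"): 5,
        SpliceJunction("chr1", 100, 400, "+"): 5,
    })
    read = ReadRecord("chr1", (GenomicInterval("chr1", 10, 90),))
    counts = count_isoforms([read], ann, jidx, sj)
    assert counts == {"a": 1, "b": 1}


def test_unobserved_unique_junction_zeroes_isoform_despite_exon_reads():
    ann, jidx = _shared_exon_setup()
    # only isoform a's junction observed; b has exon reads but no junction
    sj = ObservedJunctionTable("s", {
        SpliceJunction("chr1", 100, 200, "+"): 3,
    })
    reads = [
        ReadRecord("chr1", (GenomicInterval("chr1", 10, 90),))
        for _ in range(7)
    ]
    counts = count_isoforms(reads, ann, jidx, sj)
    assert counts["a"] == 7
    assert counts["b"] == 0


def test_one_junction_read_restores_exon_sum_count():
    ann, jidx = _shared_exon_setup()
    reads = [
        ReadRecord("chr1", (GenomicInterval("chr1", 10, 90),))
        for _ in range(7)
    ]
    sj0 = ObservedJunctionTable("s", {})
    sj1 = ObservedJunctionTable("s", {
        SpliceJunction("chr1", 100, 400, "+"): 1,
    })
    assert count_isoforms(reads, ann, jidx, sj0)["b"] == 0
    assert count_isoforms(reads, ann, jidx, sj1)["b"] == 7


def test_multi_exon_spanning_read_counts_once_per_exon():
    ann = build_annotation([
        make_isoform("t", "g", "chr1", "+", [(0, 100), (200, 300)]),
    ])
    jidx = derive_junctions(ann)
    sj = ObservedJunctionTable("s", {SpliceJunction("chr1", 100, 200, "+"): 1})
    read = ReadRecord("chr1", (
        GenomicInterval("chr1", 50, 100), GenomicInterval("chr1", 200, 250),
    ))
    assert count_isoforms([read], ann, jidx, sj)["t"] == 2


def test_multimapper_reads_are_excluded():
    ann, jidx = _shared_exon_setup()
    sj = ObservedJunctionTable("s", {
        SpliceJunction("chr1", 100, 200, "+"): 1,
        SpliceJunction("chr1", 100, 400, "+"): 1,
    })
    read = ReadRecord("chr1", (GenomicInterval("chr1", 10, 90),),
                      unique=False)
    assert count_isoforms([read], ann, jidx, sj) == {"a": 0, "b": 0}


def test_read_on_unknown_chrom_is_ignored():
    ann, jidx = _shared_exon_setup()
    sj = ObservedJunctionTable("s", {
        SpliceJunction("chr1", 100, 200, "+"): 1,
        SpliceJunction("chr1", 100, 400, "+"): 1,
    })
    read = ReadRecord("chrUn", (GenomicInterval("chrUn", 10, 90),))
    assert count_isoforms([read], ann, jidx, sj) == {"a": 0, "b": 0}


def test_zero_rule_variants():
    ann = build_annotation([
        make_isoform("t", "g", "chr1", "+",
                     [(0, 10), (20, 30), (40, 50)]),
    ])
    jidx = derive_junctions(ann)
    counts = {"t": 9}
    # one of two unique junctions observed
    sj = ObservedJunctionTable("s", {SpliceJunction("chr1", 10, 20, "+"): 2})
    assert apply_zero_rule(counts, jidx, sj, "all_unobserved")["t"] == 9
    assert apply_zero_rule(counts, jidx, sj, "any_unobserved")["t"] == 0
    with pytest.raises(ValidationError):
        apply_zero_rule(counts, jidx, sj, "bogus")


def test_counting_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(25):
        ann = random_overlapping_annotation(rng)
        jidx = derive_junctions(ann)
        reads = random_reads(rng, ann, n_reads=int(rng.integers(0, 51)))
        sj = ObservedJunctionTable("s", random_sj_depths(rng, jidx))
        raw = exon_overlap_counts(reads, ann)
        assert raw == brute_force_exon_counts(reads, ann)
        ruled = count_isoforms(reads, ann, jidx, sj)
        assert ruled == brute_force_zero_rule(raw, ann, jidx, sj.depths)


def test_zero_rule_monotone_in_junction_depth():
    rng = np.random.default_rng(7)
    ann = random_overlapping_annotation(rng)
    jidx = derive_junctions(ann)
    reads = random_reads(rng, ann, 40)
    sj_depths = random_sj_depths(rng, jidx)
    base = count_isoforms(reads, ann, jidx, ObservedJunctionTable("s", sj_depths))
    unobserved = [j for j in jidx.all_annotated if j not in sj_depths]
    for j in unobserved:
        bumped = dict(sj_depths)
        bumped[j] = 1
        after = count_isoforms(reads, ann, jidx,
                               ObservedJunctionTable("s", bumped))
        assert all(after[i] >= base[i] for i in base)


def test_flipping_unique_flag_never_increases_counts():
    rng = np.random.default_rng(13)
    ann = random_overlapping_annotation(rng)
    jidx = derive_junctions(ann)
    reads = random_reads(rng, ann, 30)
    sj = ObservedJunctionTable("s", random_sj_depths(rng, jidx))
    base = count_isoforms(reads, ann, jidx, sj)
    for k in range(len(reads)):
        if not reads[k].unique:
            continue
        flipped = list(reads)
        flipped[k] = ReadRecord(reads[k].chrom, reads[k].blocks,
                                reads[k].strand, unique=False)
        after = count_isoforms(flipped, ann, jidx, sj)
        assert all(after[i] <= base[i] for i in base)


# ------------------------------------------------------------- read tables


def test_read_table_round_trip(tmp_path):
    reads = [
        ReadRecord("chr1", (GenomicInterval("chr1", 10, 110, "+"),),
                   "+", True, "a"),
        ReadRecord("chr1", (
            GenomicInterval("chr1", 200, 260, "-"),
            GenomicInterval("chr1", 400, 440, "-"),
        ), "-", False, "b"),
    ]
    t = ReadTable.from_records(reads, "s")
    p = tmp_path / "reads.tsv"
    t.to_tsv(p)
    back = ReadTable.from_tsv(p, "s")
    assert back.records() == reads
    assert back.n_unique == 1


# ------------------------------------------------------------- RPKM


def test_rpkm_closed_form_and_edge_cases():
    counts = pd.DataFrame({"s1": {"i1": 0, "i2": 1000}})
    mat = compute_rpkm(counts, {"s1": 10_000_000}, {"i1": 500, "i2": 2000})
    assert mat.rpkm.loc["i1", "s1"] == 0.0
    assert mat.rpkm.loc["i2", "s1"] == pytest.approx(50.0, rel=1e-12)


def test_rpkm_halves_when_depth_doubles():
    counts = pd.DataFrame({"s1": {"i": 37}, "s2": {"i": 37}})
    mat = compute_rpkm(counts, {"s1": 1_000_000, "s2": 2_000_000}, {"i": 1500})
    assert mat.rpkm.loc["i", "s1"] == pytest.approx(
        2 * mat.rpkm.loc["i", "s2"], rel=1e-12
    )


def test_rpkm_linear_in_count():
    lengths = {"i": 777}
    totals = {"s": 123_456}
    a = compute_rpkm(pd.DataFrame({"s": {"i": 10}}), totals, lengths)
    b = compute_rpkm(pd.DataFrame({"s": {"i": 30}}), totals, lengths)
    assert b.rpkm.loc["i", "s"] == pytest.approx(
        3 * a.rpkm.loc["i", "s"], rel=1e-12
    )


def test_rpkm_rejects_degenerate_inputs():
    counts = pd.DataFrame({"s": {"i": 5}})
    with pytest.raises(ValidationError):
        compute_rpkm(counts, {"s": 0}, {"i": 100})
    with pytest.raises(ValidationError):
        compute_rpkm(counts, {"s": 100}, {"i": 0})
    with pytest.raises(ValidationError):
        compute_rpkm(pd.DataFrame({"s": {"i": -1}}), {"s": 10}, {"i": 10})
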