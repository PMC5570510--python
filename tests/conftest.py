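from __future__ import annotations

import numpy as np
import pytest

from rpelinc.annotation import AnnotationSet
from rpelinc.core import GenomicInterval, Isoform, ReadRecord, SpliceJunction
from rpelinc.simulate import SimulationConfig, generate_workspace

# a small but complete study: 3 conditions x 3 replicates, fewer genes and
# shallower libraries than the default study conditions, for fast pipeline
# round trips
SMALL_SIM_KW = dict(
    n_coding=24, n_lincrna=10, n_novel_genes=4, n_decoy_junctions=4,
    library_depth=25_000, n_high_expr=5, n_signature=5, n_ips_specific=3,
    n_contam_photoreceptor=2, n_contam_choroid=2,
)


def make_isoform(iid, gid, chrom, strand, exon_pairs, biotype="other"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_pairs)
    return Isoform(iid, gid, exons, biotype)


def build_annotation(isoforms) -> AnnotationSet:
    ann = AnnotationSet()
    for iso in isoforms:
        ann.add(iso, ("test",))
    return ann


def random_overlapping_annotation(rng, max_isoforms=10) -> AnnotationSet:
    """A single locus of overlapping isoforms that share exons/junctions."""
    n_exons = int(rng.integers(4, 9))
    starts, ends = [], []
    pos = int(rng.integers(0, 5_000))
    for _ in range(n_exons):
        length = int(rng.integers(50, 400))
        starts.append(pos)
        ends.append(pos + length)
        pos += length + int(rng.integers(50, 800))
    strand = "+" if rng.random() < 0.5 else "-"
    n_iso = int(rng.integers(2, max_isoforms + 1))
    isoforms = []
    seen = set()
    for k in range(n_iso):
        keep = sorted(
            rng.choice(n_exons, size=int(rng.integers(2, n_exons + 1)),
                       replace=False)
        )
        key = tuple(keep)
        if key in seen:
            continue
        seen.add(key)
        isoforms.append(
            make_isoform(
                f"iso{k}", f"g{k % 2}", "chrT", strand,
                [(starts[i], ends[i]) for i in keep],
            )
        )
    return build_annotation(isoforms)


def random_reads(rng, ann, n_reads=50) -> list[ReadRecord]:
    """Reads scattered over the locus: 1-2 blocks, some multi-mapping."""
    span_start = min(i.exons[0].start for i in ann.isoforms.values())
    span_end = max(i.exons[-1].end for i in ann.isoforms.values())
    reads = []
    for k in range(n_reads):
        s = int(rng.integers(max(span_start - 200, 0), span_end + 200))
        if rng.random() < 0.3:
            gap = int(rng.integers(20, 500))
            blocks = (
                GenomicInterval("chrT", s, s + 60),
                GenomicInterval("chrT", s + 60 + gap, s + 120 + gap),
            )
        else:
            blocks = (GenomicInterval("chrT", s, s + 100),)
        reads.append(
            ReadRecord("chrT", blocks, ".", unique=rng.random() > 0.15,
                       name=f"r{k}")
        )
    return reads


def random_sj_depths(rng, jidx) -> dict[SpliceJunction, int]:
    """Random depths over the annotated junctions; many left at zero."""
    depths = {}
    for j in sorted(jidx.all_annotated):
        if rng.random() < 0.5:
            depths[j] = int(rng.integers(1, 30))
    return depths


@pytest.fixture(scope="session")
def small_workspace(tmp_path_factory):
    out = tmp_path_factory.mktemp("workspace")
    cfg = SimulationConfig(seed=11, **SMALL_SIM_KW)
    generate_workspace(cfg, out)
    return out, cfg
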