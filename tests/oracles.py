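"""Independent brute-force reference implementations used only by tests.

Each oracle is written as the most direct possible statement of the rule it
checks — nested loops, all-pairs transitive closure, textbook formulas —
and shares no code with the package internals.
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

from rpelinc.core import ReadRecord, SpliceJunction, strands_compatible


def brute_force_exon_counts(reads, ann) -> dict[str, int]:
    """Per-read / per-isoform / per-exon triple loop, no zero rule."""
    counts = {iid: 0 for iid in ann.isoforms}
    for read in reads:
        if not read.unique:
            continue
        for iid, iso in ann.isoforms.items():
            for exon in iso.exons:
                hit = any(
                    block.chrom == exon.chrom
                    and block.start < exon.end
                    and exon.start < block.end
                    for block in read.blocks
                )
                if hit:
                    counts[iid] += 1
    return counts


def brute_force_zero_rule(counts, ann, jidx, sj_depths) -> dict[str, int]:
    """Direct restatement: zero an isoform iff it owns unique junctions and
    none of them has an observed read, using lenient strand matching."""
    out = dict(counts)
    for iid in ann.isoforms:
        uniq = jidx.unique_by_isoform.get(iid, frozenset())
        if not uniq:
            continue
        observed = False
        for j in uniq:
            for oj, d in sj_depths.items():
                if (
                    oj.chrom == j.chrom
                    and oj.intron_start == j.intron_start
                    and oj.intron_end == j.intron_end
                    and strands_compatible(oj.strand, j.strand)
                    and d > 0
                ):
                    observed = True
        if not observed:
            out[iid] = 0
    return out


def brute_force_unique_junctions(ann) -> dict[str, set[SpliceJunction]]:
    """unique_by_isoform as per-isoform set difference against all others."""
    juncs = {iid: set(iso.junctions()) for iid, iso in ann.isoforms.items()}

    def matched(j, others) -> bool:
        return any(
            j.chrom == o.chrom
            and j.intron_start == o.intron_start
            and j.intron_end == o.intron_end
            and strands_compatible(j.strand, o.strand)
            for o in others
        )

    out = {}
    for iid, mine in juncs.items():
        others = set()
        for other_id, theirs in juncs.items():
            if other_id != iid:
                others |= theirs
        out[iid] = {j for j in mine if not matched(j, others)}
    return out


def brute_force_gene_spans(ann) -> dict[str, tuple[str, int, int]]:
    out = {}
    for gid, iso_ids in ann.genes.items():
        starts, ends = [], []
        chrom = None
        for iid in iso_ids:
            for e in ann.isoforms[iid].exons:
                starts.append(e.start)
                ends.append(e.end)
                chrom = e.chrom
        out[gid] = (chrom, min(starts), max(ends))
    return out


def transitive_closure_clusters(junctions, gap_bp: int):
    """All-pairs linkage graph + BFS connected components.

    Junctions must carry defined strands; linkage requires equal strand and
    edge-to-edge intron gap <= gap_bp.
    """
    n = len(junctions)

    def gap(a, b):
        if a.intron_start > b.intron_end:
            return a.intron_start - b.intron_end
        if b.intron_start > a.intron_end:
            return b.intron_start - a.intron_end
        return 0

    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = junctions[i], junctions[j]
            if (
                i != j
                and a.chrom == b.chrom
                and a.strand == b.strand
                and gap(a, b) <= gap_bp
            ):
                adj[i][j] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        comp, queue = [], [i]
        seen[i] = True
        while queue:
            k = queue.pop()
            comp.append(k)
            for j in range(n):
                if adj[k][j] and not seen[j]:
                    seen[j] = True
                    queue.append(j)
        comps.append(frozenset(comp))
    return set(comps)


def textbook_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def brute_force_bins(values: Sequence[float]) -> dict[str, int]:
    counts = {"zero": 0, "(0,1]": 0, "(1,10]": 0, "(10,100]": 0,
              "(100,1000]": 0, ">1000": 0}
    for v in values:
        if v == 0:
            counts["zero"] += 1
        elif v <= 1:
            counts["(0,1]"] += 1
        elif v <= 10:
            counts["(1,10]"] += 1
        elif v <= 100:
            counts["(10,100]"] += 1
        elif v <= 1000:
            counts["(100,1000]"] += 1
        else:
            counts[">1000"] += 1
    return counts
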