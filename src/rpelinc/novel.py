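"""Putative novel gene discovery from unannotated intergenic splice junctions.

RNA-seq junctions falling outside every annotated gene span are evidence of
unannotated transcription.  The procedure: (1) keep observed junctions that
match no annotated junction and whose intron overlaps no gene span on
either strand; (2) group junctions lying within 2 kb of each other
(single-linkage, edge-to-edge between intron intervals) as candidates of
one transcript; (3) assemble exon chains per cluster by following splice
junctions in order of read depth — internal exons are the gaps between
consecutive introns, and terminal exons are fixed at 500 bp because
junction data cannot reveal true transcript ends; (4) keep only models with
at least 3 exons (2 junctions); (5) quantify with the same exon-overlap
counting as annotated isoforms, with *no* RPKM floor for detection.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import AnnotationSet, JunctionIndex, gene_spans, write_gtf
from .core import (
    GenomicInterval,
    Isoform,
    SpliceJunction,
    ValidationError,
    strands_compatible,
)
from .quantify import (
    ExpressionMatrix,
    ObservedJunctionTable,
    ReadTable,
    compute_rpkm,
    exon_overlap_counts,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NovelJunction:
    """An observed junction that is unannotated and intergenic."""

    junction: SpliceJunction
    depth: int  # pooled unique-read depth across discovery samples
    sample_support: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValidationError("novel junction must have depth > 0")


@dataclass
class JunctionCluster:
    """Single-linkage group of novel junctions within the gap threshold."""

    members: list[NovelJunction]

    @property
    def chrom(self) -> str:
        return self.members[0].junction.chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(m.junction.intron_start for m in self.members)
        end = max(m.junction.intron_end for m in self.members)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def strand(self) -> str:
        """Majority defined strand; '.' when no member has one."""
        defined = [m.junction.strand for m in self.members
                   if m.junction.strand != "."]
        if not defined:
            return "."
        plus = sum(1 for s in defined if s == "+")
        return "+" if plus * 2 >= len(defined) else "-"


@dataclass
class NovelGeneModel:
    """An assembled multi-exon novel gene with one or more isoforms."""

    gene_id: str
    isoforms: list[Isoform]
    supporting_depths: dict[str, tuple[int, ...]]  # isoform_id -> depths
    primary_isoform: str

    @property
    def chrom(self) -> str:
        return self.isoforms[0].chrom

    def junctions(self) -> set[SpliceJunction]:
        out: set[SpliceJunction] = set()
        for iso in self.isoforms:
            out.update(iso.junctions())
        return out


def find_novel_junctions(
    sj_tables: Sequence[ObservedJunctionTable],
    jidx: JunctionIndex,
    spans: Mapping[str, GenomicInterval],
    min_depth: int = 1,
) -> list[NovelJunction]:
    """Unannotated, intergenic junctions with pooled depth >= ``min_depth``.

    Depth is pooled across the supplied tables (the discovery condition's
    samples); the intergenic test requires the full intron interval to
    overlap no gene span on *either* strand.
    """
    span_trees: dict[str, IntervalTree] = {}
    for sp in spans.values():
        span_trees.setdefault(sp.chrom, IntervalTree()).addi(sp.start, sp.end)

    pooled: dict[SpliceJunction, int] = {}
    support: dict[SpliceJunction, set[str]] = {}
    for table in sj_tables:
        for j, d in table.depths.items():
            if d <= 0:
                continue
            pooled[j] = pooled.get(j, 0) + d
            support.setdefault(j, set()).add(table.sample_id)

    out = []
    for j in sorted(pooled):
        if jidx.contains(j):
            continue
        tree = span_trees.get(j.chrom)
        if tree is not None and tree.overlap(j.intron_start, j.intron_end):
            continue
        if pooled[j] < min_depth:
            continue
        out.append(
            NovelJunction(j, pooled[j], frozenset(support[j]))
        )
    return out


def _gap(a: SpliceJunction, b: SpliceJunction) -> int:
    """Genomic gap between intron intervals; 0 if they overlap or touch."""
    return max(
        a.intron_start - b.intron_end, b.intron_start - a.intron_end, 0
    )


def cluster_junctions(
    novel: Sequence[NovelJunction], gap_bp: int = 2000
) -> list[JunctionCluster]:
    """Single-linkage clustering of junctions within ``gap_bp`` of each other.

    Distance is edge-to-edge between intron intervals; a gap of exactly
    ``gap_bp`` still joins.  Clustering is per chromosome and per strand;
    undefined-strand junctions may join either strand and are resolved to
    the nearby cluster of larger total depth when both would take them.
    Clusters are returned sorted by (chrom, start).
    """
    if gap_bp < 0:
        raise ValidationError("gap_bp must be >= 0")
    by_chrom: dict[str, list[NovelJunction]] = {}
    for nj in novel:
        by_chrom.setdefault(nj.junction.chrom, []).append(nj)

    clusters: list[list[NovelJunction]] = []
    for chrom in sorted(by_chrom):
        items = by_chrom[chrom]
        defined = sorted({nj.junction.strand for nj in items} - {"."})
        undefined = [nj for nj in items if nj.junction.strand == "."]
        if not defined:
            clusters.extend(_linkage_1d(undefined, gap_bp))
            continue
        # '.' junctions are offered to each defined strand; duplicates are
        # resolved afterwards by cluster depth
        per_strand: dict[str, list[list[NovelJunction]]] = {}
        for s in defined:
            group = [nj for nj in items if nj.junction.strand == s] + undefined
            per_strand[s] = _linkage_1d(group, gap_bp)
        if len(defined) == 1 or not undefined:
            for s in defined:
                clusters.extend(
                    [c for c in per_strand[s]
                     if any(nj.junction.strand == s for nj in c)
                     or len(defined) == 1]
                )
            if len(defined) > 1:
                # orphan '.' clusters (no stranded member on either strand)
                seen = set()
                for s in defined:
                    for c in per_strand[s]:
                        if all(nj.junction.strand == "." for nj in c):
                            key = tuple(sorted(nj.junction for nj in c))
                            if key not in seen:
                                seen.add(key)
                                clusters.append(c)
            continue
        clusters.extend(_resolve_dotted(per_strand, defined))
    out = [JunctionCluster(sorted(c, key=lambda n: n.junction))
           for c in clusters]
    out.sort(key=lambda c: (c.chrom, c.span.start, c.span.end))
    return out


def _linkage_1d(
    items: list[NovelJunction], gap_bp: int
) -> list[list[NovelJunction]]:
    """Single-linkage over sorted intron intervals via a sweep."""
    if not items:
        return []
    items = sorted(items, key=lambda n: (n.junction.intron_start,
                                         n.junction.intron_end))
    groups: list[list[NovelJunction]] = [[items[0]]]
    max_end = items[0].junction.intron_end
    for nj in items[1:]:
        if nj.junction.intron_start - max_end <= gap_bp:
            groups[-1].append(nj)
        else:
            groups.append([nj])
        max_end = max(max_end, nj.junction.intron_end)
    return groups


def _resolve_dotted(
    per_strand: dict[str, list[list[NovelJunction]]],
    defined: list[str],
) -> list[list[NovelJunction]]:
    """Assign each '.' junction to one strand's clustering by total depth."""
    choice: dict[SpliceJunction, str] = {}
    dotted: set[SpliceJunction] = set()
    cluster_of: dict[str, dict[SpliceJunction, int]] = {}
    for s in defined:
        cluster_of[s] = {}
        for ci, c in enumerate(per_strand[s]):
            for nj in c:
                if nj.junction.strand == ".":
                    dotted.add(nj.junction)
                    cluster_of[s][nj.junction] = ci
    for j in dotted:
        best, best_depth = None, -1
        for s in defined:
            ci = cluster_of[s].get(j)
            if ci is None:
                continue
            c = per_strand[s][ci]
            if not any(n.junction.strand == s for n in c):
                continue  # no stranded anchor on this strand
            depth = sum(n.depth for n in c)
            if depth > best_depth:
                best, best_depth = s, depth
        choice[j] = best if best is not None else defined[0]

    out: list[list[NovelJunction]] = []
    emitted_orphans: set[tuple] = set()
    for s in defined:
        for c in per_strand[s]:
            kept = [
                nj for nj in c
                if nj.junction.strand == s
                or (nj.junction.strand == "." and choice[nj.junction] == s)
            ]
            if not kept:
                continue
            if all(nj.junction.strand == "." for nj in kept):
                key = tuple(sorted(nj.junction for nj in kept))
                if key in emitted_orphans:
                    continue
                emitted_orphans.add(key)
            out.append(kept)
    return out


def _compatible(a: SpliceJunction, b: SpliceJunction) -> bool:
    """b can follow a in an exon chain: introns in order, non-overlapping,
    with >=1 bp of exon between them."""
    return a.intron_end < b.intron_start


def assemble_models(
    cluster: JunctionCluster,
    gene_id: str,
    terminal_bp: int = 500,
    max_isoforms: int = 5,
    chrom_size: int | None = None,
) -> NovelGeneModel | None:
    """Assemble exon-chain isoforms from a junction cluster.

    The primary isoform follows the junctions greedily by read depth:
    starting from the highest-depth junction, it repeatedly extends left
    and right to the compatible neighbour of highest depth.  Internal exons
    are the gaps between consecutive introns; terminal exons extend
    ``terminal_bp`` outward from the outermost junction boundaries
    (truncated at chromosome bounds with a warning).  Additional isoforms
    come from the remaining maximal junction chains in decreasing
    total-depth order, deduplicated by exon chain, up to ``max_isoforms``.
    Returns None when no chain has >=2 junctions (a >=3-exon model).
    """
    members = sorted(
        cluster.members,
        key=lambda n: (n.junction.intron_start, n.junction.intron_end),
    )
    n = len(members)
    if n < 2:
        return None

    def depth(i: int) -> int:
        return members[i].depth

    J = [m.junction for m in members]

    def tight_successors(i: int) -> list[int]:
        succs = [j for j in range(n) if _compatible(J[i], J[j])]
        return [
            j for j in succs
            if not any(
                _compatible(J[i], J[k]) and _compatible(J[k], J[j])
                for k in succs
            )
        ]

    def tight_predecessors(i: int) -> list[int]:
        preds = [j for j in range(n) if _compatible(J[j], J[i])]
        return [
            j for j in preds
            if not any(
                _compatible(J[j], J[k]) and _compatible(J[k], J[i])
                for k in preds
            )
        ]

    # ---- primary: greedy extension from the deepest junction, one tight
    # neighbour (nothing insertable in between) at a time
    seed = max(range(n), key=lambda i: (depth(i), -i))
    chain = [seed]
    while True:
        right = tight_successors(chain[-1])
        if not right:
            break
        chain.append(max(right, key=lambda j: (depth(j), -j)))
    while True:
        left = tight_predecessors(chain[0])
        if not left:
            break
        chain.insert(0, max(left, key=lambda j: (depth(j), -j)))
    if len(chain) < 2:
        primary_chain = None
    else:
        primary_chain = tuple(chain)

    # ---- all maximal chains (clusters are small; enumeration is cheap)
    maximal = _maximal_chains(members)
    maximal = [c for c in maximal if len(c) >= 2]
    if primary_chain is None and not maximal:
        log.info("cluster at %s:%d dropped: no >=2-junction chain",
                 cluster.chrom, cluster.span.start)
        return None
    if primary_chain is None:
        # greedy found nothing but enumeration did (cannot happen when a
        # chain exists through the deepest junction; fall back regardless)
        primary_chain = max(
            maximal, key=lambda c: (sum(depth(i) for i in c),)
        )

    ranked = sorted(
        maximal,
        key=lambda c: (-sum(depth(i) for i in c),
                       tuple(members[i].junction for i in c)),
    )
    chains: list[tuple[int, ...]] = [tuple(primary_chain)]
    for c in ranked:
        if tuple(c) not in chains:
            chains.append(tuple(c))
        if len(chains) >= max_isoforms:
            break

    strand = cluster.strand
    isoforms: list[Isoform] = []
    depths: dict[str, tuple[int, ...]] = {}
    seen_chains: set[tuple] = set()
    for k, c in enumerate(chains):
        introns = [members[i].junction for i in c]
        exons = _exon_chain(cluster.chrom, strand, introns, terminal_bp,
                            chrom_size)
        sig = tuple((e.start, e.end) for e in exons)
        if sig in seen_chains:
            continue
        seen_chains.add(sig)
        iid = f"{gene_id}.{len(isoforms) + 1}"
        isoforms.append(Isoform(iid, gene_id, tuple(exons), "other"))
        depths[iid] = tuple(members[i].depth for i in c)
    return NovelGeneModel(
        gene_id=gene_id,
        isoforms=isoforms,
        supporting_depths=depths,
        primary_isoform=isoforms[0].isoform_id,
    )


def _maximal_chains(members: list[NovelJunction]) -> list[tuple[int, ...]]:
    """All maximal junction chains under the compatibility order.

    A chain is maximal when no junction can be prepended, appended, or
    inserted between consecutive elements.
    """
    n = len(members)
    J = [m.junction for m in members]
    starts = [
        i for i in range(n)
        if not any(_compatible(J[k], J[i]) for k in range(n))
    ]
    out: list[tuple[int, ...]] = []

    def extend(chain: list[int]) -> None:
        last = chain[-1]
        succs = [j for j in range(n) if _compatible(J[last], J[j])]
        # tight successors: nothing fits between last and j
        tight = [
            j for j in succs
            if not any(
                _compatible(J[last], J[k]) and _compatible(J[k], J[j])
                for k in succs
            )
        ]
        if not tight:
            out.append(tuple(chain))
            return
        for j in tight:
            extend(chain + [j])

    for s in starts:
        extend([s])
    return out


def _exon_chain(
    chrom: str,
    strand: str,
    introns: Sequence[SpliceJunction],
    terminal_bp: int,
    chrom_size: int | None,
) -> list[GenomicInterval]:
    first, last = introns[0], introns[-1]
    start = first.intron_start - terminal_bp
    end = last.intron_end + terminal_bp
    if start < 0:
        log.warning("terminal exon truncated at start of %s", chrom)
        start = 0
    if chrom_size is not None and end > chrom_size:
        log.warning("terminal exon truncated at end of %s", chrom)
        end = chrom_size
    exons = [GenomicInterval(chrom, start, first.intron_start, strand)]
    for a, b in zip(introns, introns[1:]):
        exons.append(GenomicInterval(chrom, a.intron_end, b.intron_start,
                                     strand))
    exons.append(GenomicInterval(chrom, last.intron_end, end, strand))
    return exons


def discover_novel_genes(
    sj_tables: Sequence[ObservedJunctionTable],
    jidx: JunctionIndex,
    spans: Mapping[str, GenomicInterval],
    min_depth: int = 1,
    gap_bp: int = 2000,
    terminal_bp: int = 500,
    min_exons: int = 3,
    max_isoforms: int = 5,
    chrom_sizes: Mapping[str, int] | None = None,
    gene_prefix: str = "NOVELG",
) -> tuple[list[NovelGeneModel], int]:
    """Full discovery: filter, cluster, assemble; returns (models, n_2exon).

    ``n_2exon`` counts clusters rejected only because they could not yield
    a >=``min_exons``-exon model (single junctions or incompatible pairs);
    such 2-exon candidates are reported but never emitted as genes.  Gene
    ids are assigned in genomic order, so identical inputs give identical
    ids.
    """
    if min_exons < 3:
        raise ValidationError("min_exons < 3 is not supported: terminal "
                              "exons cannot be annotated from junction data")
    novel = find_novel_junctions(sj_tables, jidx, spans, min_depth)
    clusters = cluster_junctions(novel, gap_bp)
    models: list[NovelGeneModel] = []
    n_two_exon = 0
    counter = 1
    for cl in clusters:
        gid = f"{gene_prefix}{counter:04d}"
        size = None
        if chrom_sizes is not None:
            size = chrom_sizes.get(cl.chrom)
        model = assemble_models(cl, gid, terminal_bp, max_isoforms, size)
        if model is None:
            n_two_exon += 1
            continue
        # enforce the minimum exon count on every retained isoform
        kept = [iso for iso in model.isoforms if len(iso.exons) >= min_exons]
        if not kept:
            n_two_exon += 1
            continue
        model.isoforms = kept
        if model.primary_isoform not in {i.isoform_id for i in kept}:
            model.primary_isoform = kept[0].isoform_id
        models.append(model)
        counter += 1
    return models, n_two_exon


def novel_annotation(models: Sequence[NovelGeneModel]) -> AnnotationSet:
    """The novel models as an :class:`AnnotationSet` for quantification."""
    ann = AnnotationSet()
    for m in models:
        for iso in m.isoforms:
            ann.add(iso, ("novel",))
    return ann


def quantify_novel(
    models: Sequence[NovelGeneModel],
    read_tables: Mapping[str, ReadTable],
    sj_tables: Mapping[str, ObservedJunctionTable],
    totals: Mapping[str, int] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Counts/RPKM for novel isoforms plus a per-sample detection table.

    No zero rule is applied (each model's junctions are unique to it by
    construction) and detection carries *no* RPKM floor: a model is
    detected in a sample when any supporting junction has reads there or
    any exon read overlaps it.  Returns (matrix, gene x sample detection).
    """
    ann = novel_annotation(models)
    model_chroms = {m.chrom for m in models}
    counts: dict[str, dict[str, int]] = {}
    use_totals: dict[str, int] = {}
    for sample, table in read_tables.items():
        # totals must reflect the whole library, so restrict only the
        # overlap scan (models cover few chroms) after capturing n_unique
        n_uniq = table.n_unique
        sub = ReadTable(
            table.df[table.df["chrom"].isin(model_chroms)], table.sample_id
        )
        counts[sample] = exon_overlap_counts(sub, ann)
        use_totals[sample] = (
            int(totals[sample]) if totals is not None else n_uniq
        )
    mat = compute_rpkm(pd.DataFrame(counts), use_totals, ann.lengths_bp())

    det = pd.DataFrame(
        False, index=[m.gene_id for m in models], columns=list(read_tables)
    )
    for m in models:
        juncs = m.junctions()
        iso_ids = [i.isoform_id for i in m.isoforms]
        for sample in read_tables:
            sj = sj_tables.get(sample)
            j_hit = bool(sj) and any(sj.depth_of(j) > 0 for j in juncs)
            e_hit = int(mat.raw_counts.loc[iso_ids, sample].sum()) > 0
            det.loc[m.gene_id, sample] = bool(j_hit or e_hit)
    return mat, det


def detection_by_condition(
    detection: pd.DataFrame, design
) -> pd.DataFrame:
    """Gene x condition: detected in >=1 sample of the condition."""
    out = {}
    for cond, reps in design.replicates.items():
        cols = [r for r in reps if r in detection.columns]
        out[cond] = detection[cols].any(axis=1)
    return pd.DataFrame(out)


def summarize_novel(
    models: Sequence[NovelGeneModel],
    expr: ExpressionMatrix | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-gene structural statistics and their aggregates.

    Exon counts and lengths describe the primary isoform; internal exon
    statistics and transcript length exclude the two fixed-length terminal
    exons, whose extent is arbitrary rather than observed.
    """
    if not models:
        raise ValidationError("no models to summarise")
    rows = []
    for m in models:
        primary = next(i for i in m.isoforms
                       if i.isoform_id == m.primary_isoform)
        internal = primary.exons[1:-1]
        internal_lengths = [len(e) for e in internal]
        mean_rpkm = float("nan")
        if expr is not None:
            iso_ids = [i.isoform_id for i in m.isoforms
                       if i.isoform_id in expr.rpkm.index]
            if iso_ids:
                mean_rpkm = float(expr.rpkm.loc[iso_ids].mean(axis=1).max())
        rows.append(
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "start": primary.span.start,
                "end": primary.span.end,
                "strand": primary.strand,
                "n_isoforms": len(m.isoforms),
                "n_exons": len(primary.exons),
                "internal_exon_mean_bp": (
                    float(np.mean(internal_lengths)) if internal_lengths
                    else float("nan")
                ),
                "internal_exon_min_bp": (
                    min(internal_lengths) if internal_lengths else np.nan
                ),
                "internal_exon_max_bp": (
                    max(internal_lengths) if internal_lengths else np.nan
                ),
                "transcript_length_internal_bp": sum(internal_lengths),
                "mean_rpkm": mean_rpkm,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    all_internal = [
        length
        for m in models
        for length in (
            len(e)
            for e in next(
                i for i in m.isoforms if i.isoform_id == m.primary_isoform
            ).exons[1:-1]
        )
    ]
    agg = {
        "n_genes": float(len(models)),
        "n_multi_isoform": float((df["n_isoforms"] > 1).sum()),
        "mean_exons_per_gene": float(df["n_exons"].mean()),
        "min_exons": float(df["n_exons"].min()),
        "max_exons": float(df["n_exons"].max()),
        "mean_internal_exon_bp": (
            float(np.mean(all_internal)) if all_internal else float("nan")
        ),
        "min_internal_exon_bp": (
            float(min(all_internal)) if all_internal else float("nan")
        ),
        "max_internal_exon_bp": (
            float(max(all_internal)) if all_internal else float("nan")
        ),
        "mean_transcript_length_internal_bp": float(
            df["transcript_length_internal_bp"].mean()
        ),
        "mean_rpkm": float(df["mean_rpkm"].mean()),
        "max_rpkm": float(df["mean_rpkm"].max()),
    }
    return df, agg


def write_novel_gtf(models: Sequence[NovelGeneModel], path: str | Path) -> None:
    """Export models as GTF (round-trips through annotation loading)."""
    write_gtf(novel_annotation(models), path, source="rpelinc_novel")
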