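"""Transcript annotation database: GTF I/O, non-redundant merging, junction
indexing, gene spans.

The analysis starts from a merged, non-redundant transcript database (e.g.
GENCODE plus a lincRNA catalogue).  Two annotation sources frequently carry
the same transcript under different identifiers; after merging, no two
isoforms share an identical (chrom, strand, exon-chain) signature.

From the merged database we derive, per isoform, its set of splice
junctions and the subset of junctions found in no other isoform.  Those
isoform-unique junctions are the evidence used downstream to decide whether
a specific isoform of a multi-isoform gene is expressed at all.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .core import (
    GenomicInterval,
    Isoform,
    SpliceJunction,
    ValidationError,
    strands_compatible,
)

log = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lincRNA", "other")


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


def _normalise_biotype(raw: str | None) -> str:
    if raw is None:
        return "other"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lincRNA", "lncRNA"):
        return "lincRNA"
    return "other"


@dataclass
class AnnotationSet:
    """A collection of isoforms grouped into genes.

    ``source_labels`` records the originating annotation source(s) of each
    isoform; after a non-redundant merge an isoform may carry several.
    """

    isoforms: dict[str, Isoform] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)
    source_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, iso_ids in self.genes.items():
            if not iso_ids:
                raise ValidationError(f"gene {gid} has no isoforms")

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_of(self, isoform_id: str) -> str:
        return self.isoforms[isoform_id].gene_id

    def lengths_bp(self) -> dict[str, int]:
        return {i: iso.length_bp for i, iso in self.isoforms.items()}

    def biotype_of_gene(self, gene_id: str) -> str:
        """Gene biotype: lincRNA/protein_coding if any isoform says so."""
        bts = {self.isoforms[i].biotype for i in self.genes[gene_id]}
        for bt in ("protein_coding", "lincRNA"):
            if bt in bts:
                return bt
        return "other"

    def add(self, iso: Isoform, sources: tuple[str, ...] = ()) -> None:
        if iso.isoform_id in self.isoforms:
            raise ValidationError(f"duplicate isoform id {iso.isoform_id}")
        self.isoforms[iso.isoform_id] = iso
        self.genes.setdefault(iso.gene_id, []).append(iso.isoform_id)
        self.source_labels[iso.isoform_id] = sources

    def content_equal(self, other: "AnnotationSet") -> bool:
        """Equality of exon structures, gene grouping and biotypes."""
        if set(self.isoforms) != set(other.isoforms):
            return False
        for iid, iso in self.isoforms.items():
            o = other.isoforms[iid]
            if (
                iso.chain_signature() != o.chain_signature()
                or iso.gene_id != o.gene_id
                or iso.biotype != o.biotype
            ):
                return False
        return True


def _validate_gtf_line(lineno: int, line: str) -> None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GTFParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
    if fields[2] == "exon" and start > end:
        raise ValidationError(
            f"line {lineno}: exon start {start} > end {end}"
        )


def load_gtf(path: str | Path, source_label: str = "") -> AnnotationSet:
    """Read exon features from a GTF file into an :class:`AnnotationSet`.

    One isoform is built per ``transcript_id``; exons are sorted by start.
    Biotype is taken from ``gene_type``/``transcript_type`` (falling back to
    ``gene_biotype``/``transcript_biotype``) when present, else ``other``.
    GTF coordinates (1-based inclusive) are converted to internal 0-based
    half-open.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_feature_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            _validate_gtf_line(lineno, line)
            n_feature_lines += 1
    if n_feature_lines == 0:
        return AnnotationSet()

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - guarded by pre-validation
        raise GTFParseError(f"{path}: {exc}") from exc

    by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_biotype: dict[str, str] = {}
    for feat in db.features_of_type("exon"):
        attrs = feat.attributes
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise GTFParseError(
                f"{path}: exon at {feat.seqid}:{feat.start} lacks "
                "gene_id/transcript_id"
            )
        tid = attrs["transcript_id"][0]
        tx_gene[tid] = attrs["gene_id"][0]
        raw_bt = None
        for key in ("transcript_type", "gene_type",
                    "transcript_biotype", "gene_biotype"):
            if key in attrs:
                raw_bt = attrs[key][0]
                break
        tx_biotype[tid] = _normalise_biotype(raw_bt)
        by_tx.setdefault(tid, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )

    ann = AnnotationSet()
    for tid in by_tx:
        exons = tuple(sorted(by_tx[tid], key=lambda e: (e.start, e.end)))
        iso = Isoform(tid, tx_gene[tid], exons, tx_biotype[tid])
        sources = (source_label,) if source_label else ()
        ann.add(iso, sources)
    return ann


def write_gtf(ann: AnnotationSet, path: str | Path, source: str = "rpelinc") -> None:
    """Write gene/transcript/exon features, 1-based inclusive coordinates."""
    lines: list[str] = []

    def feat(chrom, kind, start0, end0, strand, attrs) -> str:
        attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
        return (
            f"{chrom}\t{source}\t{kind}\t{start0 + 1}\t{end0}\t.\t{strand}"
            f"\t.\t{attr_str}"
        )

    spans = gene_spans(ann)
    for gid in sorted(ann.genes, key=lambda g: (spans[g].chrom, spans[g].start, g)):
        sp = spans[gid]
        bt = ann.biotype_of_gene(gid)
        lines.append(
            feat(sp.chrom, "gene", sp.start, sp.end, sp.strand,
                 [("gene_id", gid), ("gene_type", bt)])
        )
        for iid in sorted(ann.genes[gid]):
            iso = ann.isoforms[iid]
            tx_attrs = [("gene_id", gid), ("transcript_id", iid),
                        ("gene_type", iso.biotype)]
            lines.append(
                feat(iso.chrom, "transcript", iso.span.start, iso.span.end,
                     iso.strand, tx_attrs)
            )
            for e in iso.exons:
                lines.append(
                    feat(iso.chrom, "exon", e.start, e.end, iso.strand, tx_attrs)
                )
    Path(path).write_text("\n".join(lines) + "\n")


def merge_nonredundant(sets: Sequence[AnnotationSet]) -> AnnotationSet:
    """Collapse isoforms with identical (chrom, strand, exon-chain) signatures.

    The first source wins for the retained id and gene membership; the
    provenance of every collapsed duplicate is kept in ``source_labels``.
    Identical chains under different gene ids collapse too ("non-redundant"
    at the transcript level).  Isoform-id collisions across sources with
    *different* exon chains are resolved by namespacing the later id with
    its source label (or positional index).
    """
    if not sets:
        raise ValidationError("merge requires >=1 annotation set")
    merged = AnnotationSet()
    by_signature: dict[tuple, str] = {}
    for idx, ann in enumerate(sets):
        for iid, iso in ann.isoforms.items():
            sig = iso.chain_signature()
            sources = ann.source_labels.get(iid, ())
            if sig in by_signature:
                kept = by_signature[sig]
                merged.source_labels[kept] = tuple(
                    dict.fromkeys(merged.source_labels[kept] + sources)
                )
                continue
            new_id = iid
            if new_id in merged.isoforms:
                ns = sources[0] if sources else f"src{idx}"
                new_id = f"{ns}:{iid}"
                if new_id in merged.isoforms:
                    raise ValidationError(
                        f"isoform id collision not resolvable: {iid}"
                    )
                iso = Isoform(new_id, iso.gene_id, iso.exons, iso.biotype)
            merged.add(iso, sources)
            by_signature[sig] = new_id
    return merged


@dataclass
class JunctionIndex:
    """Per-isoform junction sets plus the database-wide unique subset.

    A junction is *unique* when exactly one isoform in the whole database
    contains it (``scope="database"``), or exactly one isoform of its gene
    (``scope="gene"``).  Matching is coordinate-exact with undefined-strand
    leniency.
    """

    by_isoform: dict[str, frozenset[SpliceJunction]]
    unique_by_isoform: dict[str, frozenset[SpliceJunction]]
    all_annotated: frozenset[SpliceJunction]
    scope: str = "database"
    # coords -> strands seen, for lenient membership tests
    _coord_strands: dict[tuple[str, int, int], set[str]] = field(
        default_factory=dict, repr=False
    )

    def contains(self, junction: SpliceJunction) -> bool:
        """Lenient membership: coords match and strands are compatible."""
        strands = self._coord_strands.get(junction.coords)
        if strands is None:
            return False
        return any(strands_compatible(junction.strand, s) for s in strands)

    def unique_junction_table(self, ann: AnnotationSet) -> "pd.DataFrame":
        import pandas as pd

        rows = []
        for iid in sorted(self.unique_by_isoform):
            for j in sorted(self.unique_by_isoform[iid]):
                rows.append(
                    {
                        "isoform_id": iid,
                        "gene_id": ann.gene_of(iid),
                        "chrom": j.chrom,
                        "intron_start": j.intron_start,
                        "intron_end": j.intron_end,
                        "strand": j.strand,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["isoform_id", "gene_id", "chrom",
                     "intron_start", "intron_end", "strand"],
        )


def derive_junctions(ann: AnnotationSet, scope: str = "database") -> JunctionIndex:
    """Build the junction index and isoform-unique junction sets.

    ``scope="database"`` (default): a junction is unique iff exactly one
    isoform anywhere contains it.  ``scope="gene"``: uniqueness is assessed
    among the isoforms of each gene only.
    """
    if scope not in ("database", "gene"):
        raise ValidationError(f"unknown uniqueness scope {scope!r}")
    by_isoform = {
        iid: frozenset(iso.junctions()) for iid, iso in ann.isoforms.items()
    }
    # owners keyed on strand-free coords; a '.' copy of a stranded junction
    # matches it, while '+' and '-' at the same coords stay distinct
    owners: dict[tuple[str, int, int], list[tuple[str, str]]] = {}
    for iid, juncs in by_isoform.items():
        for j in juncs:
            owners.setdefault(j.coords, []).append((iid, j.strand))

    unique: dict[str, set[SpliceJunction]] = {iid: set() for iid in by_isoform}
    for iid, juncs in by_isoform.items():
        gid = ann.gene_of(iid)
        for j in juncs:
            own = {
                o
                for o, s in owners[j.coords]
                if strands_compatible(s, j.strand)
            }
            if scope == "gene":
                own = {o for o in own if ann.gene_of(o) == gid}
            if len(own) == 1:
                unique[iid].add(j)

    all_annotated = frozenset().union(*by_isoform.values()) if by_isoform else frozenset()
    coord_strands: dict[tuple[str, int, int], set[str]] = {}
    for j in all_annotated:
        coord_strands.setdefault(j.coords, set()).add(j.strand)
    return JunctionIndex(
        by_isoform=by_isoform,
        unique_by_isoform={i: frozenset(s) for i, s in unique.items()},
        all_annotated=all_annotated,
        scope=scope,
        _coord_strands=coord_strands,
    )


def gene_spans(ann: AnnotationSet) -> dict[str, GenomicInterval]:
    """Per gene: min exon start to max exon end across its isoforms."""
    spans: dict[str, GenomicInterval] = {}
    for gid, iso_ids in ann.genes.items():
        isos = [ann.isoforms[i] for i in iso_ids]
        start = min(iso.exons[0].start for iso in isos)
        end = max(iso.exons[-1].end for iso in isos)
        spans[gid] = GenomicInterval(isos[0].chrom, start, end, isos[0].strand)
    return spans
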