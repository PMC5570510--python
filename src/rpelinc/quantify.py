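"""Isoform quantification from uniquely-mapped reads and splice junctions.

Counting model: raw counts are generated per exon (a read counts toward an
exon if any aligned block overlaps it by >=1 bp) and summed over each
isoform's exons.  Reads falling within overlapping isoforms count toward
every isoform they overlap — *unless* the unique-junction zero rule fires:
an isoform that owns at least one junction found in no other isoform, none
of which has any junction-spanning reads in the sample, is considered not
expressed and given a raw count of zero.

RPKM = raw count x 1e9 / (total unique reads x transcript length in bp).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, JunctionIndex
from .core import (
    GenomicInterval,
    ReadRecord,
    SpliceJunction,
    ValidationError,
    strands_compatible,
)

log = logging.getLogger(__name__)

_STAR_STRAND = {0: ".", 1: "+", 2: "-"}
_STAR_STRAND_INV = {".": 0, "+": 1, "-": 2}

SJ_COLUMNS = [
    "chrom", "intron_start", "intron_end", "strand_code",
    "motif", "annotated", "unique_reads", "multi_reads", "overhang",
]

READ_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "block_count", "block_sizes", "block_starts", "unique",
]


class ObservedJunctionTable:
    """Per-sample junction read depths in the aligner's junction dialect.

    Depths are *unique-read* counts; the multi-mapper column of the input
    table is ignored.  Lookup is coordinate-exact with undefined-strand
    leniency.
    """

    def __init__(
        self, sample_id: str, depths: Mapping[SpliceJunction, int]
    ) -> None:
        for j, d in depths.items():
            if d < 0:
                raise ValidationError(f"negative junction count for {j}")
        self.sample_id = sample_id
        self.depths: dict[SpliceJunction, int] = dict(depths)
        self._by_coords: dict[tuple[str, int, int], list[tuple[str, int]]] = {}
        for j, d in self.depths.items():
            self._by_coords.setdefault(j.coords, []).append((j.strand, d))

    def depth_of(self, junction: SpliceJunction) -> int:
        """Depth of the matching junction (0 if unobserved)."""
        hits = self._by_coords.get(junction.coords, ())
        return sum(
            d for s, d in hits if strands_compatible(s, junction.strand)
        )

    def junctions(self) -> list[SpliceJunction]:
        return list(self.depths)

    def __len__(self) -> int:
        return len(self.depths)


def read_sj_table(path: str | Path, sample_id: str) -> ObservedJunctionTable:
    """Parse a 9-column splice-junction table (STAR ``SJ.out.tab`` dialect).

    Columns: chrom, intron start (1-based), intron end (1-based inclusive),
    strand code (0 undefined / 1 ``+`` / 2 ``-``), intron motif, annotated
    flag, unique-read count, multi-read count, max overhang.  Coordinates
    are converted to 0-based half-open; depth is the unique-read column.
    """
    path = Path(path)
    depths: dict[SpliceJunction, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path} line {lineno}: expected 9 columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            start1, end1 = int(fields[1]), int(fields[2])
            code = int(fields[3])
            uniq = int(fields[6])
            if uniq < 0:
                raise ValidationError(
                    f"{path} line {lineno}: negative unique-read count"
                )
            if code not in _STAR_STRAND:
                raise ValueError(
                    f"{path} line {lineno}: bad strand code {code}"
                )
            j = SpliceJunction(chrom, start1 - 1, end1, _STAR_STRAND[code])
            depths[j] = depths.get(j, 0) + uniq
    return ObservedJunctionTable(sample_id, depths)


def write_sj_table(table: ObservedJunctionTable, path: str | Path) -> None:
    """Inverse of :func:`read_sj_table` (motif/annotated/overhang zeroed)."""
    lines = []
    for j in sorted(table.depths):
        d = table.depths[j]
        lines.append(
            f"{j.chrom}\t{j.intron_start + 1}\t{j.intron_end}\t"
            f"{_STAR_STRAND_INV[j.strand]}\t0\t0\t{d}\t0\t0"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


class ReadTable:
    """A per-sample table of block-aligned reads (BED12-like dialect).

    Stored columnar for speed; :meth:`records` materialises
    :class:`~rpelinc.core.ReadRecord` objects for small inputs.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "") -> None:
        self.df = df
        self.sample_id = sample_id

    @classmethod
    def from_records(
        cls, reads: Iterable[ReadRecord], sample_id: str = ""
    ) -> "ReadTable":
        rows = []
        for i, r in enumerate(reads):
            sizes = ",".join(str(len(b)) for b in r.blocks)
            starts = ",".join(str(b.start - r.blocks[0].start) for b in r.blocks)
            rows.append(
                {
                    "chrom": r.chrom,
                    "start": r.blocks[0].start,
                    "end": r.blocks[-1].end,
                    "name": r.name or f"read{i}",
                    "score": 0,
                    "strand": r.strand,
                    "block_count": len(r.blocks),
                    "block_sizes": sizes,
                    "block_starts": starts,
                    "unique": int(r.unique),
                }
            )
        return cls(pd.DataFrame(rows, columns=READ_COLUMNS), sample_id)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str = "") -> "ReadTable":
        df = pd.read_csv(
            str(path), sep="\t", names=READ_COLUMNS, header=None,
            dtype={
                "chrom": str, "start": np.int64, "end": np.int64,
                "name": str, "score": np.int64, "strand": str,
                "block_count": np.int64, "block_sizes": str,
                "block_starts": str, "unique": np.int64,
            },
        )
        return cls(df, sample_id)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(str(path), sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_unique(self) -> int:
        """Library-wide total of uniquely-mapped reads (RPKM denominator)."""
        return int((self.df["unique"] != 0).sum())

    def records(self) -> list[ReadRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            sizes = [int(x) for x in str(row.block_sizes).split(",") if x != ""]
            offs = [int(x) for x in str(row.block_starts).split(",") if x != ""]
            blocks = tuple(
                GenomicInterval(row.chrom, row.start + o, row.start + o + s,
                                row.strand)
                for o, s in zip(offs, sizes)
            )
            out.append(
                ReadRecord(row.chrom, blocks, row.strand,
                           bool(row.unique), str(row.name))
            )
        return out

    def unique_blocks(self) -> pd.DataFrame:
        """Long table of aligned blocks of uniquely-mapped reads.

        Columns: chrom, bstart, bend, read_idx.
        """
        df = self.df[self.df["unique"] != 0]
        if df.empty:
            return pd.DataFrame(
                columns=["chrom", "bstart", "bend", "read_idx"]
            )
        single = df[df["block_count"] <= 1]
        multi = df[df["block_count"] > 1]
        parts = []
        if len(single):
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": single["chrom"].to_numpy(),
                        "bstart": single["start"].to_numpy(),
                        "bend": single["end"].to_numpy(),
                        "read_idx": single.index.to_numpy(),
                    }
                )
            )
        for row in multi.itertuples():
            sizes = [int(x) for x in str(row.block_sizes).split(",") if x != ""]
            offs = [int(x) for x in str(row.block_starts).split(",") if x != ""]
            for o, s in zip(offs, sizes):
                parts.append(
                    pd.DataFrame(
                        {
                            "chrom": [row.chrom],
                            "bstart": [row.start + o],
                            "bend": [row.start + o + s],
                            "read_idx": [row.Index],
                        }
                    )
                )
        out = pd.concat(parts, ignore_index=True)
        return out


def _as_read_table(reads) -> ReadTable:
    if isinstance(reads, ReadTable):
        return reads
    return ReadTable.from_records(list(reads))


def _exon_instances(ann: AnnotationSet):
    """Flatten annotation into per-exon-instance arrays, grouped by chrom.

    The same genomic exon shared by two isoforms yields two instances, so a
    read overlapping it counts toward both isoforms.
    """
    iso_ids = sorted(ann.isoforms)
    iso_pos = {iid: k for k, iid in enumerate(iso_ids)}
    per_chrom: dict[str, dict[str, list]] = {}
    for iid in iso_ids:
        iso = ann.isoforms[iid]
        d = per_chrom.setdefault(
            iso.chrom, {"start": [], "end": [], "iso": []}
        )
        for e in iso.exons:
            d["start"].append(e.start)
            d["end"].append(e.end)
            d["iso"].append(iso_pos[iid])
    out = {}
    for chrom, d in per_chrom.items():
        out[chrom] = (
            np.asarray(d["start"]), np.asarray(d["end"]), np.asarray(d["iso"])
        )
    return iso_ids, out


def exon_overlap_counts(reads, ann: AnnotationSet) -> dict[str, int]:
    """Exon-summed raw counts per isoform, before any zero rule.

    A (read, exon-instance) pair contributes 1 when any block of the read
    overlaps the exon by >=1 bp; an isoform's count sums its exon
    instances.  Multi-mapping reads (``unique`` false) are discarded.
    """
    table = _as_read_table(reads)
    iso_ids, exons_by_chrom = _exon_instances(ann)
    counts = np.zeros(len(iso_ids), dtype=np.int64)

    blocks = table.unique_blocks()
    for chrom, grp in blocks.groupby("chrom", sort=False):
        if chrom not in exons_by_chrom:
            log.warning("reads on %s not present in annotation; ignored", chrom)
            continue
        estart, eend, eiso = exons_by_chrom[chrom]
        order = np.argsort(estart, kind="stable")
        estart, eend, eiso = estart[order], eend[order], eiso[order]
        # prefix max of exon ends enables a contiguous candidate scan
        prefix_max_end = np.maximum.accumulate(eend)
        bstart = grp["bstart"].to_numpy()
        bend = grp["bend"].to_numpy()
        ridx = grp["read_idx"].to_numpy()
        # exons with start < block_end form the right boundary; scan left
        # until the running max of exon ends drops at or below block start
        hi = np.searchsorted(estart, bend, side="left")
        pairs: set[tuple[int, int]] = set()
        for bs, rid, h in zip(bstart, ridx, hi):
            k = h - 1
            while k >= 0 and prefix_max_end[k] > bs:
                if eend[k] > bs:  # overlap; estart[k] < block end by choice of h
                    pairs.add((int(rid), k))
                k -= 1
        for _, k in pairs:
            counts[eiso[k]] += 1
    return dict(zip(iso_ids, counts.tolist()))


def apply_zero_rule(
    counts: Mapping[str, int],
    jidx: JunctionIndex,
    sj: ObservedJunctionTable,
    variant: str = "all_unobserved",
) -> dict[str, int]:
    """Zero out isoforms whose unique junctions carry no reads.

    ``variant="all_unobserved"`` (default): an isoform owning >=1 unique
    junction is zeroed iff *none* of its unique junctions has depth > 0 —
    a junction with spanning reads is direct evidence the isoform is
    expressed, so any observed unique junction rescues it.
    ``variant="any_unobserved"``: zeroed if *any* unique junction has
    depth 0 (a stricter reading).  Isoforms with no unique junction are
    never zeroed: there is no isoform-specific evidence either way.
    """
    if variant not in ("all_unobserved", "any_unobserved"):
        raise ValidationError(f"unknown zero-rule variant {variant!r}")
    out = dict(counts)
    for iid, uniq in jidx.unique_by_isoform.items():
        if iid not in out or not uniq:
            continue
        depths = [sj.depth_of(j) for j in uniq]
        if variant == "all_unobserved":
            zero = all(d == 0 for d in depths)
        else:
            zero = any(d == 0 for d in depths)
        if zero:
            out[iid] = 0
    return out


def count_isoforms(
    reads,
    ann: AnnotationSet,
    jidx: JunctionIndex,
    sj: ObservedJunctionTable,
    zero_rule: str | None = "all_unobserved",
) -> dict[str, int]:
    """Raw isoform counts: exon-overlap counting plus the zero rule.

    ``reads`` may be a :class:`ReadTable` or an iterable of
    :class:`~rpelinc.core.ReadRecord`.  Pass ``zero_rule=None`` to skip the
    unique-junction rule (used for novel-gene quantification, where every
    junction is unique to its model by construction).
    """
    counts = exon_overlap_counts(reads, ann)
    if zero_rule is not None:
        counts = apply_zero_rule(counts, jidx, sj, zero_rule)
    return counts


@dataclass
class ExpressionMatrix:
    """Isoform x sample raw counts and RPKM.

    ``rpkm = raw_counts * 1e9 / (total_unique_reads * lengths_bp)``, the
    reads-per-kilobase-per-million normalisation computed from library-wide
    unique-read totals and transcript lengths.
    """

    raw_counts: pd.DataFrame
    rpkm: pd.DataFrame
    total_unique_reads: dict[str, int]
    lengths_bp: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.raw_counts.columns)

    @property
    def isoforms(self) -> list[str]:
        return list(self.raw_counts.index)

    def restrict(self, isoform_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = [i for i in isoform_ids if i in self.raw_counts.index]
        return ExpressionMatrix(
            self.raw_counts.loc[ids],
            self.rpkm.loc[ids],
            self.total_unique_reads,
            {i: self.lengths_bp[i] for i in ids},
        )


def compute_rpkm(
    counts: pd.DataFrame | Mapping[str, Mapping[str, float]],
    total_unique_reads: Mapping[str, int],
    lengths_bp: Mapping[str, int],
) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from raw counts.

    ``counts`` is an isoform x sample frame (or nested mapping
    sample -> isoform -> count).  Totals must be positive and lengths
    positive; violations raise :class:`ValidationError`.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts)
    counts = counts.sort_index()
    for s in counts.columns:
        if s not in total_unique_reads:
            raise ValidationError(f"no total unique reads for sample {s}")
        if total_unique_reads[s] <= 0:
            raise ValidationError(f"total unique reads must be > 0 for {s}")
    for i in counts.index:
        if i not in lengths_bp:
            raise ValidationError(f"no transcript length for isoform {i}")
        if lengths_bp[i] <= 0:
            raise ValidationError(f"transcript length must be > 0 for {i}")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative raw count")

    totals = np.array([total_unique_reads[s] for s in counts.columns],
                      dtype=float)
    lengths = np.array([lengths_bp[i] for i in counts.index], dtype=float)
    rpkm = counts.to_numpy(dtype=float) * 1e9 / np.outer(lengths, totals)
    rpkm_df = pd.DataFrame(rpkm, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(
        raw_counts=counts,
        rpkm=rpkm_df,
        total_unique_reads={s: int(total_unique_reads[s]) for s in counts.columns},
        lengths_bp={i: int(lengths_bp[i]) for i in counts.index},
    )


def quantify_samples(
    read_tables: Mapping[str, ReadTable],
    sj_tables: Mapping[str, ObservedJunctionTable],
    ann: AnnotationSet,
    jidx: JunctionIndex,
    zero_rule: str | None = "all_unobserved",
) -> ExpressionMatrix:
    """End-to-end per-sample counting and RPKM over a sample collection."""
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for sample, table in read_tables.items():
        sj = sj_tables.get(sample) or ObservedJunctionTable(sample, {})
        counts[sample] = count_isoforms(table, ann, jidx, sj, zero_rule)
        totals[sample] = table.n_unique
    return compute_rpkm(pd.DataFrame(counts), totals, ann.lengths_bp())
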