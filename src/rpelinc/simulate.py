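"""Synthetic RNA-seq workspace generator with known ground truth.

Emulates the statistical structure of a three-condition RPE study — fetal
RPE (fRPE), stem-cell-derived RPE (iPS_RPE) and undifferentiated stem
cells (iPS), three replicates each — at desk scale:

* a merged annotation of multi-isoform protein-coding genes (shared exons
  and junctions, so isoform-unique junction logic is exercised) plus
  mostly single-isoform lincRNA genes;
* per-gene condition profiles in which the two RPE conditions share a
  per-gene expression shift while the stem-cell condition gets an
  independent one, so the RPE pair is the more concordant pair;
* active lincRNAs drawn so that the bulk of them land in the low
  (1, 10] RPKM decade;
* per-sample uniquely-aligned read tables (single-block exon reads plus
  junction-spanning two-block reads), junction tables in the aligner
  dialect, a design table, gene panels, and planted intergenic novel
  genes with depth-1 decoy junctions.

Everything is deterministic under the configured seed; per-sample streams
are derived independently so adding a sample never perturbs earlier ones.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, write_gtf
from .core import GenomicInterval, Isoform, SpliceJunction, ValidationError
from .expression import ConditionDesign
from .quantify import (
    READ_COLUMNS,
    ObservedJunctionTable,
    ReadTable,
    write_sj_table,
)

log = logging.getLogger(__name__)

CONDITIONS = ("fRPE", "iPS_RPE", "iPS")

# per-class target RPKM ranges (log-uniform draws) and activity patterns
_CLASS_RPKM = {
    "high": (100.0, 1500.0),
    "broad": (3.0, 80.0),
    "signature": (10.0, 150.0),
    "ips_specific": (5.0, 100.0),
    "contam_photoreceptor": (2.5, 20.0),
    "contam_choroid": (2.5, 20.0),
    "lincRNA": (3.2, 7.0),
}
_ALWAYS_ON = {"high", "broad"}

# lincRNA activity patterns: subset of conditions -> probability; the fRPE
# condition carries the most active lincRNAs, mirroring an RPE-skewed
# lincRNA complement
_LINC_PATTERNS = (
    (("fRPE", "iPS_RPE", "iPS"), 0.30),
    (("fRPE", "iPS_RPE"), 0.20),
    (("fRPE",), 0.20),
    (("iPS",), 0.15),
    (("iPS_RPE",), 0.05),
    (("fRPE", "iPS"), 0.05),
    (("iPS_RPE", "iPS"), 0.05),
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed is mandatory.

    Defaults describe the study conditions the package is tested under:
    200 annotated genes (140 coding / 60 lincRNA), 3 conditions x 3
    replicates, 150k uniquely-mapped reads per sample, log-normal
    replicate noise, and a handful of planted intergenic novel genes plus
    depth-1 decoy junctions.
    """

    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000
        }
    )
    n_coding: int = 140
    n_lincrna: int = 60
    n_high_expr: int = 20
    n_signature: int = 25
    n_ips_specific: int = 15
    n_contam_photoreceptor: int = 10
    n_contam_choroid: int = 8
    conditions: tuple[str, ...] = CONDITIONS
    n_replicates: int = 3
    library_depth: int = 150_000  # unique reads per sample
    read_length: int = 100
    replicate_sigma: float = 0.25  # log-normal replicate noise (natural log)
    rpe_effect_sigma: float = 0.4  # per-gene shift shared by RPE conditions
    ips_effect_sigma: float = 0.6  # independent per-gene shift for iPS
    lincrna_effect_sigma: float = 0.25
    junction_depth_factor: float = 1.0
    junction_read_fraction: float = 0.15  # of a transcript's reads, as 2-block
    multimapper_fraction: float = 0.05
    # planted novel genes and decoys
    n_novel_genes: int = 10
    novel_exon_range: tuple[int, int] = (3, 6)
    novel_junction_depth: float = 8.0  # per-sample Poisson mean when active
    novel_exon_read_depth: float = 2.0
    novel_alt_isoform_prob: float = 0.35
    novel_active_prob: dict[str, float] = field(
        default_factory=lambda: {"fRPE": 1.0, "iPS_RPE": 0.85, "iPS": 0.45}
    )
    n_decoy_junctions: int = 10
    expression_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("simulation seed is mandatory")
        counts = [
            self.n_coding, self.n_lincrna, self.n_novel_genes,
            self.n_decoy_junctions, self.library_depth, self.n_replicates,
        ]
        if any(c < 0 for c in counts):
            raise ValidationError("negative count in simulation config")
        special = (self.n_high_expr + self.n_signature + self.n_ips_specific
                   + self.n_contam_photoreceptor + self.n_contam_choroid)
        if special > self.n_coding:
            raise ValidationError(
                "special coding classes exceed n_coding"
            )
        for p in (self.junction_read_fraction, self.multimapper_fraction,
                  self.novel_alt_isoform_prob):
            if not 0 <= p <= 1:
                raise ValidationError("probability outside [0, 1]")

    @classmethod
    def with_proportional_classes(
        cls, seed: int, n_coding: int = 140, **kwargs
    ) -> "SimulationConfig":
        """Scale the special coding-gene classes with ``n_coding``.

        Keeps the default class mix (high expressers, RPE signature,
        stem-cell-specific, contamination panels) at roughly the default
        proportions for any gene count.
        """
        frac = n_coding / 140
        return cls(
            seed=seed,
            n_coding=n_coding,
            n_high_expr=max(1, round(20 * frac)),
            n_signature=max(1, round(25 * frac)),
            n_ips_specific=max(1, round(15 * frac)),
            n_contam_photoreceptor=max(1, round(10 * frac)),
            n_contam_choroid=max(1, round(8 * frac)),
            **kwargs,
        )


@dataclass
class PlantedNovelGene:
    """Ground truth for one planted intergenic novel gene."""

    gene_id: str
    chrom: str
    strand: str
    main_junctions: tuple[SpliceJunction, ...]
    alt_junction: SpliceJunction | None
    internal_exons: tuple[tuple[int, int], ...]  # truth chain between introns
    active_conditions: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Everything needed to verify pipeline output against the simulation."""

    isoform_table: pd.DataFrame  # per isoform: gene, biotype, class, targets
    expected_calls: pd.DataFrame  # isoform x condition bool
    gene_classes: dict[str, str]
    novel_genes: list[PlantedNovelGene]
    decoy_junctions: list[SpliceJunction]
    panels: dict[str, list[str]]
    free_space: dict[str, list[tuple[int, int]]]  # intergenic, for background

    def expected_gene_calls(self) -> pd.DataFrame:
        genes = self.isoform_table["gene_id"]
        out = self.expected_calls.groupby(genes).any()
        out.index.name = None
        return out


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *stream]))


# --------------------------------------------------------------------------
# annotation simulation


def _gene_structure(rng: np.random.Generator, biotype: str):
    """Draw exon/intron skeleton (lengths) for one gene."""
    if biotype == "lincRNA":
        n_exons = int(rng.integers(3, 5))
        exon_lengths = rng.integers(600, 1200, size=n_exons)
        intron_lengths = rng.integers(500, 3000, size=n_exons - 1)
    else:
        n_exons = int(rng.integers(4, 11))
        exon_lengths = rng.integers(120, 400, size=n_exons)
        intron_lengths = rng.integers(300, 2000, size=n_exons - 1)
    return exon_lengths.tolist(), intron_lengths.tolist()


def _isoforms_for_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    offset: int,
    exon_lengths: list[int],
    intron_lengths: list[int],
    biotype: str,
    n_iso: int,
) -> list[Isoform]:
    """Build isoforms as exon chains: the full chain plus skip variants.

    Isoform k >= 2 skips the k-th internal exon, which gives every isoform
    at least one junction private to it within the gene while exons are
    shared.  With small probability the second isoform is instead a
    terminal-start variant with the *same* junction chain, producing a
    gene whose isoforms own no unique junction at all.
    """
    starts, ends = [], []
    pos = offset
    for e_len, i_len in zip(exon_lengths, intron_lengths + [0]):
        starts.append(pos)
        ends.append(pos + int(e_len))
        pos += int(e_len) + int(i_len)
    n_exons = len(exon_lengths)
    full = [(s, e) for s, e in zip(starts, ends)]

    isoforms = []

    def mk(idx: int, chain: list[tuple[int, int]]) -> Isoform:
        exons = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in chain
        )
        return Isoform(f"{gene_id}.t{idx}", gene_id, exons, biotype)

    isoforms.append(mk(1, full))
    terminal_variant = (
        n_iso == 2 and n_exons >= 3 and rng.random() < 0.10
    )
    if terminal_variant:
        # same junctions, shifted transcription start
        shift = int(rng.integers(30, min(80, exon_lengths[0] - 20)))
        chain = [(full[0][0] + shift, full[0][1])] + full[1:]
        isoforms.append(mk(2, chain))
        return isoforms
    internal = list(range(1, n_exons - 1))
    for k in range(2, n_iso + 1):
        skip = internal[(k - 2) % len(internal)]
        chain = [full[i] for i in range(n_exons) if i != skip]
        isoforms.append(mk(k, chain))
    return isoforms


def _draw_class_labels(cfg: SimulationConfig, rng: np.random.Generator):
    labels = (
        ["high"] * cfg.n_high_expr
        + ["signature"] * cfg.n_signature
        + ["ips_specific"] * cfg.n_ips_specific
        + ["contam_photoreceptor"] * cfg.n_contam_photoreceptor
        + ["contam_choroid"] * cfg.n_contam_choroid
    )
    labels += ["broad"] * (cfg.n_coding - len(labels))
    rng.shuffle(labels)
    return labels


def simulate_annotation(
    cfg: SimulationConfig,
) -> tuple[AnnotationSet, SyntheticTruth]:
    """Generate the annotated transcriptome and the full ground truth.

    Planted novel genes are recorded in the truth but *excluded* from the
    returned annotation, as are decoy junction positions.  Raises
    :class:`ValidationError` when the genes do not fit the chromosomes.
    """
    rng = _rng(cfg.seed, 0)
    chroms = sorted(cfg.chrom_sizes)
    cursors = {c: 10_000 for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    coding_classes = _draw_class_labels(cfg, rng)
    # placement plan: all features shuffled so novel genes and decoys are
    # interleaved between annotated genes
    plan: list[tuple[str, str]] = (
        [("gene", cls) for cls in coding_classes]
        + [("gene", "lincRNA")] * cfg.n_lincrna
        + [("novel", "")] * cfg.n_novel_genes
        + [("decoy", "")] * cfg.n_decoy_junctions
    )
    rng.shuffle(plan)

    ann = AnnotationSet()
    gene_classes: dict[str, str] = {}
    novel_genes: list[PlantedNovelGene] = []
    decoys: list[SpliceJunction] = []
    gene_n = 0
    linc_n = 0
    novel_n = 0

    def place(chrom: str, extent: int, margin: int, pad: int = 200) -> int:
        start = cursors[chrom] + margin
        end = start + extent
        if end + margin > cfg.chrom_sizes[chrom]:
            raise ValidationError(
                f"features exceed size of {chrom}; enlarge chrom_sizes"
            )
        cursors[chrom] = end
        occupied[chrom].append((start - pad, end + pad))
        return start

    for kind, cls in plan:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "gene":
            biotype = "lincRNA" if cls == "lincRNA" else "protein_coding"
            exon_lengths, intron_lengths = _gene_structure(rng, biotype)
            extent = sum(exon_lengths) + sum(intron_lengths)
            margin = int(rng.integers(8_000, 20_000))
            offset = place(chrom, extent, margin)
            if biotype == "lincRNA":
                linc_n += 1
                gid = f"LINC{linc_n:04d}"
                n_iso = 1 if rng.random() < 0.85 else 2
            else:
                gene_n += 1
                gid = f"GENE{gene_n:04d}"
                n_iso = int(rng.choice([1, 2, 3, 4],
                                       p=[0.35, 0.35, 0.20, 0.10]))
                n_iso = min(n_iso, len(exon_lengths) - 1)
            gene_classes[gid] = cls if biotype != "lincRNA" else "lincRNA"
            for iso in _isoforms_for_gene(
                rng, gid, chrom, strand, offset,
                exon_lengths, intron_lengths, biotype, n_iso,
            ):
                ann.add(iso, ("sim",))
        elif kind == "novel":
            novel_n += 1
            novel_genes.append(
                _plant_novel_gene(cfg, rng, f"PLANTED{novel_n:04d}",
                                  chrom, strand, place)
            )
        else:  # decoy
            offset = place(chrom, 900, 3_000)
            decoys.append(
                SpliceJunction(chrom, offset, offset + 700, strand)
            )

    truth = _build_truth(cfg, rng, ann, gene_classes, novel_genes, decoys)
    truth.free_space = _free_space(cfg, occupied)
    return ann, truth


def _plant_novel_gene(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    place,
) -> PlantedNovelGene:
    n_exons = int(rng.integers(cfg.novel_exon_range[0],
                               cfg.novel_exon_range[1] + 1))
    n_junc = n_exons - 1
    internal_lengths = rng.integers(30, 400, size=n_exons - 2)
    intron_lengths = rng.integers(300, 1500, size=n_junc)
    extent = int(internal_lengths.sum() + intron_lengths.sum())
    # pad covers the 500 bp terminal exons so background reads stay clear
    offset = place(chrom, extent, 3_500, pad=700)

    juncs = []
    internal = []
    pos = offset
    for k in range(n_junc):
        jstart = pos
        jend = pos + int(intron_lengths[k])
        juncs.append(SpliceJunction(chrom, jstart, jend, strand))
        pos = jend
        if k < n_junc - 1:
            internal.append((pos, pos + int(internal_lengths[k])))
            pos += int(internal_lengths[k])
    alt = None
    if (
        cfg.novel_alt_isoform_prob > 0
        and rng.random() < cfg.novel_alt_isoform_prob
        and n_junc >= 2
    ):
        # alternative donor for one internal intron: overlaps the main
        # junction, so it forms a second, lower-depth path
        k = int(rng.integers(0, n_junc - 1))
        base = juncs[k]
        shift = int(rng.integers(20, 120))
        if k >= 1:
            shift = min(shift, int(internal_lengths[k - 1]) - 10)
        if shift >= 20 and base.intron_start - shift > offset:
            alt = SpliceJunction(chrom, base.intron_start - shift,
                                 base.intron_end, strand)
    active = tuple(
        c for c in cfg.conditions
        if rng.random() < cfg.novel_active_prob.get(c, 0.0)
    )
    if not active:
        active = (cfg.conditions[0],)
    return PlantedNovelGene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        main_junctions=tuple(juncs),
        alt_junction=alt,
        internal_exons=tuple(internal),
        active_conditions=active,
    )


def _build_truth(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    ann: AnnotationSet,
    gene_classes: dict[str, str],
    novel_genes: list[PlantedNovelGene],
    decoys: list[SpliceJunction],
) -> SyntheticTruth:
    """Per-gene activity patterns and per-isoform target RPKM profiles."""
    pattern_names = [p for p, _ in _LINC_PATTERNS]
    pattern_probs = np.array([w for _, w in _LINC_PATTERNS])
    pattern_probs = pattern_probs / pattern_probs.sum()

    gene_active: dict[str, set[str]] = {}
    gene_mult: dict[str, dict[str, float]] = {}
    for gid in sorted(ann.genes):
        cls = gene_classes[gid]
        if cls in _ALWAYS_ON:
            active = set(cfg.conditions)
        elif cls == "signature":
            active = {"fRPE", "iPS_RPE"} & set(cfg.conditions)
        elif cls == "ips_specific":
            active = {"iPS"} & set(cfg.conditions)
        elif cls.startswith("contam"):
            active = {c for c in cfg.conditions if rng.random() < 0.25}
        else:  # lincRNA
            k = int(rng.choice(len(pattern_names), p=pattern_probs))
            active = set(pattern_names[k]) & set(cfg.conditions)
        gene_active[gid] = active

        eff_sigma = (cfg.lincrna_effect_sigma if cls == "lincRNA"
                     else cfg.rpe_effect_sigma)
        rpe = float(np.exp(rng.normal(0.0, eff_sigma)))
        ips = float(np.exp(rng.normal(
            0.0,
            cfg.ips_effect_sigma if cls != "lincRNA"
            else cfg.lincrna_effect_sigma,
        )))
        mult = {}
        for c in cfg.conditions:
            mult[c] = ips if c == "iPS" else rpe
        gene_mult[gid] = mult

    rows = []
    for iid in sorted(ann.isoforms):
        iso = ann.isoforms[iid]
        cls = gene_classes[iso.gene_id]
        lo, hi = _CLASS_RPKM["lincRNA" if cls == "lincRNA" else cls]
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        row = {
            "isoform_id": iid,
            "gene_id": iso.gene_id,
            "biotype": iso.biotype,
            "gene_class": cls,
            "length_bp": iso.length_bp,
        }
        for c in cfg.conditions:
            on = c in gene_active[iso.gene_id]
            row[f"active_{c}"] = on
            row[f"target_rpkm_{c}"] = base * gene_mult[iso.gene_id][c] if on else 0.0
        rows.append(row)
    table = pd.DataFrame(rows).set_index("isoform_id")

    calls = pd.DataFrame(
        {
            c: table[f"target_rpkm_{c}"] > cfg.expression_threshold
            for c in cfg.conditions
        }
    )

    panels = {
        "signature": sorted(g for g, c in gene_classes.items()
                            if c == "signature"),
        "photoreceptor": sorted(g for g, c in gene_classes.items()
                                if c == "contam_photoreceptor"),
        "choroid": sorted(g for g, c in gene_classes.items()
                          if c == "contam_choroid"),
    }
    return SyntheticTruth(
        isoform_table=table,
        expected_calls=calls,
        gene_classes=gene_classes,
        novel_genes=novel_genes,
        decoy_junctions=decoys,
        panels=panels,
        free_space={},
    )


def _free_space(
    cfg: SimulationConfig, occupied: dict[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    """Intergenic intervals where background reads may land."""
    free: dict[str, list[tuple[int, int]]] = {}
    for chrom, size in sorted(cfg.chrom_sizes.items()):
        blocks = sorted(occupied.get(chrom, []))
        out = []
        pos = 500
        for s, e in blocks:
            if s - pos >= 1_000:
                out.append((pos, s))
            pos = max(pos, e)
        if size - 500 - pos >= 1_000:
            out.append((pos, size - 500))
        free[chrom] = out
    return free


# --------------------------------------------------------------------------
# sample simulation


def make_design(cfg: SimulationConfig) -> ConditionDesign:
    return ConditionDesign(
        {
            f"{cond}_{r}": cond
            for cond in cfg.conditions
            for r in range(1, cfg.n_replicates + 1)
        }
    )


def _novel_exon_bounds(gene: PlantedNovelGene, terminal_reach: int = 450):
    """Usable exon intervals of a planted gene (truth chain + terminal reach)."""
    first = gene.main_junctions[0]
    last = gene.main_junctions[-1]
    bounds = [(first.intron_start - terminal_reach, first.intron_start)]
    bounds.extend(gene.internal_exons)
    bounds.append((last.intron_end, last.intron_end + terminal_reach))
    return bounds


def simulate_samples(
    ann: AnnotationSet,
    truth: SyntheticTruth,
    cfg: SimulationConfig,
) -> tuple[dict[str, ReadTable], dict[str, ObservedJunctionTable], ConditionDesign]:
    """Per-sample read tables and junction tables consistent with the truth.

    Per sample, isoform abundance is the truth target RPKM times a
    log-normal replicate factor; expected counts invert the RPKM formula
    (count = RPKM x length_kb x depth_in_millions) and are realised as
    Poisson draws.  Junction depths are Poisson with mean equal to the
    summed expected count of the isoforms containing the junction.  The
    unique-read total of every emitted table equals ``library_depth``
    exactly, topped up with intergenic background reads; a configurable
    fraction of multi-mapping reads is added on top and excluded from the
    totals by the consumer.
    """
    design = make_design(cfg)
    iso_ids = sorted(ann.isoforms)
    table = truth.isoform_table
    read_tables: dict[str, ReadTable] = {}
    sj_tables: dict[str, ObservedJunctionTable] = {}

    flat_free = [
        (chrom, s, e)
        for chrom in sorted(truth.free_space)
        for (s, e) in truth.free_space[chrom]
    ]
    if not flat_free:
        raise ValidationError("no intergenic space for background reads")
    free_len = np.array([e - s for _, s, e in flat_free], dtype=float)
    free_p = free_len / free_len.sum()

    for si, (sample, cond) in enumerate(design.samples.items()):
        rng = _rng(cfg.seed, 1000 + si)
        rows: list[dict] = []
        sj_lambda: dict[SpliceJunction, float] = {}
        counter = 0

        def draw(lam: float) -> int:
            # zero-noise limit: counts and depths become deterministic, so
            # replicates differ only in read placement
            if cfg.replicate_sigma == 0:
                return int(round(lam))
            return int(rng.poisson(lam))

        def emit(chrom, blocks, strand, unique=1):
            nonlocal counter
            counter += 1
            sizes = ",".join(str(e - s) for s, e in blocks)
            offs = ",".join(str(s - blocks[0][0]) for s, e in blocks)
            rows.append(
                {
                    "chrom": chrom, "start": blocks[0][0],
                    "end": blocks[-1][1], "name": f"r{counter:07d}",
                    "score": 0, "strand": strand,
                    "block_count": len(blocks), "block_sizes": sizes,
                    "block_starts": offs, "unique": unique,
                }
            )

        # ---- annotated transcript reads
        for iid in iso_ids:
            iso = ann.isoforms[iid]
            target = float(table.loc[iid, f"target_rpkm_{cond}"])
            if target <= 0:
                continue
            factor = (
                float(np.exp(rng.normal(0.0, cfg.replicate_sigma)))
                if cfg.replicate_sigma > 0 else 1.0
            )
            c = target * factor * iso.length_bp * cfg.library_depth / 1e9
            juncs = iso.junctions()
            phi = cfg.junction_read_fraction if juncs else 0.0
            n_single = draw(c * (1.0 - phi))
            n_jread = draw(c * phi / 2.0) if juncs else 0

            if n_single:
                lens = np.array([len(e) for e in iso.exons], dtype=float)
                exon_idx = rng.choice(len(lens), size=n_single,
                                      p=lens / lens.sum())
                for k in exon_idx:
                    e = iso.exons[int(k)]
                    span = max(len(e) - cfg.read_length, 0)
                    s = e.start + int(rng.integers(0, span + 1))
                    emit(iso.chrom, [(s, min(s + cfg.read_length, e.end))],
                         iso.strand)
            for _ in range(n_jread):
                j_k = int(rng.integers(0, len(juncs)))
                j = juncs[j_k]
                left_e = iso.exons[j_k]
                right_e = iso.exons[j_k + 1]
                half = cfg.read_length // 2
                b1 = (max(left_e.start, j.intron_start - half),
                      j.intron_start)
                b2 = (j.intron_end,
                      min(right_e.end, j.intron_end + half))
                emit(iso.chrom, [b1, b2], iso.strand)
            for j in juncs:
                sj_lambda[j] = sj_lambda.get(j, 0.0) + (
                    c * cfg.junction_depth_factor
                )

        # ---- planted novel genes
        for gene in truth.novel_genes:
            if cond not in gene.active_conditions:
                continue
            bounds = _novel_exon_bounds(gene)
            all_juncs = list(gene.main_junctions)
            depths_lam = [cfg.novel_junction_depth] * len(all_juncs)
            if gene.alt_junction is not None:
                all_juncs.append(gene.alt_junction)
                depths_lam.append(cfg.novel_junction_depth * 0.4)
            for j, lam in zip(all_juncs, depths_lam):
                sj_lambda[j] = sj_lambda.get(j, 0.0) + lam
                n_jr = draw(lam * 0.3)
                for _ in range(n_jr):
                    b1 = (max(j.intron_start - 50,
                              gene.main_junctions[0].intron_start - 450),
                          j.intron_start)
                    b2 = (j.intron_end, j.intron_end + 50)
                    if b1[0] >= b1[1]:
                        b1 = (j.intron_start - 1, j.intron_start)
                    emit(gene.chrom, [b1, b2], gene.strand)
            n_er = draw(cfg.novel_exon_read_depth)
            if n_er and bounds:
                lens = np.array([e - s for s, e in bounds], dtype=float)
                picks = rng.choice(len(bounds), size=n_er, p=lens / lens.sum())
                for k in picks:
                    s0, e0 = bounds[int(k)]
                    span = max(e0 - s0 - cfg.read_length, 0)
                    s = s0 + int(rng.integers(0, span + 1))
                    emit(gene.chrom, [(s, min(s + cfg.read_length, e0))],
                         gene.strand)

        # ---- decoy junctions: depth 1 in the first discovery sample only
        if sample == f"{cfg.conditions[0]}_1":
            for j in truth.decoy_junctions:
                sj_lambda[j] = sj_lambda.get(j, 0.0)  # ensure key exists

        # ---- finalize SJ depths
        depths: dict[SpliceJunction, int] = {}
        for j in sorted(sj_lambda):
            d = draw(sj_lambda[j]) if sj_lambda[j] > 0 else 0
            if d > 0:
                depths[j] = d
        if sample == f"{cfg.conditions[0]}_1":
            for j in truth.decoy_junctions:
                depths[j] = 1
        sj_tables[sample] = ObservedJunctionTable(sample, depths)

        # ---- multi-mappers and background fill (vectorized)
        n_transcript = counter
        if n_transcript > cfg.library_depth:
            raise ValidationError(
                "library_depth too small for configured expression levels"
            )
        n_bg = cfg.library_depth - n_transcript
        n_mm = int(round(cfg.library_depth * cfg.multimapper_fraction))
        frame_parts = [pd.DataFrame(rows, columns=READ_COLUMNS)] if rows else []
        for n_fill, uniq_flag, tag in ((n_bg, 1, "b"), (n_mm, 0, "m")):
            if n_fill <= 0:
                continue
            pick = rng.choice(len(flat_free), size=n_fill, p=free_p)
            offs = rng.random(n_fill)
            chroms = np.array([flat_free[k][0] for k in pick])
            starts = np.array([flat_free[k][1] for k in pick], dtype=np.int64)
            ends = np.array([flat_free[k][2] for k in pick], dtype=np.int64)
            span = np.maximum(ends - starts - cfg.read_length, 1)
            rstart = starts + (offs * span).astype(np.int64)
            rend = np.minimum(rstart + cfg.read_length, ends)
            sizes = (rend - rstart).astype(np.int64)
            names = np.char.add(tag, np.arange(n_fill).astype(str))
            frame_parts.append(
                pd.DataFrame(
                    {
                        "chrom": chroms, "start": rstart, "end": rend,
                        "name": names, "score": 0, "strand": ".",
                        "block_count": 1,
                        "block_sizes": sizes.astype(str),
                        "block_starts": "0",
                        "unique": uniq_flag,
                    }
                )
            )
        df = pd.concat(frame_parts, ignore_index=True)[READ_COLUMNS]
        read_tables[sample] = ReadTable(df, sample)

    return read_tables, sj_tables, design


# --------------------------------------------------------------------------
# workspace emission


def generate_workspace(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Emit the complete analysis workspace plus ground truth and a ready
    pipeline configuration.  Returns the workspace directory."""
    out = Path(outdir)
    for sub in ("annotation", "reads", "sj", "panels", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    ann, truth = simulate_annotation(cfg)
    read_tables, sj_tables, design = simulate_samples(ann, truth, cfg)

    coding = AnnotationSet()
    lincs = AnnotationSet()
    for iid in sorted(ann.isoforms):
        iso = ann.isoforms[iid]
        if iso.biotype == "lincRNA":
            lincs.add(iso, ("lincrna_catalog",))
        else:
            coding.add(iso, ("gencode_like",))
    # the gencode-like source also carries the lincRNAs, so the two files
    # overlap and the non-redundant merge is exercised end to end
    full = AnnotationSet()
    for iid in sorted(ann.isoforms):
        iso = ann.isoforms[iid]
        full.add(iso, ("gencode_like",))
    write_gtf(full, out / "annotation" / "gencode_like.gtf")
    write_gtf(lincs, out / "annotation" / "lincrna_catalog.gtf")

    design.to_tsv(out / "design.tsv")
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom in sorted(cfg.chrom_sizes):
            fh.write(f"{chrom}\t{cfg.chrom_sizes[chrom]}\n")

    samples_cfg = {}
    for sample in design.samples:
        rpath = out / "reads" / f"{sample}.reads.tsv"
        jpath = out / "sj" / f"{sample}.SJ.out.tab"
        read_tables[sample].to_tsv(rpath)
        write_sj_table(sj_tables[sample], jpath)
        samples_cfg[sample] = {
            "reads": f"reads/{sample}.reads.tsv",
            "sj": f"sj/{sample}.SJ.out.tab",
        }

    for name, genes in truth.panels.items():
        (out / "panels" / f"{name}_genes.txt").write_text(
            "\n".join(genes) + "\n"
        )

    truth.isoform_table.to_csv(out / "truth" / "isoform_table.tsv", sep="\t")
    truth.expected_calls.to_csv(out / "truth" / "expected_calls.tsv", sep="\t")
    novel_json = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "main_junctions": [
                [j.intron_start, j.intron_end] for j in g.main_junctions
            ],
            "alt_junction": (
                [g.alt_junction.intron_start, g.alt_junction.intron_end]
                if g.alt_junction else None
            ),
            "internal_exons": [list(x) for x in g.internal_exons],
            "active_conditions": list(g.active_conditions),
        }
        for g in truth.novel_genes
    ]
    (out / "truth" / "novel_genes.json").write_text(
        json.dumps(novel_json, indent=1, sort_keys=True) + "\n"
    )
    (out / "truth" / "decoys.json").write_text(
        json.dumps(
            [[j.chrom, j.intron_start, j.intron_end, j.strand]
             for j in truth.decoy_junctions],
            sort_keys=True,
        ) + "\n"
    )

    import yaml

    pipeline_cfg = {
        "annotations": [
            {"path": "annotation/gencode_like.gtf", "label": "gencode_like"},
            {"path": "annotation/lincrna_catalog.gtf",
             "label": "lincrna_catalog"},
        ],
        "design": "design.tsv",
        "chrom_sizes": "chrom_sizes.tsv",
        "samples": samples_cfg,
        "panels": {
            name: f"panels/{name}_genes.txt" for name in sorted(truth.panels)
        },
        "parameters": {
            "expression_threshold": cfg.expression_threshold,
            "concordance_transform": "log2",
            "concordance_set_mode": "intersection",
            "unique_junction_scope": "database",
            "zero_rule": "all_unobserved",
            "gap_bp": 2000,
            "terminal_bp": 500,
            "min_exons": 3,
            "min_depth": 1,
            "max_isoforms": 5,
            "discovery_condition": cfg.conditions[0],
        },
        "seed": cfg.seed,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "n_genes": ann.n_genes,
        "n_isoforms": ann.n_isoforms,
        "samples": sorted(design.samples),
    }
    (out / "truth" / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )
    return out
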