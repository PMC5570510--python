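"""End-to-end pipeline: configuration, orchestration and report export.

Stages, in order: merge annotations into the non-redundant database and
derive the unique-junction table; quantify every sample (exon-overlap
counting, zero rule, RPKM); call expression and bin RPKM distributions;
compute replicate and cross-condition concordance at gene and isoform
level, whole-transcriptome and lincRNA-only; produce gene-panel reports;
discover, assemble and quantify novel intergenic genes.  All reports are
TSV; a JSON manifest records the configuration hash so identical configs
give byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    AnnotationSet,
    derive_junctions,
    gene_spans,
    load_gtf,
    merge_nonredundant,
    write_gtf,
)
from .core import ValidationError
from .expression import (
    ConditionDesign,
    bin_rpkm,
    call_expressed,
    inter_concordance,
    intra_concordance,
    load_panel,
    panel_report,
)
from .novel import (
    detection_by_condition,
    discover_novel_genes,
    quantify_novel,
    summarize_novel,
    write_novel_gtf,
)
from .quantify import ReadTable, quantify_samples, read_sj_table

log = logging.getLogger(__name__)

_PARAM_DEFAULTS: dict[str, Any] = {
    "expression_threshold": 1.0,
    "concordance_transform": "log2",
    "concordance_set_mode": "intersection",
    "unique_junction_scope": "database",
    "zero_rule": "all_unobserved",
    "gap_bp": 2000,
    "terminal_bp": 500,
    "min_exons": 3,
    "min_depth": 1,
    "max_isoforms": 5,
    "discovery_condition": None,  # default: first condition in the design
}

_PARAM_RANGES = {
    "expression_threshold": (0.0, float("inf")),
    "gap_bp": (0, 10_000_000),
    "terminal_bp": (1, 100_000),
    "min_exons": (3, 100),
    "min_depth": (0, 10**9),
    "max_isoforms": (1, 1000),
}

_PARAM_CHOICES = {
    "concordance_transform": ("log2", "raw"),
    "concordance_set_mode": ("intersection", "union"),
    "unique_junction_scope": ("database", "gene"),
    "zero_rule": ("all_unobserved", "any_unobserved", "none"),
}

_TOP_KEYS = {
    "annotations", "design", "chrom_sizes", "samples", "panels",
    "parameters", "seed",
}


class ConfigError(ValueError):
    """A pipeline configuration problem, naming the offending key."""


@dataclass
class PipelineConfig:
    """Fully resolved, validated pipeline configuration."""

    annotations: list[tuple[Path, str]]  # (gtf path, source label)
    design: Path
    samples: dict[str, dict[str, Path]]  # sample -> {reads, sj}
    chrom_sizes: Path | None
    panels: dict[str, Path]
    parameters: dict[str, Any]
    seed: int
    base_dir: Path

    def config_hash(self) -> str:
        payload = {
            "annotations": [[str(p), l] for p, l in self.annotations],
            "design": str(self.design),
            "samples": {
                s: {k: str(v) for k, v in d.items()}
                for s, d in self.samples.items()
            },
            "chrom_sizes": str(self.chrom_sizes),
            "panels": {k: str(v) for k, v in self.panels.items()},
            "parameters": self.parameters,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default, range-check and path-check a YAML pipeline config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("annotations", "design", "samples"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key}")

    def resolve(p: str, key: str) -> Path:
        rp = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
        if not rp.exists():
            raise ConfigError(f"{key}: path does not exist: {p}")
        return rp

    annotations = []
    for i, entry in enumerate(raw["annotations"]):
        if isinstance(entry, str):
            entry = {"path": entry, "label": f"src{i}"}
        annotations.append(
            (resolve(entry["path"], "annotations"),
             str(entry.get("label", f"src{i}")))
        )
    if not annotations:
        raise ConfigError("annotations: need at least one GTF")

    design = resolve(raw["design"], "design")
    samples: dict[str, dict[str, Path]] = {}
    for sample, d in raw["samples"].items():
        if "reads" not in d or "sj" not in d:
            raise ConfigError(f"samples.{sample}: needs 'reads' and 'sj'")
        samples[sample] = {
            "reads": resolve(d["reads"], f"samples.{sample}.reads"),
            "sj": resolve(d["sj"], f"samples.{sample}.sj"),
        }
    chrom_sizes = (
        resolve(raw["chrom_sizes"], "chrom_sizes")
        if raw.get("chrom_sizes") else None
    )
    panels = {
        name: resolve(p, f"panels.{name}")
        for name, p in (raw.get("panels") or {}).items()
    }

    params = dict(_PARAM_DEFAULTS)
    for key, val in (raw.get("parameters") or {}).items():
        if key not in _PARAM_DEFAULTS:
            raise ConfigError(f"parameters.{key}: unknown parameter")
        params[key] = val
    for key, (lo, hi) in _PARAM_RANGES.items():
        v = params[key]
        if not (isinstance(v, (int, float)) and lo <= v <= hi):
            raise ConfigError(
                f"parameters.{key}: value {v!r} outside [{lo}, {hi}]"
            )
    for key, choices in _PARAM_CHOICES.items():
        if params[key] not in choices:
            raise ConfigError(
                f"parameters.{key}: {params[key]!r} not one of {choices}"
            )
    for key, default in _PARAM_DEFAULTS.items():
        if params[key] != default:
            log.info("parameter %s overridden: %r (default %r)",
                     key, params[key], default)

    seed = int(raw.get("seed", 0))
    return PipelineConfig(
        annotations=annotations,
        design=design,
        samples=samples,
        chrom_sizes=chrom_sizes,
        panels=panels,
        parameters=params,
        seed=seed,
        base_dir=base,
    )


def _read_chrom_sizes(path: Path | None) -> dict[str, int] | None:
    if path is None:
        return None
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, size = line.split("\t")[:2]
        out[chrom] = int(size)
    return out


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.6g")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.parameters
    produced: dict[str, Path] = {}

    def record(name: str, p: Path) -> Path:
        produced[name] = p
        return p

    stage = "load-annotations"
    try:
        sources = [load_gtf(p, label) for p, label in cfg.annotations]
        ann = merge_nonredundant(sources)
        jidx = derive_junctions(ann, scope=params["unique_junction_scope"])
        spans = gene_spans(ann)
        write_gtf(ann, record("merged_annotation", out / "merged_annotation.gtf"))
        jidx.unique_junction_table(ann).to_csv(
            record("unique_junctions", out / "unique_junctions.tsv"),
            sep="\t", index=False,
        )

        stage = "quantify"
        design = ConditionDesign.from_tsv(cfg.design)
        missing = set(design.samples) - set(cfg.samples)
        if missing:
            raise ConfigError(f"design samples without inputs: {sorted(missing)}")
        read_tables = {
            s: ReadTable.from_tsv(cfg.samples[s]["reads"], s)
            for s in design.samples
        }
        sj_tables = {
            s: read_sj_table(cfg.samples[s]["sj"], s) for s in design.samples
        }
        zero_rule = params["zero_rule"]
        mat = quantify_samples(
            read_tables, sj_tables, ann, jidx,
            None if zero_rule == "none" else zero_rule,
        )
        _write_tsv(mat.raw_counts, record("counts", out / "counts.tsv"),
                   "isoform_id")
        _write_tsv(mat.rpkm, record("rpkm", out / "rpkm.tsv"), "isoform_id")

        stage = "expression-calls"
        call = call_expressed(mat, design, ann,
                              threshold=params["expression_threshold"])
        _write_tsv(call.expressed,
                   record("calls_isoform", out / "expression_calls_isoform.tsv"),
                   "isoform_id")
        _write_tsv(call.gene_expressed,
                   record("calls_gene", out / "expression_calls_gene.tsv"),
                   "gene_id")
        _write_tsv(call.mean_rpkm,
                   record("mean_rpkm", out / "mean_rpkm_condition.tsv"),
                   "isoform_id")

        stage = "bin-distributions"
        linc_isoforms = [
            i for i in mat.isoforms
            if i in ann.isoforms and ann.isoforms[i].biotype == "lincRNA"
        ]
        bin_rows = []
        for cond in design.conditions:
            for scope, idx in (("all", list(call.mean_rpkm.index)),
                               ("lincRNA", linc_isoforms)):
                dist = bin_rpkm(call.mean_rpkm.loc[idx, cond], cond)
                for label, n in dist.counts.items():
                    bin_rows.append(
                        {"condition": cond, "scope": scope,
                         "bin": label, "n_isoforms": n}
                    )
        pd.DataFrame(bin_rows).to_csv(
            record("rpkm_bins", out / "rpkm_bins.tsv"), sep="\t", index=False
        )

        stage = "concordance"
        gene_map = {i: ann.gene_of(i) for i in mat.isoforms
                    if i in ann.isoforms}
        transform = params["concordance_transform"]
        set_mode = params["concordance_set_mode"]
        intra_rows, inter_rows = [], []
        scopes: list[tuple[str, list[str] | None]] = [("all", None)]
        if linc_isoforms:
            scopes.append(("lincRNA", linc_isoforms))
        for scope, idx in scopes:
            sub = mat if idx is None else mat.restrict(idx)
            sub_gene_map = {i: gene_map[i] for i in sub.isoforms
                           if i in gene_map}
            sub_call = call_expressed(sub, design, ann,
                                      threshold=params["expression_threshold"])
            for level in ("gene", "isoform"):
                n_expr = {
                    c: sub_call.n_expressed(c, level)
                    for c in design.conditions
                }
                intra = intra_concordance(
                    sub, design, sub_call, level, sub_gene_map, transform,
                    strict=False,
                )
                for cond in design.conditions:
                    intra_rows.append(
                        {"scope": scope, "level": level, "condition": cond,
                         "n_expressed": n_expr[cond],
                         "concordance": intra[cond]}
                    )
                for pair in itertools.combinations(design.conditions, 2):
                    ic = inter_concordance(
                        sub, sub_call, design, pair, level, sub_gene_map,
                        transform, set_mode,
                    )
                    inter_rows.append(
                        {"scope": scope, "level": level,
                         "condition_a": pair[0], "condition_b": pair[1],
                         "overlap": ic.overlap,
                         "concordance": ic.r if ic.r is not None else float("nan")}
                    )
        pd.DataFrame(intra_rows).to_csv(
            record("concordance_intra", out / "concordance_intra.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )
        pd.DataFrame(inter_rows).to_csv(
            record("concordance_inter", out / "concordance_inter.tsv"),
            sep="\t", index=False, float_format="%.6g",
        )

        stage = "panels"
        for name in sorted(cfg.panels):
            genes = load_panel(cfg.panels[name])
            rep = panel_report(mat, call, design, genes, ann, name, transform)
            rows = []
            for cond in design.conditions:
                rows.append(
                    {"condition": cond,
                     "genes_expressed": rep.genes_expressed[cond],
                     "isoforms_expressed": rep.isoforms_expressed[cond],
                     "intra_gene": rep.intra["gene"][cond],
                     "intra_isoform": rep.intra["isoform"][cond]}
                )
            pd.DataFrame(rows).to_csv(
                record(f"panel_{name}", out / f"panel_{name}_summary.tsv"),
                sep="\t", index=False, float_format="%.6g",
            )
            prows = []
            for level in ("gene", "isoform"):
                for pair, ic in rep.inter[level].items():
                    prows.append(
                        {"level": level, "condition_a": pair[0],
                         "condition_b": pair[1], "overlap": ic.overlap,
                         "concordance": ic.r if ic.r is not None else float("nan")}
                    )
            pd.DataFrame(prows).to_csv(
                record(f"panel_{name}_inter",
                       out / f"panel_{name}_inter.tsv"),
                sep="\t", index=False, float_format="%.6g",
            )
            _write_tsv(rep.heatmap_matrix,
                       record(f"panel_{name}_heatmap",
                              out / f"panel_{name}_mean_rpkm.tsv"),
                       "gene_id")

        stage = "novel-genes"
        discovery_cond = params["discovery_condition"] or design.conditions[0]
        if discovery_cond not in design.replicates:
            raise ConfigError(
                f"discovery_condition {discovery_cond!r} not in design"
            )
        disc_tables = [sj_tables[s] for s in design.replicates[discovery_cond]]
        models, n_two_exon = discover_novel_genes(
            disc_tables, jidx, spans,
            min_depth=params["min_depth"],
            gap_bp=params["gap_bp"],
            terminal_bp=params["terminal_bp"],
            min_exons=params["min_exons"],
            max_isoforms=params["max_isoforms"],
            chrom_sizes=_read_chrom_sizes(cfg.chrom_sizes),
        )
        if models:
            novel_mat, detection = quantify_novel(
                models, read_tables, sj_tables,
                totals=mat.total_unique_reads,
            )
            summary, agg = summarize_novel(models, novel_mat)
            write_novel_gtf(models,
                            record("novel_gtf", out / "novel_genes.gtf"))
            _write_tsv(summary, record("novel_summary",
                                       out / "novel_summary.tsv"), "gene_id")
            _write_tsv(detection_by_condition(detection, design),
                       record("novel_detection",
                              out / "novel_detection.tsv"), "gene_id")
            _write_tsv(novel_mat.rpkm,
                       record("novel_rpkm", out / "novel_rpkm.tsv"),
                       "isoform_id")
        else:
            agg = {}
            (out / "novel_genes.gtf").write_text("")
            record("novel_gtf", out / "novel_genes.gtf")
        agg["n_two_exon_candidates"] = float(n_two_exon)
        (out / "novel_aggregate.json").write_text(
            json.dumps(agg, indent=1, sort_keys=True) + "\n"
        )
        record("novel_aggregate", out / "novel_aggregate.json")

        stage = "manifest"
        manifest = {
            "config_hash": cfg.config_hash(),
            "version": __version__,
            "parameters": params,
            "n_isoforms": ann.n_isoforms,
            "n_genes": ann.n_genes,
            "n_samples": len(design.samples),
            "outputs": sorted(str(p.name) for p in produced.values()),
        }
        (out / "run_manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        record("manifest", out / "run_manifest.json")
    except (ConfigError, ValidationError):
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return produced
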