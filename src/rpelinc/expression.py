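"""Expression calls, RPKM binning, replicate and cross-condition concordance,
and gene-panel reports.

An isoform is called *expressed* in a condition when its mean RPKM across
the condition's replicates is strictly greater than 1 (the conservative
convention for bulk RNA-seq); a gene is expressed when any of its isoforms
is.  RPKM distributions are summarised on the decade ladder
zero, (0,1], (1,10], (10,100], (100,1000], >1000.

Concordance is the Pearson product-moment correlation.  Within a condition
(intra) it is the mean of pairwise replicate correlations; between
conditions (inter) it is the correlation of condition-mean values over the
features expressed in both.  By default correlations are computed on
log2(RPKM + 1): raw RPKM correlations are dominated by a handful of very
high expressers.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .core import ValidationError
from .quantify import ExpressionMatrix

log = logging.getLogger(__name__)

BIN_LABELS = ("zero", "(0,1]", "(1,10]", "(10,100]", "(100,1000]", ">1000")
_BIN_EDGES = (0.0, 1.0, 10.0, 100.0, 1000.0)


class ConcordanceError(ValueError):
    """Pearson correlation is undefined (constant vector or n < 2)."""


@dataclass
class ConditionDesign:
    """Sample -> condition mapping with ordered per-condition replicates."""

    samples: dict[str, str]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("design has no samples")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples.values()))

    @property
    def replicates(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, c in self.samples.items():
            out.setdefault(c, []).append(s)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConditionDesign":
        df = pd.read_csv(str(path), sep="\t", header=None,
                         names=["sample_id", "condition"], dtype=str,
                         comment="#")
        return cls(dict(zip(df["sample_id"], df["condition"])))

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{s}\t{c}" for s, c in self.samples.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ExpressionCall:
    """Boolean expression calls at isoform and gene level per condition."""

    expressed: pd.DataFrame  # isoform x condition, bool
    gene_expressed: pd.DataFrame  # gene x condition, bool
    mean_rpkm: pd.DataFrame  # isoform x condition
    threshold: float = 1.0

    def n_expressed(self, condition: str, level: str = "isoform") -> int:
        table = self.expressed if level == "isoform" else self.gene_expressed
        return int(table[condition].sum())

    def expressed_set(self, condition: str, level: str = "isoform") -> set[str]:
        table = self.expressed if level == "isoform" else self.gene_expressed
        return set(table.index[table[condition]])


def call_expressed(
    mat: ExpressionMatrix,
    design: ConditionDesign,
    ann: AnnotationSet | None = None,
    threshold: float = 1.0,
    gene_map: Mapping[str, str] | None = None,
) -> ExpressionCall:
    """Mean-RPKM expression calls per condition (strict ``mean > threshold``).

    Gene calls are the OR over each gene's isoforms.  Gene membership comes
    from ``ann`` or an explicit ``gene_map`` (isoform -> gene).
    """
    missing = [s for s in design.samples if s not in mat.rpkm.columns]
    if missing:
        raise ValidationError(f"design samples missing from matrix: {missing}")
    for cond, reps in design.replicates.items():
        if not reps:
            raise ValidationError(f"condition {cond} has no samples")

    mean_rpkm = pd.DataFrame(
        {
            cond: mat.rpkm[reps].mean(axis=1)
            for cond, reps in design.replicates.items()
        }
    )
    expressed = mean_rpkm > threshold

    if gene_map is None and ann is not None:
        gene_map = {i: ann.gene_of(i) for i in mat.isoforms if i in ann.isoforms}
    if gene_map:
        genes = pd.Series({i: gene_map[i] for i in expressed.index
                           if i in gene_map})
        gene_expressed = expressed.loc[genes.index].groupby(genes).any()
        gene_expressed.index.name = None
    else:
        gene_expressed = pd.DataFrame(columns=expressed.columns, dtype=bool)
    return ExpressionCall(expressed, gene_expressed, mean_rpkm, threshold)


@dataclass
class BinnedDistribution:
    """RPKM counts on the fixed ladder zero,(0,1],(1,10],(10,100],(100,1000],>1000."""

    condition: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def bin_rpkm(values: Sequence[float] | pd.Series, condition: str = "") -> BinnedDistribution:
    """Assign each value to its decade bin; exact zeros get the zero bin.

    Bins are half-open on the left, ``(lo, hi]``, so 10 falls in (1,10].
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValidationError("negative RPKM value cannot be binned")
    counts = dict.fromkeys(BIN_LABELS, 0)
    counts["zero"] = int((arr == 0).sum())
    nz = arr[arr > 0]
    # np.digitize with right=True puts v == edge into the lower bin;
    # positive values get indices 1..5 against edges (0, 1, 10, 100, 1000)
    idx = np.digitize(nz, _BIN_EDGES, right=True)
    for k, label in enumerate(BIN_LABELS[1:], start=1):
        counts[label] = int((idx == k).sum())
    return BinnedDistribution(condition, counts)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation with explicit degeneracy errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if x.size < 2:
        raise ConcordanceError("correlation needs >=2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConcordanceError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _expression_values(
    mat: ExpressionMatrix,
    level: str,
    gene_map: Mapping[str, str] | None,
) -> pd.DataFrame:
    """Feature x sample RPKM at the requested level.

    Gene-level expression is the sum of the gene's isoform RPKMs.
    """
    if level == "isoform":
        return mat.rpkm
    if level != "gene":
        raise ValidationError(f"unknown level {level!r}")
    if not gene_map:
        raise ValidationError("gene-level analysis requires gene membership")
    genes = pd.Series({i: gene_map[i] for i in mat.rpkm.index if i in gene_map})
    out = mat.rpkm.loc[genes.index].groupby(genes).sum()
    out.index.name = None
    return out


def _transform(values: pd.DataFrame | np.ndarray, transform: str):
    if transform == "log2":
        return np.log2(np.asarray(values, dtype=float) + 1.0)
    if transform == "raw":
        return np.asarray(values, dtype=float)
    raise ValidationError(f"unknown transform {transform!r}")


def intra_concordance(
    mat: ExpressionMatrix,
    design: ConditionDesign,
    call: ExpressionCall | None = None,
    level: str = "isoform",
    gene_map: Mapping[str, str] | None = None,
    transform: str = "log2",
    strict: bool = True,
) -> dict[str, float]:
    """Mean pairwise replicate Pearson correlation per condition.

    Vectors are restricted to features called expressed in the condition
    (when ``call`` is given) and always exclude features with zero RPKM in
    every replicate, which carry no information.  Undefined pairs raise
    :class:`ConcordanceError` naming the pair; with ``strict=False`` an
    undefined condition yields NaN instead.
    """
    values = _expression_values(mat, level, gene_map)
    out: dict[str, float] = {}
    for cond, reps in design.replicates.items():
        if len(reps) < 2:
            raise ValidationError(
                f"condition {cond} needs >=2 replicates for concordance"
            )
        sub = values[reps]
        if call is not None:
            keep = call.expressed_set(cond, level)
            sub = sub.loc[[f for f in sub.index if f in keep]]
        sub = sub.loc[(sub != 0).any(axis=1)]
        rs = []
        undefined = False
        for a, b in itertools.combinations(reps, 2):
            try:
                rs.append(pearson(_transform(sub[a], transform),
                                  _transform(sub[b], transform)))
            except ConcordanceError as exc:
                if strict:
                    raise ConcordanceError(
                        f"{cond}: pair ({a}, {b}): {exc}"
                    ) from exc
                undefined = True
        out[cond] = float("nan") if undefined or not rs else float(np.mean(rs))
    return out


@dataclass
class InterConcordance:
    """Expressed-set overlap and cross-condition correlation for one pair."""

    pair: tuple[str, str]
    overlap: int
    r: float | None  # None when undefined (empty overlap / constant vector)


def inter_concordance(
    mat: ExpressionMatrix,
    call: ExpressionCall,
    design: ConditionDesign,
    pair: tuple[str, str],
    level: str = "isoform",
    gene_map: Mapping[str, str] | None = None,
    transform: str = "log2",
    set_mode: str = "intersection",
) -> InterConcordance:
    """Overlap of expressed sets and Pearson r of condition means.

    ``set_mode="intersection"`` (default) correlates over features
    expressed in both conditions; ``"union"`` over features expressed in
    either.  The reported ``overlap`` is always the intersection size.
    """
    a, b = pair
    for c in pair:
        if c not in design.replicates:
            raise ValidationError(f"condition {c} not in design")
    if set_mode not in ("intersection", "union"):
        raise ValidationError(f"unknown set mode {set_mode!r}")
    set_a = call.expressed_set(a, level)
    set_b = call.expressed_set(b, level)
    overlap = set_a & set_b
    chosen = overlap if set_mode == "intersection" else (set_a | set_b)

    values = _expression_values(mat, level, gene_map)
    means = pd.DataFrame(
        {c: values[design.replicates[c]].mean(axis=1) for c in pair}
    )
    feats = sorted(f for f in chosen if f in means.index)
    if not feats:
        return InterConcordance(pair, len(overlap), None)
    try:
        r = pearson(_transform(means.loc[feats, a], transform),
                    _transform(means.loc[feats, b], transform))
    except ConcordanceError:
        log.warning("undefined inter-condition correlation for %s", pair)
        return InterConcordance(pair, len(overlap), None)
    return InterConcordance(pair, len(overlap), r)


@dataclass
class PanelReport:
    """Restriction of the expression analyses to a curated gene panel."""

    name: str
    resolved_genes: list[str]
    unresolved: list[str]
    isoforms: list[str]
    genes_expressed: dict[str, int]  # condition -> n genes expressed
    isoforms_expressed: dict[str, int]
    intra: dict[str, dict[str, float]]  # level -> condition -> r
    inter: dict[str, dict[tuple[str, str], InterConcordance]]
    bins: dict[str, BinnedDistribution]  # condition -> isoform-level bins
    heatmap_matrix: pd.DataFrame  # gene x condition mean RPKM


def load_panel(path: str | Path) -> list[str]:
    """One gene id per line; an optional second column is ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(line.split("\t")[0])
    return ids


def panel_report(
    mat: ExpressionMatrix,
    call: ExpressionCall,
    design: ConditionDesign,
    panel: Sequence[str],
    ann: AnnotationSet,
    name: str = "panel",
    transform: str = "log2",
) -> PanelReport:
    """All expression analyses restricted to a panel of gene ids.

    Panel ids absent from the annotation are reported as unresolved, not
    fatal; an entirely unresolvable panel is an error.
    """
    resolved = [g for g in panel if g in ann.genes]
    unresolved = [g for g in panel if g not in ann.genes]
    if not resolved:
        raise ValidationError(f"panel {name!r}: no ids resolve in annotation")
    if unresolved:
        log.warning("panel %s: %d unresolved ids", name, len(unresolved))
    isoforms = [i for g in resolved for i in ann.genes[g]
                if i in mat.rpkm.index]
    gene_map = {i: ann.gene_of(i) for i in isoforms}
    sub = mat.restrict(isoforms)
    sub_call = ExpressionCall(
        call.expressed.loc[isoforms],
        call.gene_expressed.loc[[g for g in resolved
                                 if g in call.gene_expressed.index]],
        call.mean_rpkm.loc[isoforms],
        call.threshold,
    )
    conds = design.conditions
    genes_expressed = {c: sub_call.n_expressed(c, "gene") for c in conds}
    isoforms_expressed = {c: sub_call.n_expressed(c, "isoform") for c in conds}
    intra = {
        level: intra_concordance(sub, design, sub_call, level, gene_map,
                                 transform, strict=False)
        for level in ("gene", "isoform")
    }
    inter: dict[str, dict[tuple[str, str], InterConcordance]] = {}
    for level in ("gene", "isoform"):
        inter[level] = {}
        for pair in itertools.combinations(conds, 2):
            inter[level][pair] = inter_concordance(
                sub, sub_call, design, pair, level, gene_map, transform
            )
    bins = {c: bin_rpkm(sub_call.mean_rpkm[c], c) for c in conds}
    heat = pd.DataFrame(
        {
            c: sub.rpkm[design.replicates[c]].mean(axis=1)
            for c in conds
        }
    )
    gene_series = pd.Series(gene_map)
    heat = heat.loc[gene_series.index].groupby(gene_series).sum()
    heat.index.name = None
    return PanelReport(
        name=name,
        resolved_genes=resolved,
        unresolved=unresolved,
        isoforms=isoforms,
        genes_expressed=genes_expressed,
        isoforms_expressed=isoforms_expressed,
        intra=intra,
        inter=inter,
        bins=bins,
        heatmap_matrix=heat,
    )
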