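"""Expression-pattern and methylation analyses of a gene set.

Covers the descriptive side of the pipeline: per-sample gene-set mean
expression compared across groups (tumor/normal, stage, cell-line
differentiation) with a Kruskal–Wallis omnibus test, per-gene monotone
trends against histological grade (Spearman), pairwise gene–gene
correlation within the set, and methylation–expression correlation per
gene stratified into normal and tumor samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ExpressionMatrix,
    GeneSet,
    GRADE_CODES,
    MethylationMatrix,
    ScaleError,
)


@dataclass
class GroupComparison:
    per_sample_mean: pd.Series      # gene-set mean per sample
    groups: pd.Series               # aligned group labels
    h_statistic: float              # Kruskal–Wallis H (tie-corrected)
    p: float
    group_medians: dict[str, float]


def _kruskal(samples_by_group: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(samples_by_group)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples_by_group)
    return float(h), float(p)


def _group_compare(per_sample: pd.Series, groups: pd.Series) -> GroupComparison:
    groups = groups.loc[per_sample.index]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index[0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    arrays = [per_sample[groups == g].to_numpy(dtype=float) for g in sizes.index]
    h, p = _kruskal(arrays)
    medians = {g: float(per_sample[groups == g].median()) for g in sizes.index}
    return GroupComparison(per_sample_mean=per_sample, groups=groups,
                           h_statistic=h, p=p, group_medians=medians)


def _present_genes(gene_ids: Sequence[str], gs: GeneSet, what: str) -> list[str]:
    present = [g for g in gs.genes if g in set(gene_ids)]
    missing = gs.n - len(present)
    if not present:
        raise ValueError(f"no gene of set {gs.name!r} present in the {what}")
    if missing:
        warnings.warn(f"{missing} gene(s) of set {gs.name!r} absent from the "
                      f"{what}; dropped", stacklevel=3)
    return present


def geneset_mean_by_group(
    m: ExpressionMatrix, gs: GeneSet, groups: pd.Series
) -> GroupComparison:
    """Per-sample mean log2 expression of the set, compared across groups.

    The matrix must be log2-transformed; every group needs >= 2 samples.
    """
    if m.scale != "log2":
        raise ScaleError("geneset_mean_by_group expects a log2-scale matrix")
    present = _present_genes(m.gene_ids, gs, "expression matrix")
    per_sample = m.values.loc[present].mean(axis=0)
    return _group_compare(per_sample, groups)


@dataclass
class TrendRecord:
    gene_id: str
    spearman_rho: float
    p: float
    decreasing: bool


@dataclass
class GradeTrendResult:
    records: list[TrendRecord]
    fraction_decreasing: float      # rho < 0 and p < alpha, over valid genes
    fraction_negative_rho: float    # sign-only variant: rho < 0
    n_excluded_constant: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("gene_id")


def grade_trend(
    m: ExpressionMatrix, grades: pd.Series, alpha: float = 0.05
) -> GradeTrendResult:
    """Per-gene Spearman trend of expression against ordinal grade.

    Grades are coded G1=1, G2=2, G3/4=3; a gene is "decreasing" when
    rho < 0 with p < alpha.  Because Spearman is rank-based the matrix
    scale (linear or log2) is immaterial.  Constant genes have no
    defined correlation and are excluded from both fractions.
    """
    coded = grades.map(lambda g: GRADE_CODES.get(g, np.nan)).dropna()
    if coded.nunique() < 3:
        raise ValueError("need at least 3 distinct grade levels")
    common = [s for s in m.sample_ids if s in coded.index]
    coded = coded.loc[common].astype(float)
    records: list[TrendRecord] = []
    n_constant = 0
    for g in m.gene_ids:
        vals = m.values.loc[g, common].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            n_constant += 1
            continue
        rho, p = stats.spearmanr(vals, coded.to_numpy())
        records.append(TrendRecord(g, float(rho), float(p),
                                   bool(rho < 0 and p < alpha)))
    if n_constant:
        warnings.warn(f"{n_constant} constant gene(s) excluded from grade trend")
    n_valid = len(records)
    if n_valid == 0:
        raise ValueError("no gene with a defined grade trend")
    frac_dec = sum(r.decreasing for r in records) / n_valid
    frac_neg = sum(r.spearman_rho < 0 for r in records) / n_valid
    return GradeTrendResult(records=records, fraction_decreasing=frac_dec,
                            fraction_negative_rho=frac_neg,
                            n_excluded_constant=n_constant)


@dataclass
class GeneCorrelationResult:
    matrix: pd.DataFrame            # symmetric Spearman rho, unit diagonal
    fraction_positive: float        # positive share of valid off-diagonal pairs


def pairwise_gene_correlation(m: ExpressionMatrix, gs: GeneSet) -> GeneCorrelationResult:
    """Spearman correlation between all gene pairs of the set."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    present = _present_genes(m.gene_ids, gs, "expression matrix")
    sub = m.values.loc[present]
    constant = sub.std(axis=1) == 0
    corr = sub.T.corr(method="spearman")
    for g in sub.index[constant]:
        corr.loc[g, :] = np.nan
        corr.loc[:, g] = np.nan
    iu = np.triu_indices(len(present), k=1)
    off = corr.to_numpy()[iu]
    valid = off[~np.isnan(off)]
    frac_pos = float((valid > 0).mean()) if len(valid) else np.nan
    return GeneCorrelationResult(matrix=corr, fraction_positive=frac_pos)


@dataclass
class MethylCorrRecord:
    gene_id: str
    rn: float
    pn: float
    rt: float
    pt: float


def methylation_expression_correlation(
    meth: MethylationMatrix, expr: ExpressionMatrix, gs: GeneSet
) -> list[MethylCorrRecord]:
    """Spearman rho/p of beta vs expression, per gene, per stratum.

    Samples are intersected by id and split into normal (rn/pn) and
    tumor (rt/pt) strata using the methylation metadata.  Genes absent
    from either matrix are skipped with a warning.  Spearman is
    rank-based, so the expression scale does not matter.
    """
    common = [s for s in meth.sample_ids if s in set(expr.sample_ids)]
    if not common:
        raise ValueError("no samples shared between methylation and expression")
    is_tumor = meth.sample_meta.loc[common, "is_tumor"]
    normal_ids = list(is_tumor.index[~is_tumor])
    tumor_ids = list(is_tumor.index[is_tumor])
    if len(normal_ids) < 3 or len(tumor_ids) < 3:
        raise ValueError("each stratum needs at least 3 shared samples")
    shared_genes = set(meth.gene_ids) & set(expr.gene_ids)
    records: list[MethylCorrRecord] = []
    skipped = 0
    for g in gs.genes:
        if g not in shared_genes:
            skipped += 1
            continue
        out = {}
        for key, ids in (("n", normal_ids), ("t", tumor_ids)):
            b = meth.beta.loc[g, ids].to_numpy(dtype=float)
            e = expr.values.loc[g, ids].to_numpy(dtype=float)
            keep = ~(np.isnan(b) | np.isnan(e))
            if keep.sum() < 3 or np.all(b[keep] == b[keep][0]) \
                    or np.all(e[keep] == e[keep][0]):
                out[key] = (np.nan, np.nan)
                continue
            rho, p = stats.spearmanr(b[keep], e[keep])
            out[key] = (float(rho), float(p))
        records.append(MethylCorrRecord(g, out["n"][0], out["n"][1],
                                        out["t"][0], out["t"][1]))
    if skipped:
        warnings.warn(f"{skipped} gene(s) of set {gs.name!r} not covered by "
                      "both matrices; skipped")
    return records


def methylation_by_group(
    meth: MethylationMatrix, gs: GeneSet, groups: pd.Series
) -> GroupComparison:
    """Per-sample mean beta of the set, compared across groups."""
    present = _present_genes(meth.gene_ids, gs, "methylation matrix")
    per_sample = meth.beta.loc[present].mean(axis=0)
    return _group_compare(per_sample, groups)
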