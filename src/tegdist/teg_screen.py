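"""Tissue-enriched gene (TEG) screening.

A gene is called enriched in a tissue when, over non-tumor samples,

1. its mean linear-scale expression ranks first in that tissue and is
   significantly different from the runner-up tissue (two-sided
   Mann–Whitney U on per-sample values), and
2. the top tissue's mean is at least ``fold_threshold`` (default 100)
   times the largest mean among all remaining tissues.

Both criteria operate on linear-scale means; because the significance
test is rank-based, the whole screen is invariant to global positive
rescaling of the matrix.  A tie for first place is treated as
no enrichment.  When the two tissues' sample sizes are so small that
the minimal attainable two-sided exact p-value is >= alpha, the record
carries a warning and cannot pass.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneSet, ScaleError

FOLD_EPS = 1e-9  # denominator floor for an all-zero background


@dataclass
class TEGRecord:
    gene_id: str
    top_tissue: str
    top_mean: float
    runner_up_tissue: str
    runner_up_mean: float
    fold_ratio: float
    p_second: float
    passes: bool
    warning: Optional[str] = None


@dataclass
class TEGScreenResult:
    records: list[TEGRecord]
    gene_sets: dict[str, GeneSet]     # per-tissue enriched sets (non-empty only)
    counts: dict[str, int]            # per-tissue enriched gene counts (all tissues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("gene_id")


def _nontumor(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.scale != "linear":
        raise ScaleError("TEG screening operates on linear-scale values")
    return m.normal_subset()


def tissue_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene, per-tissue arithmetic mean over non-tumor samples."""
    nm = _nontumor(m)
    tissue = nm.sample_meta["tissue_type"]
    sizes = tissue.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"tissue {small.index[0]!r} has fewer than 2 samples; "
            "significance testing impossible"
        )
    if len(sizes) < 2:
        raise ValueError("need at least 2 tissues")
    return nm.values.T.groupby(tissue).mean().T


def screen_tegs(
    m: ExpressionMatrix, fold_threshold: float = 100.0, alpha: float = 0.05
) -> TEGScreenResult:
    """Screen every gene for tissue enrichment (see module docstring)."""
    nm = _nontumor(m)
    means = tissue_means(m)
    tissue = nm.sample_meta["tissue_type"]
    cols_by_tissue = {t: nm.values.columns[tissue == t] for t in means.columns}

    records: list[TEGRecord] = []
    for gene in means.index:
        row = means.loc[gene]
        order = row.sort_values(ascending=False, kind="mergesort")
        top_t, top_mean = order.index[0], float(order.iloc[0])
        run_t, run_mean = order.index[1], float(order.iloc[1])
        fold = top_mean / max(run_mean, FOLD_EPS)
        warning = None
        if top_mean == run_mean:
            # a tie for first place contradicts criterion 1
            records.append(TEGRecord(gene, top_t, top_mean, run_t, run_mean,
                                     fold, 1.0, False, "tie for first place"))
            continue
        x = nm.values.loc[gene, cols_by_tissue[top_t]].to_numpy(dtype=float)
        y = nm.values.loc[gene, cols_by_tissue[run_t]].to_numpy(dtype=float)
        min_p = 2.0 / comb(len(x) + len(y), len(x))
        if min_p >= alpha:
            warning = (
                f"sample sizes ({len(x)}, {len(y)}) too small: minimal "
                f"attainable two-sided p {min_p:.3g} >= alpha"
            )
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            records.append(TEGRecord(gene, top_t, top_mean, run_t, run_mean,
                                     fold, p, False, warning))
            continue
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        passes = bool(fold >= fold_threshold and p < alpha)
        records.append(TEGRecord(gene, top_t, top_mean, run_t, run_mean,
                                 fold, p, passes, warning))

    counts = {t: 0 for t in means.columns}
    per_tissue: dict[str, list[str]] = {t: [] for t in means.columns}
    for r in records:
        if r.passes:
            counts[r.top_tissue] += 1
            per_tissue[r.top_tissue].append(r.gene_id)
    gene_sets = {
        t: GeneSet(name=f"{t}_enriched", genes=tuple(g))
        for t, g in per_tissue.items() if g
    }
    return TEGScreenResult(records=records, gene_sets=gene_sets, counts=counts)


@dataclass
class GeneSetOverlap:
    set_names: list[str]
    regions: dict[frozenset, int]      # exact Venn region -> count
    in_at_least: dict[int, int]        # k -> number of genes in >= k sets
    union_size: int
    intersection_size: int


def compare_gene_sets(sets: Sequence[GeneSet]) -> GeneSetOverlap:
    """Exact Venn-region counts for any number of gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets to compare")
    names = [s.name for s in sets]
    members = {s.name: set(s.genes) for s in sets}
    universe = set().union(*members.values())
    regions: dict[frozenset, int] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(names, r):
            regions[frozenset(combo)] = 0
    in_at_least = {k: 0 for k in range(1, len(sets) + 1)}
    for g in universe:
        holders = frozenset(n for n in names if g in members[n])
        regions[holders] += 1
        for k in range(1, len(holders) + 1):
            in_at_least[k] += 1
    return GeneSetOverlap(
        set_names=names,
        regions=regions,
        in_at_least=in_at_least,
        union_size=len(universe),
        intersection_size=regions[frozenset(names)],
    )
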