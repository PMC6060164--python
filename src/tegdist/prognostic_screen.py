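"""Genome-wide per-gene prognostic screening by median split.

Each gene is dichotomized at its median expression over the screened
tumor samples (median-valued samples go to the low group), the two
groups are compared by the log-rank test, and genes with p < alpha are
called prognostic.  No multiplicity correction is applied.  Direction
is determined by comparing restricted mean survival between the two
groups, avoiding any model fit inside the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix, GeneSet
from .survival_stats import KMCurve, SurvivalData, km_estimate, logrank_test

HIGH_PROTECTIVE = "high_expression_protective"
HIGH_ADVERSE = "high_expression_adverse"


@dataclass
class PrognosticRecord:
    gene_id: str
    cutoff: float
    p_logrank: float
    direction: Optional[str]
    is_prognostic: bool
    unsplittable: bool = False


def _rmst(curve: KMCurve, tau: float) -> float:
    """Restricted mean survival time: area under the KM step curve to tau."""
    t_prev, s_prev, area = 0.0, 1.0, 0.0
    for t, s in zip(curve.event_times, curve.survival_probs):
        if t >= tau:
            break
        area += s_prev * (t - t_prev)
        t_prev, s_prev = t, s
    area += s_prev * (tau - t_prev)
    return area


def median_split_logrank(
    gene_values: pd.Series, clin: ClinicalTable, alpha: float = 0.05,
    gene_id: str = "",
) -> PrognosticRecord:
    """Median-split log-rank screen for one gene."""
    common = [s for s in gene_values.index if s in clin.data.index]
    if not common:
        raise ValueError("no samples shared between gene values and clinical table")
    vals = gene_values.loc[common].astype(float)
    cutoff = float(vals.median())
    low_mask = vals <= cutoff
    gene_id = gene_id or str(gene_values.name or "")
    if low_mask.sum() < 2 or (~low_mask).sum() < 2:
        return PrognosticRecord(gene_id, cutoff, np.nan, None, False,
                                unsplittable=True)
    clin_sub = clin.data.loc[common]
    groups = []
    for mask in (low_mask, ~low_mask):
        ids = list(vals.index[mask])
        sub = clin_sub.loc[ids]
        groups.append(SurvivalData(sub["os_time_days"].to_numpy(),
                                   sub["os_event"].to_numpy(), ids))
    res = logrank_test(groups)
    tau = min(g.times.max() for g in groups)
    rm_low = _rmst(km_estimate(groups[0]), tau)
    rm_high = _rmst(km_estimate(groups[1]), tau)
    direction = HIGH_PROTECTIVE if rm_high >= rm_low else HIGH_ADVERSE
    return PrognosticRecord(gene_id, cutoff, res.p, direction,
                            bool(res.p < alpha), unsplittable=False)


@dataclass
class PrognosticScreenResult:
    records: list[PrognosticRecord]
    n_prognostic: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records]).set_index("gene_id")

    @property
    def prognostic_gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records if r.is_prognostic]


def screen_prognostic(
    m: ExpressionMatrix, clin: ClinicalTable, alpha: float = 0.05
) -> PrognosticScreenResult:
    """Median-split log-rank screen over every gene of a tumor matrix."""
    tumors = m.tumor_subset() if (~m.sample_meta["is_tumor"]).any() else m
    unmatched = [s for s in tumors.sample_ids if s not in clin.data.index]
    if unmatched:
        raise ValueError(
            "tumor samples missing from clinical table: "
            + ", ".join(unmatched[:5])
        )
    if tumors.n_samples == 0:
        raise ValueError("no tumor samples shared with the clinical table")
    records = [
        median_split_logrank(tumors.values.loc[g], clin, alpha=alpha, gene_id=g)
        for g in tumors.gene_ids
    ]
    return PrognosticScreenResult(
        records=records, n_prognostic=sum(r.is_prognostic for r in records)
    )


@dataclass
class OverlapResult:
    n_teg: int
    n_prog: int
    n_overlap: int
    pct_of_tegs: float


def overlap_prognostic_tegs(tegs: GeneSet, prognostic: Sequence[str]) -> OverlapResult:
    """Overlap of a tissue-enriched set with a prognostic gene list."""
    prog = set(prognostic)
    overlap = [g for g in tegs.genes if g in prog]
    return OverlapResult(
        n_teg=tegs.n,
        n_prog=len(prog),
        n_overlap=len(overlap),
        pct_of_tegs=100.0 * len(overlap) / tegs.n,
    )
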