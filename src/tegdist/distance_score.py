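"""Mean expression distance: a tumor-vs-normal dissimilarity risk score.

For a gene set of n genes, p normal samples x_ik and tumor sample j
with expression y_ij, the mean expression distance is

    med_j = (1/n) * sum_i sqrt( (1/p) * sum_k (log2 y_ij - log2 x_ik)^2 )

i.e. per gene the root-mean-square log2 difference between the tumor
and *every* normal sample, averaged over the gene set.  Patients sorted
by increasing med are split into equal tertiles (small / middle / large
distance); med itself serves as a risk score (higher = higher risk) and
is evaluated with the concordance index, IPCW Brier score,
time-dependent ROC and group-wise Kaplan–Meier / log-rank comparisons.
A Table-2-style association of the distance groups with clinical
covariates is also provided.

With a pseudocount of 0 the score is invariant under global positive
rescaling of the expression values (only log-ratios enter), and with a
single normal sample it reduces to the mean absolute log2 difference
over the gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ClinicalTable, ExpressionMatrix, GeneSet
from .survival_stats import (
    BrierResult,
    ConcordanceResult,
    KMCurve,
    LogrankResult,
    SurvivalData,
    brier_score,
    concordance_index,
    km_estimate,
    logrank_test,
    time_dependent_roc,
)

GROUP_LABELS = {2: ("small", "large"), 3: ("small", "middle", "large")}


@dataclass
class DistanceScores:
    med: pd.Series                   # per-tumor med_j, tumor sample order
    gene_set_name: str
    n_genes: int
    p_normals: int
    q_tumors: int
    pseudocount: float


def _log2_values(m: ExpressionMatrix, genes: list[str], pc: float) -> np.ndarray:
    if m.scale == "log2":
        return m.values.loc[genes].to_numpy(dtype=float)
    arr = m.values.loc[genes].to_numpy(dtype=float)
    if pc == 0 and arr.min() <= 0:
        raise ValueError("zero expression with pseudocount 0: log2 undefined")
    return np.log2(arr + pc)


def mean_expression_distance(
    tumors: ExpressionMatrix,
    normals: ExpressionMatrix,
    gs: GeneSet,
    pseudocount: float = 1.0,
) -> DistanceScores:
    """Compute med_j for every tumor sample (see module docstring).

    Both matrices are expected on the linear scale; a matrix already
    flagged log2 is used as-is (its pseudocount step is skipped), which
    covers microarray inputs distributed in log space.  Set genes
    missing from either matrix are dropped with a warning.
    """
    if normals.n_samples < 1 or tumors.n_samples < 1:
        raise ValueError("need at least one normal and one tumor sample")
    avail = set(tumors.gene_ids) & set(normals.gene_ids)
    genes = [g for g in gs.genes if g in avail]
    if not genes:
        raise ValueError(f"no gene of set {gs.name!r} present in both matrices")
    if len(genes) < gs.n:
        warnings.warn(f"{gs.n - len(genes)} gene(s) of set {gs.name!r} missing "
                      "from the matrices; n adjusted", stacklevel=2)
    ly = _log2_values(tumors, genes, pseudocount)   # n × q
    lx = _log2_values(normals, genes, pseudocount)  # n × p
    mean_x = lx.mean(axis=1, keepdims=True)
    msq_x = (lx**2).mean(axis=1, keepdims=True)
    per_gene = np.sqrt(np.maximum(ly**2 - 2.0 * ly * mean_x + msq_x, 0.0))
    med = pd.Series(per_gene.mean(axis=0), index=tumors.sample_ids, name="med")
    return DistanceScores(
        med=med, gene_set_name=gs.name, n_genes=len(genes),
        p_normals=normals.n_samples, q_tumors=tumors.n_samples,
        pseudocount=pseudocount,
    )


@dataclass
class DistanceGroups:
    labels: pd.Series                # per-sample group label
    cut_points: list[float]          # boundary med values (first of each block)
    tie_flag: bool = False


def assign_groups(scores: DistanceScores, n_groups: int = 3) -> DistanceGroups:
    """Split patients into equal contiguous groups by increasing med.

    Ties are broken by sample id; block sizes differ by at most one,
    with the remainder going to the earliest (smallest-distance) groups.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    q = len(scores.med)
    if q < n_groups:
        raise ValueError("fewer samples than groups")
    order = scores.med.reset_index()
    order.columns = ["sample_id", "med"]
    order = order.sort_values(["med", "sample_id"], kind="mergesort")
    base, rem = divmod(q, n_groups)
    sizes = [base + 1 if i < rem else base for i in range(n_groups)]
    names = GROUP_LABELS.get(n_groups,
                             tuple(f"group{i+1}" for i in range(n_groups)))
    labels = np.repeat(list(names), sizes)
    lab = pd.Series(labels, index=order["sample_id"].to_numpy(), name="distance_group")
    cuts, tie = [], False
    start = 0
    for i, size in enumerate(sizes):
        if i > 0:
            boundary = float(order["med"].iloc[start])
            cuts.append(boundary)
            if order["med"].iloc[start - 1] == boundary:
                tie = True
        start += size
    return DistanceGroups(labels=lab.loc[scores.med.index], cut_points=cuts,
                          tie_flag=tie)


@dataclass
class EvalMetrics:
    concordance: ConcordanceResult
    brier: BrierResult
    auc_at: dict[float, float]
    km_by_group: dict[str, KMCurve]
    logrank: LogrankResult


def _survival_from_clinical(clin: ClinicalTable, ids: list[str]) -> SurvivalData:
    missing = [s for s in ids if s not in clin.data.index]
    if missing:
        raise ValueError("samples missing from clinical table: "
                         + ", ".join(missing[:5]))
    sub = clin.data.loc[ids]
    return SurvivalData(np.maximum(sub["os_time_days"].to_numpy(dtype=float), 1e-9),
                        sub["os_event"].to_numpy(), ids)


def evaluate_distance_prognosis(
    scores: DistanceScores,
    groups: DistanceGroups,
    clin: ClinicalTable,
    eval_times: Sequence[float],
) -> EvalMetrics:
    """Full survival evaluation of med as a risk score."""
    ids = list(scores.med.index)
    d = _survival_from_clinical(clin, ids)
    med = scores.med.to_numpy(dtype=float)
    conc = concordance_index(med, d)
    brier = brier_score(med, d, eval_times)
    aucs = {float(t): time_dependent_roc(med, d, t)[0] for t in eval_times}
    km_by_group, group_data = {}, []
    for g in groups.labels.loc[ids].unique():
        g_ids = [s for s in ids if groups.labels[s] == g]
        sd = _survival_from_clinical(clin, g_ids)
        km_by_group[g] = km_estimate(sd)
        group_data.append(sd)
    lr = logrank_test(group_data)
    return EvalMetrics(concordance=conc, brier=brier, auc_at=aucs,
                       km_by_group=km_by_group, logrank=lr)


# ---------------------------------------------------------------------------
# clinical association (Table-2 style)
# ---------------------------------------------------------------------------

CATEGORICAL_VARS = ["gender", "afp_high", "child_pugh", "inflammation",
                    "vascular_invasion", "grade", "stage", "vital_status"]
CONTINUOUS_VARS = ["age", "patient_weight", "tumor_weight"]


def row_percentages(counts: Sequence[float]) -> list[float]:
    """Percentages of counts across distance groups, rounded to 1 decimal
    (the denominator is the row total across groups)."""
    total = float(np.sum(counts))
    if total == 0:
        return [float("nan")] * len(counts)
    return [round(100.0 * c / total, 1) for c in counts]


@dataclass
class AssociationRow:
    variable: str
    level: Optional[str]             # None for continuous summary rows
    counts: Optional[list[int]]      # per group, categorical only
    percentages: Optional[list[float]]
    means: Optional[list[float]]     # per group, continuous only
    sds: Optional[list[float]]
    p_value: float
    test: str
    n_missing: int
    low_expected_flag: bool = False


def clinical_association(
    groups: DistanceGroups, clin: ClinicalTable
) -> list[AssociationRow]:
    """Association of distance groups with clinical characteristics.

    Categorical variables get contingency counts with row percentages
    and a chi-square test (Fisher exact for 2×2 tables with any
    expected cell < 5; larger sparse tables keep chi-square but are
    flagged).  Continuous variables get per-group mean/SD with a
    Kruskal–Wallis p.  Missing values are excluded per variable.
    """
    ids = [s for s in groups.labels.index if s in clin.data.index]
    if not ids:
        raise ValueError("no samples shared between groups and clinical table")
    lab = groups.labels.loc[ids]
    present = list(pd.unique(lab))
    preferred = ["small", "middle", "large"]
    group_names = [g for g in preferred if g in present] + \
        [g for g in present if g not in preferred]
    if len(group_names) < 2:
        raise ValueError("need at least 2 non-empty groups")
    data = clin.data.loc[ids].copy()
    data["vital_status"] = np.where(data["os_event"], "dead", "alive")

    rows: list[AssociationRow] = []
    for var in CATEGORICAL_VARS:
        if var not in data.columns or data[var].dropna().empty:
            warnings.warn(f"variable {var!r} absent or empty; skipped")
            continue
        col = data[var]
        if col.dtype == bool or set(col.dropna().unique()) <= {True, False}:
            col = col.map(lambda v: np.nan if pd.isna(v) else ("yes" if v else "no"))
        keep = col.notna()
        table = pd.crosstab(col[keep], lab[keep]).reindex(columns=group_names,
                                                          fill_value=0)
        counts = table.to_numpy()
        low_expected = False
        if counts.shape[0] < 2 or (counts.sum(axis=1) == 0).any():
            p, test = np.nan, "none"
        else:
            chi2, p, _, expected = stats.chi2_contingency(counts, correction=False)
            test = "chi2"
            if (expected < 5).any():
                if counts.shape == (2, 2):
                    _, p = stats.fisher_exact(counts)
                    test = "fisher"
                else:
                    low_expected = True
        for level in table.index:
            c = table.loc[level].tolist()
            rows.append(AssociationRow(
                variable=var, level=str(level), counts=[int(v) for v in c],
                percentages=row_percentages(c), means=None, sds=None,
                p_value=float(p), test=test, n_missing=int((~keep).sum()),
                low_expected_flag=low_expected,
            ))
    for var in CONTINUOUS_VARS:
        if var not in data.columns or data[var].dropna().empty:
            warnings.warn(f"variable {var!r} absent or empty; skipped")
            continue
        col = data[var].astype(float)
        keep = col.notna()
        by_group = [col[keep & (lab == g)].to_numpy() for g in group_names]
        if any(len(v) == 0 for v in by_group):
            p = np.nan
        else:
            pooled = np.concatenate(by_group)
            if np.all(pooled == pooled[0]):
                p = 1.0
            else:
                _, p = stats.kruskal(*by_group)
        rows.append(AssociationRow(
            variable=var, level=None, counts=None, percentages=None,
            means=[float(np.mean(v)) if len(v) else np.nan for v in by_group],
            sds=[float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
                 for v in by_group],
            p_value=float(p), test="kruskal", n_missing=int((~keep).sum()),
        ))
    return rows


def association_frame(rows: list[AssociationRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
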