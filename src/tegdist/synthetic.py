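"""Fully in-silico cohorts with known ground truth.

The generator emulates the data structure of a pan-tissue expression
compendium plus a matched tumor cohort:

* a multi-tissue non-tumor expression matrix with a set of planted
  tissue-enriched genes (all enriched in a designated "liver" tissue,
  at a configurable fold over the background),
* a tumor cohort in which the planted genes are progressively
  downregulated with pathological stage,
* methylation beta values anti-correlated with expression for a
  configurable fraction of the planted genes,
* right-censored overall survival whose log-hazard increases with the
  (standardized) true expression-distance of each tumor from normal.

Expression is log-normal: log2 values are Gaussian around per-gene
means, so fold-change planting is exact in expectation and the noise
level has a single interpretable unit (log2 standard deviations).

Randomness is split into named substreams (expression / methylation /
survival / clinical) derived from one master seed, so regenerating one
component never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import ClinicalTable, ExpressionMatrix, MethylationMatrix

STAGE_LABELS = ("I", "II", "III/IV")
GRADE_LABELS = ("G1", "G2", "G3/4")

_STREAMS = {"expression": 0, "tumor": 1, "methylation": 2, "survival": 3,
            "clinical": 4, "subtypes": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror a 12-tissue compendium with a liver-enriched gene
    set: 1000 genes of which 50 are planted 1000-fold enriched in the
    liver, 300 tumors with one log2 unit of per-stage downregulation,
    80% of planted genes methylation-coupled, a log-hazard slope of 2
    per standard deviation of true distance, 30% uniform censoring and
    0.5 log2 units of measurement noise.
    """

    n_tissues: int = 12
    samples_per_tissue: int = 10
    n_genes: int = 1000
    n_planted_tegs: int = 50
    planted_fold: float = 1000.0
    n_tumors: int = 300
    stage_effect: float = 1.0
    methyl_coupling: float = 0.8
    hazard_coef: float = 2.0
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0
    stage_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)

    def __post_init__(self) -> None:
        if self.n_planted_tegs > self.n_genes:
            raise ValueError("n_planted_tegs cannot exceed n_genes")
        if self.samples_per_tissue < 2:
            raise ValueError("need at least 2 samples per tissue")
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        if not (0.0 <= self.methyl_coupling <= 1.0):
            raise ValueError("methyl_coupling must lie in [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    planted_teg_ids: list[str]
    enriched_tissue: dict[str, str]
    gene_log2_mean: pd.Series  # background log2 mean per gene
    tumor_stage: Optional[pd.Series] = None   # per tumor sample
    tumor_grade: Optional[pd.Series] = None
    true_downregulation: Optional[pd.Series] = None  # log2 units, per tumor
    true_linear_predictor: Optional[pd.Series] = None  # log-hazard scale
    methyl_coupled_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        unknown = set(self.planted_teg_ids) - set(self.gene_log2_mean.index)
        if unknown:
            raise ValueError(f"planted ids not among simulated genes: {sorted(unknown)[:5]}")


def simulate_multitissue(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a multi-tissue non-tumor compendium with planted TEGs.

    Background genes share one log2 mean across tissues; each planted
    gene's mean in its enriched tissue (the first tissue, ``liver``) is
    ``planted_fold`` times the background mean.  Values are
    ``2**(mean + N(0, noise_sd))``, hence strictly positive.
    """
    rng = _rng(config.seed, "expression")
    tissues = ["liver"] + [f"tissue{i:02d}" for i in range(2, config.n_tissues + 1)]
    genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    planted = list(rng.choice(genes, size=config.n_planted_tegs, replace=False))
    planted_mask = pd.Index(genes).isin(planted)

    mu = pd.Series(rng.normal(3.0, 1.5, size=config.n_genes), index=genes)
    sample_ids, tissue_of = [], []
    for t in tissues:
        for j in range(1, config.samples_per_tissue + 1):
            sample_ids.append(f"{t}_N{j:03d}")
            tissue_of.append(t)

    log2fold = np.log2(config.planted_fold)
    means = np.tile(mu.to_numpy()[:, None], (1, len(sample_ids)))
    liver_cols = np.array([t == "liver" for t in tissue_of])
    means[np.ix_(planted_mask, liver_cols)] += log2fold
    log2vals = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    values = pd.DataFrame(np.exp2(log2vals), index=genes, columns=sample_ids)

    meta = pd.DataFrame(
        {"tissue_type": tissue_of, "is_tumor": False, "cohort": "sim_normal"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimTruth(
        planted_teg_ids=sorted(planted),
        enriched_tissue={g: "liver" for g in planted},
        gene_log2_mean=mu,
    )
    return ExpressionMatrix(values=values, sample_meta=meta), truth


def _stage_assignment(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Stage index (1, 2, 3) per tumor, at the configured proportions."""
    props = np.asarray(config.stage_proportions, dtype=float)
    props = props / props.sum()
    counts = np.floor(props * config.n_tumors).astype(int)
    counts[0] += config.n_tumors - counts.sum()
    idx = np.repeat([1, 2, 3], counts)
    rng.shuffle(idx)
    return idx


def simulate_tumor_cohort(
    config: SimConfig, normals: ExpressionMatrix, truth: SimTruth
) -> tuple[ExpressionMatrix, ClinicalTable, MethylationMatrix, SimTruth]:
    """Simulate a tumor cohort derived from the enriched tissue.

    Tumors copy the liver expression profile except that every planted
    gene's log2 mean is reduced by ``stage_index * stage_effect`` plus a
    per-tumor continuous jitter (the *true downregulation* ``a_j``).
    Survival is exponential with log-hazard ``hazard_coef * z_j`` where
    ``z_j`` standardizes ``a_j``; a fraction ``censor_rate`` of subjects
    is right-censored uniformly on ``(0, T_j)``.  Beta values of coupled
    genes increase affinely with each sample's expression deficit and
    are clipped to ``[0, 1]``.
    """
    if not truth.planted_teg_ids:
        raise ValueError("planted gene set is empty")
    tissues = set(normals.sample_meta["tissue_type"])
    if "liver" not in tissues:
        raise ValueError("normals must contain the enriched tissue 'liver'")

    genes = normals.gene_ids
    planted = truth.planted_teg_ids
    planted_mask = pd.Index(genes).isin(planted)
    log2fold = np.log2(config.planted_fold)

    rng_t = _rng(config.seed, "tumor")
    stage_idx = _stage_assignment(config, rng_t)
    tumor_ids = [f"tumor_T{j:03d}" for j in range(1, config.n_tumors + 1)]

    # continuous per-tumor downregulation around the stage mean
    a = stage_idx * config.stage_effect + rng_t.normal(0.0, 0.3, config.n_tumors)
    a = np.clip(a, 0.0, None)

    # liver baseline log2 mean per gene (enrichment included for planted)
    mu = truth.gene_log2_mean.reindex(genes).to_numpy().copy()
    mu[planted_mask] += log2fold
    means = np.tile(mu[:, None], (1, config.n_tumors))
    means[planted_mask, :] -= a[None, :]
    log2vals = means + rng_t.normal(0.0, config.noise_sd, size=means.shape)
    tumor_values = pd.DataFrame(np.exp2(log2vals), index=genes, columns=tumor_ids)
    tumor_meta = pd.DataFrame(
        {"tissue_type": "liver", "is_tumor": True, "cohort": "sim_tumor"},
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    tumors = ExpressionMatrix(values=tumor_values, sample_meta=tumor_meta)

    # grade loosely tracks stage
    rng_c = _rng(config.seed, "clinical")
    grade_idx = np.clip(
        stage_idx + rng_c.choice([-1, 0, 1], size=config.n_tumors, p=[0.25, 0.5, 0.25]),
        1, 3,
    )

    # survival: exponential, baseline median ~3 years
    rng_s = _rng(config.seed, "survival")
    sd_a = a.std(ddof=0)
    z = (a - a.mean()) / sd_a if sd_a > 0 else np.zeros_like(a)
    base_rate = np.log(2.0) / 1095.0
    rate = base_rate * np.exp(config.hazard_coef * z)
    t_event = rng_s.exponential(1.0 / rate)
    censored = rng_s.uniform(size=config.n_tumors) < config.censor_rate
    t_obs = np.where(censored, rng_s.uniform(0.0, 1.0, config.n_tumors) * t_event,
                     t_event)
    t_obs = np.maximum(t_obs, 1.0)
    os_event = ~censored

    zc = z  # shared latent severity for clinical covariates
    sigmoid = lambda x: 1.0 / (1.0 + np.exp(-x))
    clin = pd.DataFrame(index=pd.Index(tumor_ids, name="sample_id"))
    clin["os_time_days"] = np.round(t_obs, 1)
    clin["os_event"] = os_event
    clin["grade"] = [GRADE_LABELS[i - 1] for i in grade_idx]
    clin["stage"] = [STAGE_LABELS[i - 1] for i in stage_idx]
    clin["afp_high"] = rng_c.uniform(size=config.n_tumors) < sigmoid(-1.0 + 1.2 * zc)
    clin["gender"] = np.where(
        rng_c.uniform(size=config.n_tumors) < sigmoid(-0.8 + 0.8 * zc),
        "female", "male",
    )
    clin["vascular_invasion"] = np.where(
        rng_c.uniform(size=config.n_tumors) < sigmoid(-0.7 + 1.0 * zc), "yes", "no"
    )
    clin["child_pugh"] = np.where(rng_c.uniform(size=config.n_tumors) < 0.85, "a", "b/c")
    clin["inflammation"] = rng_c.choice(["no", "mild", "severe"],
                                        size=config.n_tumors, p=[0.5, 0.4, 0.1])
    clin["age"] = np.clip(np.round(60.0 - 3.0 * zc + rng_c.normal(0, 10, config.n_tumors), 1),
                          25, 90)
    clin["patient_weight"] = np.clip(
        np.round(72.0 - 4.0 * zc + rng_c.normal(0, 15, config.n_tumors), 1), 35, 160
    )
    clin["tumor_weight"] = np.clip(
        np.round(260.0 + 120.0 * zc + rng_c.normal(0, 200, config.n_tumors), 1), 5, None
    )
    clinical = ClinicalTable(clin)

    # methylation: planted genes plus 20% of background genes are covered
    rng_m = _rng(config.seed, "methylation")
    background = [g for g in genes if g not in set(planted)]
    n_bg_meth = int(0.2 * len(background))
    meth_genes = sorted(planted) + sorted(
        rng_m.choice(background, size=n_bg_meth, replace=False)
    )
    n_coupled = int(round(config.methyl_coupling * len(planted)))
    coupled = sorted(rng_m.choice(sorted(planted), size=n_coupled, replace=False))
    coupled_set = set(coupled)

    liver_normals = normals.subset_samples(
        list(normals.sample_meta.index[
            (normals.sample_meta["tissue_type"] == "liver")
            & (~normals.sample_meta["is_tumor"])
        ])
    )
    meth_samples = liver_normals.sample_ids + tumor_ids
    expr_all = pd.concat(
        [np.log2(liver_normals.values.loc[meth_genes]),
         np.log2(tumor_values.loc[meth_genes])], axis=1
    )
    b0 = pd.Series(rng_m.uniform(0.15, 0.35, size=len(meth_genes)), index=meth_genes)
    ref = pd.Series(mu, index=genes).reindex(meth_genes)
    beta = pd.DataFrame(index=meth_genes, columns=meth_samples, dtype=float)
    deficit = ref.to_numpy()[:, None] - expr_all.to_numpy()  # high when downregulated
    noise = rng_m.normal(0.0, 0.02, size=deficit.shape)
    base = b0.to_numpy()[:, None]
    coupled_mask = pd.Index(meth_genes).isin(coupled_set)
    vals = np.where(coupled_mask[:, None], base + 0.1 * deficit + noise,
                    base + rng_m.normal(0.0, 0.05, size=deficit.shape))
    beta.loc[:, :] = np.clip(vals, 0.0, 1.0)
    meth_meta = pd.concat([liver_normals.sample_meta, tumor_meta])
    methylation = MethylationMatrix(beta=beta, sample_meta=meth_meta)

    new_truth = replace(
        truth,
        tumor_stage=pd.Series(clin["stage"].to_numpy(), index=tumor_ids),
        tumor_grade=pd.Series(clin["grade"].to_numpy(), index=tumor_ids),
        true_downregulation=pd.Series(a, index=tumor_ids),
        true_linear_predictor=pd.Series(config.hazard_coef * z, index=tumor_ids),
        methyl_coupled_ids=coupled,
    )
    return tumors, clinical, methylation, new_truth


def simulate_subtypes(
    n_samples: int = 60,
    n_genes: int = 120,
    n_subtypes: int = 2,
    separation: float = 2.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a tumor cohort with planted expression subtypes.

    Each subtype upregulates its own disjoint block of genes by
    ``separation`` log2 units, giving roughly equidistant subtype
    centroids — the setting used to validate consensus clustering.
    Returns the (linear-scale) matrix and the true subtype labels.
    """
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes")
    rng = _rng(seed, "subtypes")
    genes = [f"sg{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"sub_T{j:03d}" for j in range(1, n_samples + 1)]
    labels = np.sort(np.arange(n_samples) % n_subtypes)
    rng.shuffle(labels)
    mu = rng.normal(3.0, 1.0, size=n_genes)
    log2vals = np.tile(mu[:, None], (1, n_samples))
    block = n_genes // n_subtypes
    for s in range(n_subtypes):
        rows = slice(s * block, (s + 1) * block)
        log2vals[rows, labels == s] += separation
    log2vals = log2vals + rng.normal(0.0, noise_sd, size=log2vals.shape)
    values = pd.DataFrame(np.exp2(log2vals), index=genes, columns=samples)
    meta = pd.DataFrame(
        {"tissue_type": "liver", "is_tumor": True, "cohort": "sim_subtypes"},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values=values, sample_meta=meta), labels
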