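"""Monti-style consensus clustering with stability-based model selection.

For each candidate cluster number K, the samples are repeatedly
subsampled without replacement, k-means (Euclidean) partitions each
subsample, and the consensus matrix records, for every sample pair, the
fraction of co-clustering runs among the runs where both samples were
drawn.  Cluster-number selection uses the PAC criterion (proportion of
ambiguous consensus entries, lower = more stable) by default, with the
classical delta-area-of-the-consensus-CDF rule as an alternative.
Final labels come from average-linkage hierarchical clustering of the
consensus dissimilarity (1 - consensus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix, ScaleError


@dataclass(frozen=True)
class ConsensusConfig:
    k_max: int = 6
    iterations: int = 1000
    subsample_fraction: float = 0.8
    inner_algorithm: str = "kmeans"
    distance: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("k_max must be at least 2")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.inner_algorithm != "kmeans":
            raise ValueError("only the kmeans inner algorithm is implemented")
        if self.distance != "euclidean":
            raise ValueError("only the euclidean distance is implemented")


@dataclass
class ConsensusResult:
    sample_ids: list[str]
    matrices: dict[int, np.ndarray]       # K -> sample × sample consensus
    labels: dict[int, np.ndarray]         # K -> final labels (0-based)
    pac: dict[int, float]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    ambiguous: bool                       # PAC > 0.5 for every K
    uncovered_pairs: dict[int, int]       # K -> pairs never co-subsampled
    selection_tie: bool = False


def _check_preprocessed(data: ExpressionMatrix) -> np.ndarray:
    if data.scale != "log2" or not data.centered:
        raise ScaleError(
            "consensus clustering expects a log2-transformed, median-centered matrix"
        )
    return data.values.to_numpy(dtype=float).T  # samples × genes


def consensus_matrix(
    data: ExpressionMatrix, k: int, cfg: ConsensusConfig,
    return_details: bool = False,
):
    """Resampled k-means consensus matrix for one cluster number K.

    Entry (i, j) = co-clustering count / co-sampling count; 0 (with a
    coverage tally) for pairs never co-subsampled.  With
    ``subsample_fraction = 1`` every iteration sees all samples, so for
    deterministic inner clusterings the entries are exactly 0 or 1.
    """
    x = _check_preprocessed(data)
    n = x.shape[0]
    size = int(np.floor(cfg.subsample_fraction * n))
    if k > size:
        raise ValueError(f"k = {k} exceeds subsample size {size}")
    rng = np.random.default_rng([int(cfg.seed), int(k)])
    cocluster = np.zeros((n, n))
    cosample = np.zeros((n, n))
    details = []
    for _ in range(cfg.iterations):
        sub = rng.choice(n, size=size, replace=False)
        km = KMeans(n_clusters=k, n_init=1, max_iter=100, tol=1e-6,
                    random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(x[sub])
        cosample[np.ix_(sub, sub)] += 1.0
        for c in range(k):
            idx = sub[lab == c]
            cocluster[np.ix_(idx, idx)] += 1.0
        if return_details:
            details.append((sub.copy(), lab.copy()))
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(cosample > 0, cocluster / np.maximum(cosample, 1.0), 0.0)
    m = (m + m.T) / 2.0
    if return_details:
        return m, cosample, details
    return m, cosample


def pac_score(m: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous consensus entries in (lower, upper)."""
    iu = np.triu_indices(m.shape[0], k=1)
    vals = m[iu]
    return float(((vals > lower) & (vals < upper)).mean())


def _cdf_area(m: np.ndarray, grid: int = 101) -> float:
    iu = np.triu_indices(m.shape[0], k=1)
    vals = np.sort(m[iu])
    xs = np.linspace(0.0, 1.0, grid)
    cdf = np.searchsorted(vals, xs, side="right") / len(vals)
    return float(np.trapezoid(cdf, xs))


def _labels_from_consensus(m: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust") - 1


def run_consensus(data: ExpressionMatrix, cfg: ConsensusConfig,
                  selection: str = "pac") -> ConsensusResult:
    """Consensus clustering over K = 2..k_max with stability selection."""
    x = _check_preprocessed(data)
    n = x.shape[0]
    if n < cfg.k_max:
        raise ValueError("fewer samples than k_max")
    matrices, labels, pac, areas, uncovered = {}, {}, {}, {}, {}
    for k in range(2, cfg.k_max + 1):
        m, cosample = consensus_matrix(data, k, cfg)
        matrices[k] = m
        pac[k] = pac_score(m)
        areas[k] = _cdf_area(m)
        iu = np.triu_indices(n, k=1)
        uncovered[k] = int((cosample[iu] == 0).sum())
        labels[k] = _labels_from_consensus(m, k)
    delta = {}
    prev = None
    for k in sorted(areas):
        delta[k] = areas[k] if prev is None else (areas[k] - areas[prev]) / areas[prev]
        prev = k
    result = ConsensusResult(
        sample_ids=data.sample_ids, matrices=matrices, labels=labels,
        pac=pac, cdf_area=areas, delta_area=delta, chosen_k=2,
        ambiguous=all(v > 0.5 for v in pac.values()), uncovered_pairs=uncovered,
    )
    result.chosen_k = select_k(result, method=selection)
    return result


def select_k(result: ConsensusResult, method: str = "pac",
             delta_threshold: float = 0.025) -> int:
    """Pick the cluster number from stability diagnostics.

    ``pac``: K minimizing the PAC score (ties -> smallest K, flagged).
    ``delta_area``: largest K whose relative increase in consensus-CDF
    area exceeds ``delta_threshold``.
    """
    ks = sorted(result.pac)
    if method == "pac":
        best = min(result.pac.values())
        winners = [k for k in ks if result.pac[k] == best]
        result.selection_tie = len(winners) > 1
        return winners[0]
    if method == "delta_area":
        winners = [k for k in ks if result.delta_area[k] > delta_threshold]
        return max(winners) if winners else ks[0]
    raise ValueError(f"unknown selection method {method!r}")


def final_labels(result: ConsensusResult, k: int) -> np.ndarray:
    """Average-linkage labels from the consensus matrix for a given K."""
    if k not in result.matrices:
        raise ValueError(f"no consensus matrix for k = {k}")
    if result.uncovered_pairs.get(k, 0) > 0:
        raise ValueError(
            "some sample pairs were never co-subsampled; increase iterations"
        )
    return _labels_from_consensus(result.matrices[k], k)
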