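"""Configuration: one YAML file mirroring every threshold of the pipeline."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "io": {
        "pseudocount": 1.0,          # added before log2 on RSEM-like data
        "na_sentinel": "NA",
    },
    "teg_screen": {
        "fold_threshold": 100.0,
        "alpha": 0.05,
    },
    "prognostic_screen": {
        "alpha": 0.05,
    },
    "profile": {
        "trend_alpha": 0.05,
    },
    "consensus": {
        "k_max": 6,
        "iterations": 1000,
        "subsample_fraction": 0.8,
        "inner_algorithm": "kmeans",
        "distance": "euclidean",
        "selection": "pac",
        "delta_threshold": 0.025,
    },
    "distance": {
        "pseudocount": 1.0,
        "n_groups": 3,
    },
    "simulate": {
        "n_tissues": 12,
        "samples_per_tissue": 10,
        "n_genes": 1000,
        "n_planted_tegs": 50,
        "planted_fold": 1000.0,
        "n_tumors": 300,
        "stage_effect": 1.0,
        "methyl_coupling": 0.8,
        "hazard_coef": 2.0,
        "censor_rate": 0.3,
        "noise_sd": 0.5,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _merge(DEFAULTS, user)
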