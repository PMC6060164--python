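import warnings

import numpy as np
import pandas as pd
import pytest

import tegdist as td

# gene-set / sample warnings about dropped members are part of tested
# contracts; silence them globally so individual tests stay readable
warnings.filterwarnings("ignore", category=UserWarning)


def make_expr(values, sample_ids=None, gene_ids=None, tissue="liver",
              is_tumor=False, cohort="c", scale="linear"):
    """Build a small ExpressionMatrix from a 2-D array-like."""
    arr = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    tissues = [tissue] * arr.shape[1] if isinstance(tissue, str) else list(tissue)
    tumors = [is_tumor] * arr.shape[1] if isinstance(is_tumor, bool) else list(is_tumor)
    meta = pd.DataFrame(
        {"tissue_type": tissues, "is_tumor": tumors, "cohort": cohort},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    return td.ExpressionMatrix(values=vals, sample_meta=meta, scale=scale)


def make_clinical(sample_ids, times, events, **extra):
    df = pd.DataFrame({"os_time_days": np.asarray(times, dtype=float),
                       "os_event": np.asarray(events, dtype=bool)},
                      index=pd.Index(sample_ids, name="sample_id"))
    for k, v in extra.items():
        df[k] = v
    return td.ClinicalTable(df)


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated compendium + tumor cohort shared across tests."""
    cfg = td.SimConfig(seed=1)
    normals, truth = td.simulate_multitissue(cfg)
    tumors, clin, meth, truth = td.simulate_tumor_cohort(cfg, normals, truth)
    return {"config": cfg, "normals": normals, "tumors": tumors,
            "clinical": clin, "methylation": meth, "truth": truth}


@pytest.fixture(scope="session")
def planted_gene_set(sim_cohort):
    return td.GeneSet("planted", tuple(sim_cohort["truth"].planted_teg_ids))
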