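import numpy as np
import pandas as pd
import pytest

import mscikit as mk

SMALL_CLASSES = {"X": 300, "Autosome": 1500, "Dot": 20, "Y": 5}


@pytest.fixture(scope="session")
def msci_sim():
    """One MSCI-scenario simulation (fraction 0.5, log2fc -1), small scale."""
    cfg = mk.msci_config(seed=101, n_genes_per_class=SMALL_CLASSES)
    dataset, annotation, truth = mk.simulate_experiment(cfg)
    return cfg, dataset, annotation, truth


@pytest.fixture(scope="session")
def null_sim():
    """One global-null simulation (identity purity, no effects)."""
    cfg = mk.null_config(seed=202, n_genes_per_class=SMALL_CLASSES)
    dataset, annotation, truth = mk.simulate_experiment(cfg)
    return cfg, dataset, annotation, truth


def toy_dataset(counts: dict[str, list[int]], stages: list[str], lengths=None):
    """Build a minimal ExpressionDataset from a column dict (one col/sample)."""
    counts_df = pd.DataFrame(counts)
    counts_df.index = [f"g{i}" for i in range(len(counts_df))]
    if lengths is None:
        lengths = pd.Series(1000, index=counts_df.index)
    else:
        lengths = pd.Series(lengths, index=counts_df.index)
    from mscikit.de import compute_tpm

    tpm = compute_tpm(counts_df, lengths)
    reps: dict[str, int] = {}
    rep_ids = []
    for s in stages:
        reps[s] = reps.get(s, 0) + 1
        rep_ids.append(reps[s])
    samples = pd.DataFrame(
        {"species": "toy", "stage": stages, "replicate": rep_ids},
        index=pd.Index(counts_df.columns, name="sample_id"),
    )
    return mk.ExpressionDataset(counts=counts_df, tpm=tpm, samples=samples)
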