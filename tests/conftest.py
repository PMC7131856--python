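import numpy as np
import pandas as pd
import pytest

from iopanel import (
    CountMatrix,
    PanelDefinition,
    default_config,
    simulate_counts,
    simulate_panel,
)


def make_panel(n_targets: int = 8, n_hk: int = 6, baseline: float = 100.0):
    """Small hand-built panel: T01..Tnn targets + HK01..HKnn controls."""
    targets = [f"T{i + 1:02d}" for i in range(n_targets)]
    hk = [f"HK{i + 1:02d}" for i in range(n_hk)]
    cats = [
        "checkpoint pathway", "lymphocyte infiltration", "TCR coexpression",
        "type II interferon signaling", "tumor antigen", "tumor marker",
        "other immune function",
    ]
    category = {g: cats[i % len(cats)] for i, g in enumerate(targets)}
    category.update({g: "housekeeping" for g in hk})
    return PanelDefinition(
        genes=targets + hk,
        category=category,
        hk_genes=hk,
        hk_baseline_rpm={g: baseline for g in hk},
    )


def make_counts(panel, sample_counts: dict, ntc=None):
    """CountMatrix from {sample: per-gene count list} in panel gene order."""
    counts = pd.DataFrame(sample_counts, index=panel.genes)
    if ntc is None:
        ntc = pd.Series(0, index=panel.genes)
    else:
        ntc = pd.Series(ntc, index=panel.genes)
    return CountMatrix(counts=counts, ntc=ntc)


def random_count_matrix(panel, n_samples, rng, lam=500.0):
    counts = pd.DataFrame(
        rng.poisson(lam, size=(len(panel.genes), n_samples)),
        index=pd.Index(panel.genes, name="gene"),
        columns=[f"S{i + 1:02d}" for i in range(n_samples)],
    )
    ntc = pd.Series(rng.poisson(5.0, len(panel.genes)), index=counts.index)
    return CountMatrix(counts=counts, ntc=ntc)


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture(scope="session")
def study_sim():
    """One study-shaped synthetic cohort shared across read-only tests."""
    cfg = default_config(seed=11)
    panel = simulate_panel(cfg)
    cm, meta, qc, truth = simulate_counts(cfg, panel)
    return cfg, panel, cm, meta, qc, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
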