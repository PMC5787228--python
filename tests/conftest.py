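"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from wheatgs.containers import MarkerMatrix
from wheatgs.qc import compute_kinship
from wheatgs.simulate import (
    SimulationConfig,
    default_major_loci,
    glu_marker_ids,
    simulate_genome,
    simulate_traits,
    simulate_trials,
)


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        n_lines=200, n_markers=400, n_chromosomes=10, n_trials=10,
        lines_per_trial=25, seed=42,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def panel():
    """200-line panel with the three major glutenin-like loci planted."""
    cfg0 = small_config()
    cfg = small_config(major_loci=default_major_loci(cfg0))
    markers, mmap = simulate_genome(cfg)
    truth = simulate_traits(markers, cfg)
    return {
        "config": cfg,
        "markers": markers,
        "map": mmap,
        "truth": truth,
        "glu_ids": glu_marker_ids(cfg),
        "kinship": compute_kinship(markers),
    }


@pytest.fixture(scope="session")
def trial_data(panel):
    pheno = simulate_trials(panel["truth"], panel["config"])
    return pheno


@pytest.fixture(scope="session")
def stab_blues(panel):
    """Noisy stability phenotype (h2 = 0.5) over the panel."""
    rng = np.random.default_rng(7)
    truth = panel["truth"]
    g = truth.true_bv["STAB"]
    y = g + rng.normal(0.0, g.std(ddof=1), len(g)) + 14.26
    return pd.Series(y, index=g.index, name="STAB")


def random_markers(n, m, seed=0, maf=(0.1, 0.5)) -> MarkerMatrix:
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, m)
    calls = np.where(rng.random((n, m)) < p, 1.0, -1.0)
    return MarkerMatrix(
        pd.DataFrame(calls, index=[f"L{i:03d}" for i in range(n)],
                     columns=[f"m{j:03d}" for j in range(m)])
    )
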