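"""Shared fixtures: small hand-made trials and one paper-scale simulated fit."""

import numpy as np
import pandas as pd
import pytest

from bayesgge import (
    MCMCPlan,
    ModelConfig,
    SimConfig,
    build_design,
    gibbs_run,
    met_from_frame,
    simulate_met,
)


def make_met(v=3, l=2, b=2, responses=None, seed=0):
    """Complete small MET table with deterministic or supplied responses."""
    rows = []
    rng = np.random.default_rng(seed)
    idx = 0
    for i in range(v):
        for j in range(l):
            for k in range(b):
                y = responses[idx] if responses is not None else rng.normal(10, 2)
                rows.append((f"G{i + 1:02d}", f"E{j + 1}", f"B{k + 1}", y))
                idx += 1
    return met_from_frame(
        pd.DataFrame(rows, columns=["genotype", "environment", "block", "response"])
    )


@pytest.fixture(scope="session")
def paper_met():
    """One trial at the study design (20 genotypes, 7 environments, 3 blocks)."""
    met, truth = simulate_met(SimConfig(seed=1))
    return met, truth


@pytest.fixture(scope="session")
def entropy_chain(paper_met):
    """Entropy-variant full-rank fit on the paper-scale trial (short chain)."""
    met, _ = paper_met
    return gibbs_run(
        met,
        ModelConfig(variant="entropy", k=met.t),
        MCMCPlan(J=1, B=500, n_keep=1200, seed=11),
    )


@pytest.fixture(scope="session")
def flat_chain(paper_met):
    met, _ = paper_met
    return gibbs_run(
        met,
        ModelConfig(variant="flat", k=met.t),
        MCMCPlan(J=1, B=500, n_keep=1200, seed=11),
    )


@pytest.fixture()
def toy_design():
    """v=4, l=3, b=2 complete trial with its design matrices."""
    met = make_met(v=4, l=3, b=2, seed=3)
    return met, build_design(met)
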