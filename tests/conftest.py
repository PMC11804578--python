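import numpy as np
import pandas as pd
import pytest

from plastiscan import SimulationConfig, simulate_experiments
from plastiscan.core import CountMatrix


def make_sheet(experiment: str, cue: str, n_individuals: int = 2) -> pd.DataFrame:
    """Small valid sample sheet covering all four populations."""
    rows = []
    for pop in ("Coast-W", "Mine-W", "Coast-E", "Mine-E"):
        eco = "coast" if pop.startswith("Coast") else "mine"
        pair = pop.split("-")[1]
        for k in range(n_individuals):
            for treatment in ("control", cue):
                rows.append(
                    dict(
                        sample_id=f"{experiment}.{pop}.i{k + 1}.{treatment}",
                        population=pop,
                        ecotype=eco,
                        pair=pair,
                        individual=f"i{k + 1}",
                        treatment=treatment,
                        experiment=experiment,
                    )
                )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            {"s1": [12, 30, 0], "s2": [20, 60, 1], "s3": [15, 45, 2], "s4": [13, 33, 3]},
            index=["g1", "g2", "g3"],
        )
    )


@pytest.fixture(scope="session")
def sim_small():
    """One shared 3000-gene simulation for contrast/classifier tests."""
    cfg = SimulationConfig(n_genes=3000, seed=11)
    salt_cm, zinc_cm, sheet, truth = simulate_experiments(cfg)
    return dict(cfg=cfg, salt=salt_cm, zinc=zinc_cm, sheet=sheet, truth=truth)


@pytest.fixture(scope="session")
def pipeline_small():
    """One shared end-to-end run reused by pipeline-level assertions."""
    from plastiscan import run_full

    cfg = dict(seed=5, simulate=dict(n_genes=3000), analysis=dict(n_permutations=200))
    return run_full(cfg, out_dir=None), cfg


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: sort, scale by m/k, cumulative min from
    the right, cap at 1, return in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
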