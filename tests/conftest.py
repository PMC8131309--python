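"""Shared fixtures: toy matrices and session-scoped trained generators."""

import numpy as np
import pytest

from dualsarm.generative import TrainingConfig, finetune, pretrain
from dualsarm.sarm_core import Cell, CellStatus, Sarm
from dualsarm.synthetic_data import (
    SyntheticSpec,
    gen_analog_series,
    gen_fragment_corpus,
)


def make_measured_sarm(potency: dict[tuple[int, int], float],
                       n_rows: int, n_cols: int, target: str = "T") -> Sarm:
    """Build a bare SAR matrix with the given measured cells (one target).

    Rows/cols carry placeholder fragment labels; chemistry is irrelevant
    for potency-prediction tests.
    """
    rows = [f"core{i}" for i in range(n_rows)]
    cols = [f"sub{j}" for j in range(n_cols)]
    cells = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if (i, j) in potency:
                cells[(i, j)] = Cell(
                    key1=rows[i], value1=cols[j], status=CellStatus.EXISTING,
                    compound_id=f"c{i}_{j}", potency={target: potency[(i, j)]},
                )
            else:
                cells[(i, j)] = Cell(
                    key1=rows[i], value1=cols[j], status=CellStatus.VIRTUAL
                )
    return Sarm(rows=rows, cols=cols, cells=cells)


def additive_potencies(n_rows: int, n_cols: int, seed: int, noise_sd: float = 0.0,
                       mu: float = 6.0):
    """Ground-truth additive grid: potency(i, j) = mu + a_i + b_j + noise."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.8, n_rows)
    b = rng.normal(0, 0.5, n_cols)
    pot = {
        (i, j): float(mu + a[i] + b[j] + rng.normal(0, noise_sd))
        for i in range(n_rows)
        for j in range(n_cols)
    }
    return pot, mu, a, b


@pytest.fixture(scope="session")
def value1_corpus():
    """200-line substituent-fragment corpus from the synthetic generator."""
    spec = SyntheticSpec(
        n_scaffolds=20, n_substituents=30, fill_fraction=0.6, seed=7
    )
    dataset = gen_analog_series(spec)
    return gen_fragment_corpus(dataset, "value1")[:200]


@pytest.fixture(scope="session")
def pretrained_value1(value1_corpus):
    cfg = TrainingConfig(epochs=30, batch_size=32, seed=7)
    return pretrain(value1_corpus, "value1", cfg)


@pytest.fixture(scope="session")
def focus_fragments(value1_corpus):
    """20 focus fragments, as from a small set of dual-target ligands."""
    return sorted(set(value1_corpus))[:20]


@pytest.fixture(scope="session")
def finetuned_value1(pretrained_value1, focus_fragments):
    cfg = TrainingConfig(epochs=10, batch_size=8, seed=7)
    return finetune(pretrained_value1, focus_fragments, cfg)
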