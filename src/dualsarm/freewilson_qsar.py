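"""Local Free-Wilson potency prediction inside one SAR matrix.

The potency of a virtual cell (i, j) is estimated from *matrix
neighborhoods*: triples of measured cells (i, l), (k, j), (k, l) sharing
the virtual cell's core or substituent.  Under additivity each triple
gives pot(i, j) ~ pot(i, l) + pot(k, j) - pot(k, l); the prediction is the
unweighted mean over all complete neighborhoods, with the spread across
neighborhoods reported as a stability measure.  A global least-squares
additive fit of the same matrix serves as the reference estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ContractError, DisconnectedMatrixError
from .sarm_core import CellStatus, Sarm


@dataclass(frozen=True)
class NeighborhoodPrediction:
    cell: tuple[int, int]
    target: str
    predicted_pIC50: float
    n_neighborhoods: int
    spread: float  # sd across per-neighborhood estimates; 0 when n == 1


def complete_neighborhoods(
    sarm: Sarm, cell: tuple[int, int], target: str
) -> list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]:
    """All measured triples ((i,l), (k,j), (k,l)) around a virtual cell.

    Deterministic order: ascending (k, l).
    """
    i, j = cell
    if sarm.measured(i, j, target) is not None:
        raise ContractError(f"cell {cell} already has a {target} measurement")
    n_rows, n_cols = sarm.shape
    out = []
    for k in range(n_rows):
        if k == i or sarm.measured(k, j, target) is None:
            continue
        for l in range(n_cols):
            if l == j:
                continue
            if (
                sarm.measured(i, l, target) is not None
                and sarm.measured(k, l, target) is not None
            ):
                out.append(((i, l), (k, j), (k, l)))
    out.sort(key=lambda triple: (triple[2][0], triple[2][1]))
    return out


def predict_cell_potency(
    sarm: Sarm, cell: tuple[int, int], target: str, min_neighborhoods: int = 1
) -> NeighborhoodPrediction | None:
    """Neighborhood-mean Free-Wilson prediction for one virtual cell.

    Returns None (an explicit no-prediction result) when fewer than
    ``min_neighborhoods`` complete neighborhoods exist.
    """
    triples = complete_neighborhoods(sarm, cell, target)
    if len(triples) < max(1, min_neighborhoods):
        return None
    estimates = np.array(
        [
            sarm.measured(*il, target)
            + sarm.measured(*kj, target)
            - sarm.measured(*kl, target)
            for il, kj, kl in triples
        ]
    )
    return NeighborhoodPrediction(
        cell=cell,
        target=target,
        predicted_pIC50=float(estimates.mean()),
        n_neighborhoods=len(estimates),
        spread=float(estimates.std(ddof=0)) if len(estimates) > 1 else 0.0,
    )


def predict_all_virtual(
    sarm: Sarm, target: str, min_neighborhoods: int = 1
) -> list[NeighborhoodPrediction]:
    """Predictions for every cell without a measurement for ``target``."""
    out = []
    for ij in sorted(sarm.cells):
        c = sarm.cells[ij]
        if c.status is CellStatus.EXISTING and target in c.potency:
            continue
        pred = predict_cell_potency(sarm, ij, target, min_neighborhoods)
        if pred is not None:
            out.append(pred)
    return out


@dataclass(frozen=True)
class AdditiveFit:
    mu: float
    row_effects: np.ndarray  # sum-zero over rows with data
    col_effects: np.ndarray
    residual_rms: float

    def predict(self, i: int, j: int) -> float:
        return float(self.mu + self.row_effects[i] + self.col_effects[j])


def fit_additive_oracle(sarm: Sarm, target: str) -> AdditiveFit:
    """Least-squares additive decomposition pot(i,j) = mu + a_i + b_j.

    Identifiability: sum of a over measured rows = sum of b over measured
    cols = 0.  The measurement pattern must connect all measured rows and
    columns; disconnected blocks make the decomposition ambiguous and
    raise :class:`DisconnectedMatrixError` naming the blocks.
    """
    n_rows, n_cols = sarm.shape
    obs = [
        (i, j, sarm.measured(i, j, target))
        for i in range(n_rows)
        for j in range(n_cols)
        if sarm.measured(i, j, target) is not None
    ]
    rows_seen = {i for i, _, _ in obs}
    cols_seen = {j for _, j, _ in obs}
    if len(obs) < 3 or len(rows_seen) < 2 or len(cols_seen) < 2:
        raise ContractError(
            f"need >= 3 measurements spanning >= 2 rows and 2 cols; "
            f"got {len(obs)} over {len(rows_seen)} rows x {len(cols_seen)} cols"
        )

    graph = nx.Graph()
    graph.add_edges_from((("r", i), ("c", j)) for i, j, _ in obs)
    components = list(nx.connected_components(graph))
    if len(components) > 1:
        blocks = [
            (
                {n for kind, n in comp if kind == "r"},
                {n for kind, n in comp if kind == "c"},
            )
            for comp in components
        ]
        raise DisconnectedMatrixError(blocks)

    design = np.zeros((len(obs), 1 + n_rows + n_cols))
    y = np.zeros(len(obs))
    for row, (i, j, v) in enumerate(obs):
        design[row, 0] = 1.0
        design[row, 1 + i] = 1.0
        design[row, 1 + n_rows + j] = 1.0
        y[row] = v
    theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    mu = theta[0]
    a = theta[1 : 1 + n_rows].copy()
    b = theta[1 + n_rows :].copy()
    # re-center the minimum-norm solution onto the sum-zero convention
    ridx = sorted(rows_seen)
    cidx = sorted(cols_seen)
    a_bar = a[ridx].mean()
    b_bar = b[cidx].mean()
    a[ridx] -= a_bar
    b[cidx] -= b_bar
    mu += a_bar + b_bar
    fitted = np.array([mu + a[i] + b[j] for i, j, _ in obs])
    residual = float(np.sqrt(np.mean((fitted - y) ** 2)))
    return AdditiveFit(mu=float(mu), row_effects=a, col_effects=b, residual_rms=residual)
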