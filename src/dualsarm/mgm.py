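"""Molecular Grid Maps: similarity layout and dual-target rendering.

All compounds of one or more SAR matrices are compared by fingerprint
Tanimoto similarity, projected to 2D (a linear PCA stage, optionally
followed by t-SNE), snapped to a regular grid by solving a balanced
assignment problem, and refined by pairwise-swap local search on the
similarity-weighted grid-distance objective

    cost(placement) = sum_{i<j} sim(i, j) * ||cell_i - cell_j||.

Rendering draws each compound as a circle divided into two halves,
color-coded by (experimental or predicted) potency against the two
targets; the same renderer draws SAR matrices in grid order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import ContractError, ParseError

logger = logging.getLogger(__name__)


def similarity_matrix(compounds: list[str], radius: int = 2, n_bits: int = 2048
                      ) -> np.ndarray:
    """Pairwise Tanimoto similarity on Morgan fingerprints; diagonal 1."""
    if len(compounds) < 2:
        raise ContractError("need at least 2 compounds")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = []
    for n, smi in enumerate(compounds):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"compound {n}: unparsable SMILES {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        sim[i, i + 1:] = row
        sim[i + 1:, i] = row
    return sim


@dataclass
class EmbedConfig:
    use_pca: bool = True
    use_tsne: bool = True
    pca_components: int = 10
    perplexity: float | None = None  # default: min(30, (n - 1) / 3)
    tsne_min_n: int = 8  # below this the neighborhood stage is skipped


def embed_2d(features: np.ndarray, config: EmbedConfig | None = None, seed: int = 0
             ) -> np.ndarray:
    """Project a feature (or similarity) matrix to n x 2 coordinates.

    Linear stage (PCA) first, then a t-SNE neighborhood-embedding stage;
    either can be disabled.  Deterministic for a fixed seed.
    """
    config = config or EmbedConfig()
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 3:
        raise ContractError(f"need at least 3 items to embed, got {n}")
    coords = features
    if config.use_pca:
        k = min(config.pca_components, n - 1, features.shape[1])
        coords = PCA(n_components=k, random_state=seed).fit_transform(features)
    if config.use_tsne and n >= config.tsne_min_n:
        perplexity = config.perplexity or min(30.0, (n - 1) / 3.0)
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=seed,
        ).fit_transform(coords)
    return np.asarray(coords[:, :2], dtype=float)


def choose_grid_dims(n: int, slack: float = 0.1) -> tuple[int, int]:
    """Smallest square grid holding n compounds plus a slack margin."""
    if n < 1:
        raise ContractError("need at least one compound")
    side = math.ceil(math.sqrt(n * (1 + slack)))
    return side, side


@dataclass
class GridLayout:
    grid_dims: tuple[int, int]
    placement: dict[int, tuple[int, int]]  # compound index -> (row, col)
    cost: float
    categories: dict[int, str] = field(default_factory=dict)

    def occupied(self) -> set[tuple[int, int]]:
        return set(self.placement.values())


def grid_assign(coords: np.ndarray, grid_dims: tuple[int, int]) -> GridLayout:
    """Snap embedded coordinates to grid cells, minimizing total squared
    displacement (balanced assignment, solved exactly)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    rows, cols = grid_dims
    if rows * cols < n:
        side = math.ceil(math.sqrt(n))
        raise ContractError(
            f"grid {rows}x{cols} holds {rows * cols} < {n} compounds; "
            f"minimal square grid is {side}x{side}"
        )
    centers = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    scaled = np.empty_like(coords)
    for axis, extent in enumerate((rows - 1, cols - 1)):
        lo, hi = coords[:, axis].min(), coords[:, axis].max()
        span = hi - lo
        scaled[:, axis] = (
            (coords[:, axis] - lo) / span * extent if span > 0 else extent / 2.0
        )
    cost_matrix = ((scaled[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    row_ind, col_ind = linear_sum_assignment(cost_matrix)
    placement = {
        int(i): (int(centers[j, 0]), int(centers[j, 1]))
        for i, j in zip(row_ind, col_ind)
    }
    return GridLayout(
        grid_dims=grid_dims,
        placement=placement,
        cost=float(cost_matrix[row_ind, col_ind].sum()),
    )


def grid_cost(placement: dict[int, tuple[int, int]], similarity: np.ndarray) -> float:
    """Similarity-weighted sum of pairwise Euclidean grid distances."""
    idx = sorted(placement)
    pos = np.array([placement[i] for i in idx], dtype=float)
    dists = squareform(pdist(pos))
    sim = similarity[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float((sim[iu] * dists[iu]).sum())


def grid_optimize(
    layout: GridLayout,
    similarity: np.ndarray,
    max_iterations: int = 200,
    seed: int = 0,
) -> GridLayout:
    """Steepest-descent pairwise-swap local search on the layout.

    Each iteration applies the single swap (compound-compound or
    compound-empty cell) that lowers the objective most; the cost trace is
    monotone non-increasing by construction.  Stops at a local optimum or
    after ``max_iterations`` swaps.
    """
    idx = sorted(layout.placement)
    n = len(idx)
    rows, cols = layout.grid_dims
    cells = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    n_cells = len(cells)
    cell_dist = squareform(pdist(cells))  # grid-cell center distances
    cell_of = {(int(r), int(c)): k for k, (r, c) in enumerate(cells)}
    occ = np.array([cell_of[layout.placement[i]] for i in idx])
    sim = similarity[np.ix_(idx, idx)].astype(float)

    def total_cost() -> float:
        d = cell_dist[np.ix_(occ, occ)]
        iu = np.triu_indices(n, k=1)
        return float((sim[iu] * d[iu]).sum())

    trace = [total_cost()]
    eye = np.arange(n)
    for _ in range(max_iterations):
        # F[i, v] = sum_j sim[i, j] * dist(cell of j, cell v)
        F = sim @ cell_dist[occ, :]
        current = F[eye, occ]
        # relocation of one compound to any cell (occupied cells masked below)
        move_delta = F - current[:, None]
        occupied_mask = np.zeros(n_cells, dtype=bool)
        occupied_mask[occ] = True
        move_delta[:, occupied_mask] = np.inf
        # pairwise swap: E[i, j] = F[i, occ_j]
        E = F[:, occ]
        d_pair = cell_dist[np.ix_(occ, occ)]
        swap_delta = (
            E + E.T - current[:, None] - current[None, :]
            - 2.0 * (1.0 - sim) * d_pair
        )
        swap_delta[np.tril_indices(n)] = np.inf

        best_move = np.unravel_index(np.argmin(move_delta), move_delta.shape)
        best_swap = np.unravel_index(np.argmin(swap_delta), swap_delta.shape)
        d_move = move_delta[best_move]
        d_swap = swap_delta[best_swap]
        if min(d_move, d_swap) >= -1e-10:
            break
        if d_move <= d_swap:
            occ[best_move[0]] = best_move[1]
        else:
            i, j = best_swap
            occ[i], occ[j] = occ[j], occ[i]
        trace.append(total_cost())

    placement = {
        i: (int(cells[occ[k], 0]), int(cells[occ[k], 1]))
        for k, i in enumerate(idx)
    }

    logger.info("grid_optimize: %d swaps, cost %.4f -> %.4f",
                len(trace) - 1, trace[0], trace[-1])
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
    return GridLayout(
        grid_dims=layout.grid_dims,
        placement=placement,
        cost=trace[-1],
        categories=dict(layout.categories),
    )


# --------------------------------------------------------------- rendering

_CATEGORY_STROKE = {
    "existing": "#1f3b8f",  # blue frame, as for original-matrix compounds
    "virtual": "#808080",
    "generated-virtual": "#000000",
}


def _potency_color(value: float, lo: float, hi: float) -> str:
    """Continuous red (low) -> yellow -> green (high) scale."""
    t = 0.5 if hi <= lo else (value - lo) / (hi - lo)
    t = min(1.0, max(0.0, t))
    if t < 0.5:
        f = t / 0.5
        r, g, b = 214, int(30 + (200 - 30) * f), 30
    else:
        f = (t - 0.5) / 0.5
        r, g, b = int(214 * (1 - f)), int(200 - 60 * f), 30
    return f"#{r:02x}{g:02x}{b:02x}"


def render_dual(
    positions: dict[int, tuple[int, int]],
    values_a: dict[int, float],
    values_b: dict[int, float],
    out_path,
    categories: dict[int, str] | None = None,
    target_names: tuple[str, str] = ("A", "B"),
    cell_px: int = 34,
) -> str:
    """Write an SVG of divided-circle nodes on grid positions.

    Left half = target A, right half = target B; color anchors are the
    pooled min/max of the displayed values per target.  Nodes missing both
    values are drawn hollow (with a logged warning); output bytes are
    deterministic for fixed input.
    """
    categories = categories or {}
    ids = sorted(positions)
    lo_a, hi_a = _anchors(values_a)
    lo_b, hi_b = _anchors(values_b)
    max_r = max(r for r, _ in positions.values()) + 1
    max_c = max(c for _, c in positions.values()) + 1
    width, height = (max_c + 1) * cell_px, (max_r + 2) * cell_px + 30
    radius = cell_px * 0.42
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for i in ids:
        r, c = positions[i]
        cx = (c + 1) * cell_px
        cy = (r + 1) * cell_px
        stroke = _CATEGORY_STROKE.get(categories.get(i, "virtual"), "#808080")
        va, vb = values_a.get(i), values_b.get(i)
        if va is None and vb is None:
            logger.warning("node %s has no value for either target", i)
            parts.append(
                f'<circle cx="{cx}" cy="{cy}" r="{radius:.1f}" fill="none" '
                f'stroke="{stroke}" stroke-width="1.5"/>'
            )
            continue
        fill_a = _potency_color(va, lo_a, hi_a) if va is not None else "white"
        fill_b = _potency_color(vb, lo_b, hi_b) if vb is not None else "white"
        parts.append(
            f'<path d="M {cx} {cy - radius:.1f} A {radius:.1f} {radius:.1f} 0 0 0 '
            f'{cx} {cy + radius:.1f} Z" fill="{fill_a}"/>'
        )
        parts.append(
            f'<path d="M {cx} {cy - radius:.1f} A {radius:.1f} {radius:.1f} 0 0 1 '
            f'{cx} {cy + radius:.1f} Z" fill="{fill_b}"/>'
        )
        parts.append(
            f'<circle cx="{cx}" cy="{cy}" r="{radius:.1f}" fill="none" '
            f'stroke="{stroke}" stroke-width="1.5"/>'
        )
    ly = (max_r + 1) * cell_px + 20
    parts.append(
        f'<text x="{cell_px}" y="{ly}" font-size="12" font-family="sans-serif">'
        f"left half: {target_names[0]}  |  right half: {target_names[1]}  |  "
        "red = low, yellow = mid, green = high potency</text>"
    )
    parts.append("</svg>")
    svg = "\n".join(parts)
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(svg)
    return svg


def _anchors(values: dict[int, float]) -> tuple[float, float]:
    present = [v for v in values.values() if v is not None]
    if not present:
        return 0.0, 1.0
    return min(present), max(present)


def render_sarm_dual(sarm, values_a, values_b, out_path, **kwargs) -> str:
    """Render a SAR matrix in matrix order with divided-circle cells.

    ``values_a``/``values_b`` map (row, col) to a potency or prediction.
    """
    cell_ids = sorted(sarm.cells)
    positions = {n: ij for n, ij in enumerate(cell_ids)}
    categories = {n: sarm.cells[ij].status.value for n, ij in enumerate(cell_ids)}
    va = {n: values_a.get(ij) for n, ij in enumerate(cell_ids)}
    vb = {n: values_b.get(ij) for n, ij in enumerate(cell_ids)}
    return render_dual(positions, va, vb, out_path, categories=categories, **kwargs)
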