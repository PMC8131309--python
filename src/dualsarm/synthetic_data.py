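"""Synthetic combinatorial analog series with additive dual-target potencies.

The generator emulates the structure the pipeline assumes in real
medicinal-chemistry data sets: families of closely related scaffolds
(cores differing at one ring position), combinatorial substituent sets,
per-target potencies that are approximately additive in core and
substituent contributions, and a subset of compounds measured against
both targets.  Ground-truth effects are returned with every data set so
recovery can be tested exactly.

Scaffold decorations (F, Cl, Br, OH) are disjoint from the substituent
vocabulary, which guarantees that every (scaffold, substituent) pair
realizes a distinct molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .fragmentation import Molecule, attach, build_compound_index, canonicalize
from .sarm_core import fragment_cores

#: four scaffold families; members of one family differ at a single ring
#: position, members of different families share no two-point scaffold
SCAFFOLD_FAMILIES: tuple[tuple[str, ...], ...] = (
    (
        "[*]c1ccccc1",
        "[*]c1ccc(F)cc1",
        "[*]c1ccc(Cl)cc1",
        "[*]c1ccc(Br)cc1",
        "[*]c1ccc(O)cc1",
    ),
    (
        "[*]c1cccs1",
        "[*]c1ccc(F)s1",
        "[*]c1ccc(Cl)s1",
        "[*]c1ccc(Br)s1",
        "[*]c1ccc(O)s1",
    ),
    (
        "[*]C1CCCCC1",
        "[*]C1CCC(F)CC1",
        "[*]C1CCC(Cl)CC1",
        "[*]C1CCC(Br)CC1",
        "[*]C1CCC(O)CC1",
    ),
    (
        "[*]c1cccnc1",
        "[*]c1ccc(F)nc1",
        "[*]c1ccc(Cl)nc1",
        "[*]c1ccc(Br)nc1",
        "[*]c1ccc(O)nc1",
    ),
)

SCAFFOLDS: tuple[str, ...] = tuple(s for fam in SCAFFOLD_FAMILIES for s in fam)

SUBSTITUENTS: tuple[str, ...] = (
    "[*]C",
    "[*]CC",
    "[*]CCC",
    "[*]C(C)C",
    "[*]CCCC",
    "[*]CC(C)C",
    "[*]OC",
    "[*]OCC",
    "[*]OC(C)C",
    "[*]N",
    "[*]NC",
    "[*]N(C)C",
    "[*]C#N",
    "[*]C(F)(F)F",
    "[*]CO",
    "[*]CCO",
    "[*]CCN",
    "[*]CN",
    "[*]C(=O)C",
    "[*]C(=O)OC",
    "[*]C(=O)N",
    "[*]C=C",
    "[*]SC",
    "[*]CCF",
    "[*]CC#N",
    "[*]CCCl",
    "[*]C(C)O",
    "[*]CC=C",
    "[*]COC",
    "[*]CCOC",
)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic data set.

    Potency model per target t: pIC50(i, j, t) = mu_t + a_i(t) + b_j(t)
    + N(0, noise_sd).  ``fill_fraction`` selects which grid cells carry a
    "measured" compound; ``n_planted`` reserves that many cells of one
    high-effect row as unmeasured planted dual-target optima.
    """

    n_scaffolds: int = 4
    n_substituents: int = 5
    fill_fraction: float = 0.5
    targets: tuple[str, str] = ("A", "B")
    mu: dict[str, float] = field(default_factory=lambda: {"A": 6.5, "B": 6.0})
    scaffold_sd: float = 0.75
    substituent_sd: float = 0.5
    noise_sd: float = 0.2
    dual_overlap_fraction: float = 0.7
    n_planted: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fill_fraction <= 1):
            raise ContractError("fill_fraction must lie in (0, 1]")
        if self.n_scaffolds > len(SCAFFOLDS):
            raise ContractError(f"at most {len(SCAFFOLDS)} scaffolds available")
        if self.n_substituents > len(SUBSTITUENTS):
            raise ContractError(f"at most {len(SUBSTITUENTS)} substituents available")


@dataclass
class GroundTruth:
    mu: dict[str, float]
    scaffold_effects: dict[str, np.ndarray]  # target -> (n_scaffolds,)
    substituent_effects: dict[str, np.ndarray]  # target -> (n_substituents,)
    scaffolds: list[str]
    substituents: list[str]

    def true_potency(self, i: int, j: int, target: str) -> float:
        return float(
            self.mu[target]
            + self.scaffold_effects[target][i]
            + self.substituent_effects[target][j]
        )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    table: pd.DataFrame  # columns: id, smiles, scaffold_idx, substituent_idx, pIC50_<t>...
    truth: GroundTruth
    planted: list[tuple[int, int, str]]  # (scaffold_idx, substituent_idx, smiles)

    @property
    def compounds(self) -> list[Molecule]:
        return [
            Molecule.from_smiles(r.id, r.smiles) for r in self.table.itertuples()
        ]

    def potency_records(self) -> dict[str, dict[str, list[float]]]:
        cols = [f"pIC50_{t}" for t in self.spec.targets]
        out: dict[str, dict[str, list[float]]] = {}
        for r in self.table.itertuples():
            rec = {}
            for t, col in zip(self.spec.targets, cols):
                v = getattr(r, col)
                if np.isfinite(v):
                    rec[t] = [float(v)]
            out[r.id] = rec
        return out


def gen_analog_series(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a filled scaffold x substituent grid with additive potencies.

    Exactly ``round(fill_fraction * n_cells)`` cells become compounds (the
    selection is deterministic per seed); planted cells are excluded from
    the fill and reported separately with boosted true potency on both
    targets.
    """
    rng = np.random.default_rng(spec.seed)
    scaffolds = [canonicalize(s) for s in SCAFFOLDS[: spec.n_scaffolds]]
    subs = [canonicalize(s) for s in SUBSTITUENTS[: spec.n_substituents]]
    truth = GroundTruth(
        mu=dict(spec.mu),
        scaffold_effects={
            t: rng.normal(0.0, spec.scaffold_sd, spec.n_scaffolds)
            for t in spec.targets
        },
        substituent_effects={
            t: rng.normal(0.0, spec.substituent_sd, spec.n_substituents)
            for t in spec.targets
        },
        scaffolds=scaffolds,
        substituents=subs,
    )

    planted: list[tuple[int, int, str]] = []
    excluded: set[tuple[int, int]] = set()
    if spec.n_planted:
        if spec.n_planted > spec.n_substituents:
            raise ContractError("n_planted exceeds the number of substituents")
        i_star = 0
        for t in spec.targets:  # make row i* and the planted cols best for both
            truth.scaffold_effects[t][i_star] = 2.5 * spec.scaffold_sd
        for j_star in range(spec.n_planted):
            for t in spec.targets:
                truth.substituent_effects[t][j_star] = 2.5 * spec.substituent_sd
            smiles = attach(scaffolds[i_star], subs[j_star])
            planted.append((i_star, j_star, smiles))
            excluded.add((i_star, j_star))

    n_fill = round(spec.fill_fraction * spec.n_scaffolds * spec.n_substituents)
    chosen = _coverage_fill(
        rng, spec.n_scaffolds, spec.n_substituents, n_fill, excluded
    )

    per_row: dict[int, int] = {}
    for i, _ in chosen:
        per_row[i] = per_row.get(i, 0) + 1
    if not any(c >= 2 for c in per_row.values()):
        raise ContractError(
            "fill_fraction too low: no scaffold row has >= 2 compounds "
            "(no analog series can form)"
        )

    rows = []
    for n, (i, j) in enumerate(chosen):
        rec = {
            "id": f"syn{n:05d}",
            "smiles": attach(scaffolds[i], subs[j]),
            "scaffold_idx": i,
            "substituent_idx": j,
        }
        for t in spec.targets:
            rec[f"pIC50_{t}"] = truth.true_potency(i, j, t) + rng.normal(
                0.0, spec.noise_sd
            )
        rows.append(rec)
    table = pd.DataFrame(rows)
    return SyntheticDataset(spec=spec, table=table, truth=truth, planted=planted)


def _coverage_fill(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    n_fill: int,
    excluded: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Select grid cells to fill, observing every row and column once if
    the budget allows (real combinatorial series use every core and every
    substituent somewhere); the remainder is uniform at random."""
    cells = [
        (i, j) for i in range(n_rows) for j in range(n_cols)
        if (i, j) not in excluded
    ]
    n_fill = min(n_fill, len(cells))
    chosen: set[tuple[int, int]] = set()
    if n_fill >= max(n_rows, n_cols):
        used_cols: set[int] = set()
        for i in rng.permutation(n_rows):
            for j in rng.permutation(n_cols):
                if (i, j) not in excluded and j not in used_cols:
                    chosen.add((int(i), int(j)))
                    used_cols.add(int(j))
                    break
        for j in range(n_cols):
            if j in used_cols:
                continue
            for i in rng.permutation(n_rows):
                if (i, j) not in excluded:
                    chosen.add((int(i), int(j)))
                    used_cols.add(j)
                    break
    pool = [c for c in cells if c not in chosen]
    for k in rng.permutation(len(pool)):
        if len(chosen) >= n_fill:
            break
        chosen.add(pool[k])
    return sorted(chosen)


def gen_dual_target_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Split a generated set into per-target tables with a shared overlap.

    Each compound is assigned to both targets with probability
    ``dual_overlap_fraction``, otherwise to one target (alternating
    deterministically).  Returns (table_A, table_B, overlap_ids); each
    table has columns id, smiles, pIC50.
    """
    if not (0 < spec.dual_overlap_fraction < 1):
        raise ContractError("dual_overlap_fraction must lie in (0, 1)")
    ds = gen_analog_series(spec)
    rng = np.random.default_rng(spec.seed + 1)
    t_a, t_b = spec.targets
    rows_a, rows_b, overlap = [], [], []
    solo_toggle = 0
    for r in ds.table.itertuples():
        rec_a = {"id": r.id, "smiles": r.smiles, "pIC50": getattr(r, f"pIC50_{t_a}")}
        rec_b = {"id": r.id, "smiles": r.smiles, "pIC50": getattr(r, f"pIC50_{t_b}")}
        if rng.random() < spec.dual_overlap_fraction:
            rows_a.append(rec_a)
            rows_b.append(rec_b)
            overlap.append(r.id)
        elif solo_toggle == 0:
            rows_a.append(rec_a)
            solo_toggle = 1
        else:
            rows_b.append(rec_b)
            solo_toggle = 0
    if not overlap:
        raise ContractError("overlap subset is empty; increase dual_overlap_fraction")
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b), overlap


def gen_fragment_corpus(dataset: SyntheticDataset, role: str) -> list[str]:
    """Fragment corpus for one generator role, via the real fragmentation ops.

    Lines repeat with fragment frequency (the corpus is occurrence-
    weighted); every line has the attachment-point count its role requires
    (two for key2, one otherwise).
    """
    if role not in ("key2", "value2", "value1"):
        raise ContractError(f"unknown corpus role: {role!r}")
    index = build_compound_index(dataset.compounds)
    if role == "value1":
        return [
            e.value for k in sorted(index.entries) for e in index.entries[k]
        ]
    core_index = fragment_cores(index)
    if role == "key2":
        return [
            k2 for k2 in sorted(core_index) for _ in core_index[k2]
        ]
    return [
        v2 for k2 in sorted(core_index) for (v2, _) in core_index[k2]
    ]


def sarm_from_dataset(
    dataset: SyntheticDataset, scaffold_indices: list[int] | None = None
) -> "Sarm":
    """Assemble the ground-truth grid of a generated set as one SAR matrix.

    Rows are the (selected) scaffolds, columns the substituents; filled
    grid cells become existing cells carrying their per-target potencies,
    all other combinations (including planted hold-outs) are virtual.
    """
    from .sarm_core import Cell, CellStatus, Sarm

    truth = dataset.truth
    scaffold_indices = scaffold_indices or list(range(len(truth.scaffolds)))
    rows = [truth.scaffolds[i] for i in scaffold_indices]
    cols = list(truth.substituents)
    filled = {
        (int(r.scaffold_idx), int(r.substituent_idx)): r
        for r in dataset.table.itertuples()
    }
    cells: dict[tuple[int, int], Cell] = {}
    for ri, si in enumerate(scaffold_indices):
        for j in range(len(cols)):
            rec = filled.get((si, j))
            if rec is not None:
                potency = {
                    t: float(getattr(rec, f"pIC50_{t}")) for t in dataset.spec.targets
                }
                cells[(ri, j)] = Cell(
                    key1=rows[ri], value1=cols[j], status=CellStatus.EXISTING,
                    compound_id=rec.id, potency=potency, smiles=rec.smiles,
                )
            else:
                cells[(ri, j)] = Cell(
                    key1=rows[ri], value1=cols[j], status=CellStatus.VIRTUAL
                )
    return Sarm(rows=rows, cols=cols, cells=cells)


def gen_fragment_pairs(
    dataset: SyntheticDataset, role: str
) -> tuple[list[str], list[str]]:
    """(source, target) training pairs for one generator role.

    key2 pairs are identity (scaffold -> scaffold); value2 pairs map each
    scaffold to a substructure observed with it; value1 pairs map each
    core to a substituent observed with it.  Feeds the staged generation
    pipeline, where each generator is conditioned on the previous stage's
    output.
    """
    if role not in ("key2", "value2", "value1"):
        raise ContractError(f"unknown corpus role: {role!r}")
    index = build_compound_index(dataset.compounds)
    if role == "value1":
        pairs = [
            (k, e.value)
            for k in sorted(index.entries)
            for e in index.entries[k]
        ]
    else:
        core_index = fragment_cores(index)
        if role == "key2":
            pairs = [(k2, k2) for k2 in sorted(core_index) for _ in core_index[k2]]
        else:
            pairs = [
                (k2, v2) for k2 in sorted(core_index) for (v2, _) in core_index[k2]
            ]
    sources = [s for s, _ in pairs]
    targets = [t for _, t in pairs]
    return sources, targets
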