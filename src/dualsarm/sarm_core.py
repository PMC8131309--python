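"""SAR matrix construction and expansion.

A second fragmentation pass over the cores (key1 fragments) identifies
cores differing by a chemical change at a single site.  Each set of such
structurally analogous cores spans one SAR matrix (SARM): rows are cores,
columns are substituents, and every cell is a compound — existing (measured)
or virtual (an unexplored key/value combination).  Matrices can be expanded
with generator-proposed fragments, creating scored generated-virtual cells.
"""

from __future__ import annotations

import enum
import json
import logging
import statistics
from dataclasses import dataclass, field, replace

from rdkit import Chem

from .errors import ContractError, InvalidProductError
from .fragmentation import (
    DEFAULT_MAX_VALUE_ATOMS,
    IndexTable,
    _mol_from_smiles,
    attach,
    attach_at,
    canonicalize,
    cut_bond,
    eligible_bonds,
    heavy_atom_count,
)

logger = logging.getLogger(__name__)

#: canonical form of the hydrogen-as-substituent value2 fragment
HYDROGEN_VALUE = canonicalize("[*][H]")


def fragment_cores(
    index: IndexTable,
    include_hydrogen: bool = True,
    max_value2_atoms: int = DEFAULT_MAX_VALUE_ATOMS,
) -> dict[str, list[tuple[str, str]]]:
    """Single-cut every core of the index, yielding the second index table.

    Returns a mapping key2 -> [(value2, key1), ...].  The key2 scaffold is
    the piece holding the original attachment point (so it carries two);
    value2 is the distinguishing substructure.  With ``include_hydrogen``,
    every position of a core bearing a hydrogen also yields an entry with
    value2 = hydrogen, so unsubstituted and substituted analogs of one
    scaffold land in the same group.
    """
    if not index.entries:
        raise ContractError("empty index table")
    core_index: dict[str, list[tuple[str, str]]] = {}

    def add(key2: str, value2: str, key1: str) -> None:
        bucket = core_index.setdefault(key2, [])
        if (value2, key1) not in bucket:
            bucket.append((value2, key1))

    for key1 in sorted(index.entries):
        mol = _mol_from_smiles(key1)
        for bidx in eligible_bonds(mol):
            fa, fb = cut_bond(mol, bidx)
            # scaffold = piece with both attachment points
            if fa.count("*") == 2:
                key2, value2 = fa, fb
            elif fb.count("*") == 2:
                key2, value2 = fb, fa
            else:  # pragma: no cover - one piece always inherits the dummy
                continue
            if heavy_atom_count(value2) > max_value2_atoms:
                continue
            add(key2, value2, key1)
        if include_hydrogen:
            for key2 in _hydrogen_sites(mol):
                add(key2, HYDROGEN_VALUE, key1)
    return core_index


def _hydrogen_sites(core: Chem.Mol) -> list[str]:
    """key2 scaffolds formed by replacing one hydrogen of the core with an
    attachment point; symmetric positions are collapsed."""
    seen: set[str] = set()
    out: list[str] = []
    for atom in core.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() == 0:
            continue
        rw = Chem.RWMol(core)
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.AddBond(atom.GetIdx(), dummy, Chem.BondType.SINGLE)
        rw.GetAtomWithIdx(atom.GetIdx()).SetNumExplicitHs(
            max(0, atom.GetNumExplicitHs() - (0 if atom.GetNumImplicitHs() else 1))
        )
        try:
            m = rw.GetMol()
            Chem.SanitizeMol(m)
        except Exception:  # position cannot host a substituent
            continue
        smi = Chem.MolToSmiles(m)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out


@dataclass(frozen=True)
class CoreGroup:
    """Cores sharing one key2 scaffold, i.e. differing at a single site."""

    key2: str
    members: tuple[str, ...]  # key1 cores, deterministic order
    value2_of: dict[str, str] = field(hash=False, compare=False, default_factory=dict)


def group_analogous_cores(
    core_index: dict[str, list[tuple[str, str]]]
) -> list[CoreGroup]:
    """One group per key2 scaffold with >= 2 distinct member cores.

    A core may belong to several groups (one per key2 decomposition it
    admits); singleton scaffolds carry no structural relationship and are
    dropped.
    """
    groups = []
    for key2 in sorted(core_index):
        value2_of: dict[str, str] = {}
        for value2, key1 in core_index[key2]:
            value2_of.setdefault(key1, value2)
        if len(value2_of) < 2:
            continue
        groups.append(
            CoreGroup(
                key2=key2,
                members=tuple(sorted(value2_of)),
                value2_of=value2_of,
            )
        )
    return groups


class CellStatus(enum.Enum):
    EXISTING = "existing"
    VIRTUAL = "virtual"
    GENERATED = "generated-virtual"


@dataclass
class Cell:
    key1: str
    value1: str
    status: CellStatus
    compound_id: str | None = None
    potency: dict[str, float] = field(default_factory=dict)
    ll_score: float | None = None
    smiles: str | None = None  # realized molecule, set lazily for virtual cells
    valid: bool = True


@dataclass
class Sarm:
    """A SAR matrix: cores (rows) x substituents (cols), every cell defined."""

    rows: list[str]
    cols: list[str]
    cells: dict[tuple[int, int], Cell]
    group: CoreGroup | None = None
    provenance: str = "original"
    group_key2: str | None = None  # retained through serialization

    def __post_init__(self):
        if self.group is not None:
            self.group_key2 = self.group.key2

    def cell(self, i: int, j: int) -> Cell:
        return self.cells[(i, j)]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.rows), len(self.cols)

    def existing_cells(self) -> list[tuple[int, int]]:
        return sorted(
            ij for ij, c in self.cells.items() if c.status is CellStatus.EXISTING
        )

    def n_existing(self) -> int:
        return len(self.existing_cells())

    def measured(self, i: int, j: int, target: str) -> float | None:
        return self.cells[(i, j)].potency.get(target)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.rows,
                "cols": self.cols,
                "provenance": self.provenance,
                "group_key2": self.group_key2,
                "cells": [
                    {
                        "i": i,
                        "j": j,
                        "status": c.status.value,
                        "compound_id": c.compound_id,
                        "potency": c.potency,
                        "ll_score": c.ll_score,
                        "smiles": c.smiles,
                        "valid": c.valid,
                    }
                    for (i, j), c in sorted(self.cells.items())
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Sarm":
        d = json.loads(text)
        sarm = cls(
            rows=d["rows"], cols=d["cols"], cells={},
            provenance=d["provenance"], group_key2=d.get("group_key2"),
        )
        for rec in d["cells"]:
            i, j = rec["i"], rec["j"]
            sarm.cells[(i, j)] = Cell(
                key1=sarm.rows[i],
                value1=sarm.cols[j],
                status=CellStatus(rec["status"]),
                compound_id=rec["compound_id"],
                potency=rec["potency"],
                ll_score=rec["ll_score"],
                smiles=rec["smiles"],
                valid=rec["valid"],
            )
        return sarm

    def write_grid_csv(self, path, target: str | None = None) -> None:
        """CSV grid: one row per core; cells show compound id or status."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["core"] + self.cols)
            for i, row in enumerate(self.rows):
                line = [row]
                for j in range(len(self.cols)):
                    c = self.cells[(i, j)]
                    if c.status is CellStatus.EXISTING:
                        val = (
                            f"{c.potency.get(target, float('nan')):.2f}"
                            if target
                            else c.compound_id
                        )
                    else:
                        val = c.status.value
                    line.append(val)
                w.writerow(line)


def build_sarms(
    groups: list[CoreGroup],
    index: IndexTable,
    min_compounds: int = 2,
) -> list[Sarm]:
    """Construct one SARM per core group.

    Rows are the member cores, columns the union of substituents observed
    with any member.  Cells backed by an indexed compound become existing
    cells (duplicate measurements aggregated by median pIC50); all other
    combinations are virtual.  Groups with fewer than ``min_compounds``
    existing compounds carry no SAR information and are skipped.
    """
    sarms = []
    for group in groups:
        observed: dict[tuple[str, str], list[str]] = {}
        for core in group.members:
            for entry in index.entries.get(core, []):
                observed.setdefault((core, entry.value), []).append(entry.parent_id)
        if len(observed) < min_compounds:
            logger.info(
                "group %s skipped: only %d compounds", group.key2, len(observed)
            )
            continue
        rows = _ordered(group.members, [k for k, _ in observed])
        cols = _ordered(
            sorted({v for _, v in observed}), [v for _, v in observed]
        )
        cells: dict[tuple[int, int], Cell] = {}
        for i, core in enumerate(rows):
            for j, sub in enumerate(cols):
                parents = observed.get((core, sub))
                if parents:
                    pot = _aggregate_potency(parents, index)
                    cells[(i, j)] = Cell(
                        key1=core,
                        value1=sub,
                        status=CellStatus.EXISTING,
                        compound_id=sorted(parents)[0],
                        potency=pot,
                        smiles=index.compounds[sorted(parents)[0]].smiles,
                    )
                else:
                    cells[(i, j)] = Cell(
                        key1=core, value1=sub, status=CellStatus.VIRTUAL
                    )
        sarms.append(Sarm(rows=rows, cols=cols, cells=cells, group=group))
    return sarms


def _ordered(items, observed_keys) -> list[str]:
    """Descending count of existing cells, then canonical SMILES."""
    counts: dict[str, int] = {}
    for k in observed_keys:
        counts[k] = counts.get(k, 0) + 1
    return sorted(set(items), key=lambda s: (-counts.get(s, 0), s))


def _aggregate_potency(parents: list[str], index: IndexTable) -> dict[str, float]:
    merged: dict[str, list[float]] = {}
    for pid in parents:
        for target, values in index.potencies.get(pid, {}).items():
            merged.setdefault(target, []).extend(values)
    return {t: statistics.median(v) for t, v in merged.items()}


def enumerate_virtual_cells(sarm: Sarm) -> list[Cell]:
    """Realize every virtual cell's molecule via attach.

    Chemically invalid combinations are flagged (``valid = False``) and
    retained in the matrix but excluded from the returned candidate list.
    """
    out = []
    for ij in sorted(sarm.cells):
        cell = sarm.cells[ij]
        if cell.status is CellStatus.EXISTING:
            continue
        if cell.smiles is None and cell.valid:
            try:
                cell.smiles = attach(cell.key1, cell.value1)
            except InvalidProductError:
                cell.valid = False
                logger.warning(
                    "invalid combination %s + %s flagged", cell.key1, cell.value1
                )
        if cell.valid:
            out.append(cell)
    return out


def _fragment_score(frag) -> tuple[str, float]:
    """Accept a ScoredFragment or a plain (smiles, score) pair."""
    if hasattr(frag, "smiles"):
        return canonicalize(frag.smiles), float(frag.ll_score)
    smiles, score = frag
    return canonicalize(smiles), float(score)


def expand_sarm(sarm: Sarm, new_keys, new_values) -> Sarm:
    """Append generated fragments as new rows/cols; score the new cells.

    Each newly created (row, col) combination becomes a generated-virtual
    cell whose log-likelihood score is the sum of its fragments' scores
    (original, un-scored fragments contribute 0).  Existing cell contents
    are copied unchanged; duplicates of current rows/cols are dropped with
    a log entry.
    """
    row_scores = {r: 0.0 for r in sarm.rows}
    col_scores = {c: 0.0 for c in sarm.cols}
    rows = list(sarm.rows)
    cols = list(sarm.cols)
    for frag in new_keys:
        smi, score = _fragment_score(frag)
        if smi in row_scores:
            logger.info("duplicate key fragment %s dropped", smi)
            continue
        row_scores[smi] = score
        rows.append(smi)
    for frag in new_values:
        smi, score = _fragment_score(frag)
        if smi in col_scores:
            logger.info("duplicate value fragment %s dropped", smi)
            continue
        col_scores[smi] = score
        cols.append(smi)

    expanded = len(rows) > len(sarm.rows) or len(cols) > len(sarm.cols)
    cells: dict[tuple[int, int], Cell] = {}
    for i, core in enumerate(rows):
        for j, sub in enumerate(cols):
            if i < len(sarm.rows) and j < len(sarm.cols):
                cells[(i, j)] = replace(sarm.cells[(i, j)])
            else:
                cells[(i, j)] = Cell(
                    key1=core,
                    value1=sub,
                    status=CellStatus.GENERATED,
                    ll_score=row_scores[core] + col_scores[sub],
                )
    return Sarm(
        rows=rows,
        cols=cols,
        cells=cells,
        group=sarm.group,
        provenance="expanded" if expanded else sarm.provenance,
        group_key2=sarm.group_key2,
    )
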