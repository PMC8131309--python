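"""First-step compound fragmentation: single cuts of exocyclic single bonds.

Every compound is cut once at every eligible bond (a single, acyclic bond
between two heavy atoms), producing a *key* (the core, the larger fragment)
and a *value* (the substituent).  Keys and values carry exactly one
attachment point, written as a wildcard atom ``*``.  All (key, value) pairs
of a data set are aggregated in an :class:`IndexTable`, the input to SAR
matrix construction.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger

from .errors import ContractError, InvalidProductError, ParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: default cap on substituent size, in heavy atoms
DEFAULT_MAX_VALUE_ATOMS = 13


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ParseError(
            f"multi-component input rejected (strip salts first): {smiles!r}"
        )
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of a single-component molecule or fragment.

    Idempotent and deterministic.  Attachment points (``*`` / ``[*]``) are
    permitted; multi-component inputs (salts) are rejected.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def heavy_atom_count(smiles_or_mol) -> int:
    """Number of non-hydrogen, non-wildcard atoms."""
    mol = (
        smiles_or_mol
        if isinstance(smiles_or_mol, Chem.Mol)
        else _mol_from_smiles(smiles_or_mol)
    )
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def attachment_points(smiles_or_mol) -> int:
    """Number of wildcard (attachment-point) atoms in a fragment."""
    mol = (
        smiles_or_mol
        if isinstance(smiles_or_mol, Chem.Mol)
        else _mol_from_smiles(smiles_or_mol)
    )
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


@dataclass(frozen=True)
class Molecule:
    """A canonicalized input compound."""

    id: str
    smiles: str
    heavy_atoms: int

    @classmethod
    def from_smiles(cls, cid: str, smiles: str) -> "Molecule":
        can = canonicalize(smiles)
        return cls(id=cid, smiles=can, heavy_atoms=heavy_atom_count(can))


@dataclass(frozen=True)
class FragmentPair:
    """One single-cut decomposition of a parent compound."""

    key: str  # core fragment, one attachment point
    value: str  # substituent fragment, one attachment point
    parent_id: str
    cut_bond_index: int


def eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of single, acyclic bonds between two heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() > 1 and b.GetAtomicNum() > 1:
            out.append(bond.GetIdx())
    return out


def cut_bond(mol: Chem.Mol, bond_index: int) -> tuple[str, str]:
    """Cut one bond, returning the two fragments as canonical SMILES.

    Each fragment gains an unlabeled wildcard atom at the cut position.
    The order of the returned pair is arbitrary; callers assign roles.
    """
    pieces = Chem.FragmentOnBonds(
        mol, [bond_index], addDummies=True, dummyLabels=[(0, 0)]
    )
    frags = Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=True)
    if len(frags) != 2:  # pragma: no cover - acyclic cut always splits in two
        raise InvalidProductError(f"cut of bond {bond_index} did not yield 2 pieces")
    return Chem.MolToSmiles(frags[0]), Chem.MolToSmiles(frags[1])


def enumerate_single_cuts(
    mol: Molecule,
    max_value_atoms: int = DEFAULT_MAX_VALUE_ATOMS,
    max_value_fraction: float = 0.5,
) -> list[FragmentPair]:
    """All single-cut (key, value) decompositions of one compound.

    The key is the fragment with more heavy atoms (ties broken by
    lexicographic canonical SMILES); the value must not exceed
    ``max_value_atoms`` heavy atoms nor ``max_value_fraction`` of the
    parent's heavy atoms.  Output order follows the cut bond index.
    """
    rdmol = _mol_from_smiles(mol.smiles)
    pairs: list[FragmentPair] = []
    for bidx in eligible_bonds(rdmol):
        fa, fb = cut_bond(rdmol, bidx)
        ha, hb = heavy_atom_count(fa), heavy_atom_count(fb)
        if ha > hb or (ha == hb and fa <= fb):
            key, value, hv = fa, fb, hb
        else:
            key, value, hv = fb, fa, ha
        if hv > max_value_atoms or hv > max_value_fraction * mol.heavy_atoms:
            continue
        pairs.append(
            FragmentPair(key=key, value=value, parent_id=mol.id, cut_bond_index=bidx)
        )
    return pairs


def attach(key: str, value: str) -> str:
    """Bond two one-attachment-point fragments into a canonical molecule.

    The inverse of a single cut: the wildcard atoms are removed and their
    heavy-atom neighbors joined by a single bond.  Explicit hydrogens
    (from a hydrogen-as-substituent value) collapse into implicit ones.
    """
    for name, frag in (("key", key), ("value", value)):
        n = attachment_points(frag)
        if n != 1:
            raise ContractError(
                f"{name} fragment must have exactly 1 attachment point, got {n}: {frag!r}"
            )
    return _join(_mol_from_smiles(key), _mol_from_smiles(value))


def attach_at(scaffold: str, value: str, point: int) -> str:
    """Bond a one-point ``value`` to attachment point ``point`` of a
    multi-point ``scaffold`` fragment, keeping the other points intact.

    Points are numbered 0..k-1 in atom-index order of the canonical
    scaffold.  Used to realize a key1 core from a key2 scaffold and a
    value2 substructure.
    """
    smol = _mol_from_smiles(scaffold)
    dummies = [a.GetIdx() for a in smol.GetAtoms() if a.GetAtomicNum() == 0]
    if not 0 <= point < len(dummies):
        raise ContractError(
            f"scaffold has {len(dummies)} attachment points; point={point} out of range"
        )
    if attachment_points(value) != 1:
        raise ContractError(f"value must have exactly 1 attachment point: {value!r}")
    return _join(smol, _mol_from_smiles(value), keep_dummy=dummies[point])


def _join(mol_a: Chem.Mol, mol_b: Chem.Mol, keep_dummy: int | None = None) -> str:
    """Join the selected dummy of mol_a to the single dummy of mol_b."""
    combo = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    na = mol_a.GetNumAtoms()
    da = keep_dummy if keep_dummy is not None else next(
        a.GetIdx() for a in mol_a.GetAtoms() if a.GetAtomicNum() == 0
    )
    db = na + next(a.GetIdx() for a in mol_b.GetAtoms() if a.GetAtomicNum() == 0)
    nbrs_a = combo.GetAtomWithIdx(da).GetNeighbors()
    nbrs_b = combo.GetAtomWithIdx(db).GetNeighbors()
    if not nbrs_a or not nbrs_b:
        raise InvalidProductError(
            "attachment point has no neighbor atom (bare-wildcard fragment)"
        )
    nbr_a = nbrs_a[0].GetIdx()
    nbr_b = nbrs_b[0].GetIdx()
    combo.AddBond(nbr_a, nbr_b, Chem.BondType.SINGLE)
    for idx in sorted((da, db), reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
        product = Chem.RemoveHs(product)
    except Exception as exc:
        raise InvalidProductError(
            f"recombination produced an invalid molecule: {exc}"
        ) from exc
    return Chem.MolToSmiles(product)


@dataclass(frozen=True)
class IndexEntry:
    value: str
    parent_id: str


@dataclass
class IndexTable:
    """Aggregated (key, value) pairs of a compound set, plus potency records.

    ``entries`` maps each key SMILES to the list of (value, parent_id)
    entries observed for it; ``potencies`` maps compound id to a
    target -> [pIC50, ...] record; ``unfragmentable`` lists compounds
    without any eligible cut (retained, but excluded from matrices).
    """

    entries: dict[str, list[IndexEntry]] = field(default_factory=dict)
    compounds: dict[str, Molecule] = field(default_factory=dict)
    potencies: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    unfragmentable: list[str] = field(default_factory=list)

    def analog_series(self) -> dict[str, list[IndexEntry]]:
        """Keys observed with >= 2 distinct values (true analog series)."""
        return {
            k: v
            for k, v in self.entries.items()
            if len({e.value for e in v}) >= 2
        }

    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_json(self) -> str:
        payload = {
            "entries": {
                k: [{"value": e.value, "parent_id": e.parent_id} for e in v]
                for k, v in sorted(self.entries.items())
            },
            "compounds": {
                cid: {"smiles": m.smiles, "heavy_atoms": m.heavy_atoms}
                for cid, m in sorted(self.compounds.items())
            },
            "potencies": {k: self.potencies[k] for k in sorted(self.potencies)},
            "unfragmentable": sorted(self.unfragmentable),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IndexTable":
        payload = json.loads(text)
        table = cls()
        table.entries = {
            k: [IndexEntry(e["value"], e["parent_id"]) for e in v]
            for k, v in payload["entries"].items()
        }
        table.compounds = {
            cid: Molecule(id=cid, smiles=d["smiles"], heavy_atoms=d["heavy_atoms"])
            for cid, d in payload["compounds"].items()
        }
        table.potencies = payload["potencies"]
        table.unfragmentable = list(payload["unfragmentable"])
        return table

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value", "parent_id"])
            for k in sorted(self.entries):
                for e in self.entries[k]:
                    writer.writerow([k, e.value, e.parent_id])


def build_compound_index(
    compounds: list[Molecule],
    potencies: dict[str, dict[str, list[float]]] | None = None,
    max_value_atoms: int = DEFAULT_MAX_VALUE_ATOMS,
) -> IndexTable:
    """Fragment every compound and aggregate all pairs in an index table.

    ``potencies`` maps compound id -> {target: [pIC50, ...]}.  Duplicate
    compound ids are an error; compounds without an eligible cut are logged
    and recorded as unfragmentable.
    """
    table = IndexTable(potencies=dict(potencies or {}))
    for mol in compounds:
        if mol.id in table.compounds:
            raise ContractError(f"duplicate compound id: {mol.id!r}")
        table.compounds[mol.id] = mol
        pairs = enumerate_single_cuts(mol, max_value_atoms=max_value_atoms)
        if not pairs:
            logger.warning("compound %s (%s) has no eligible cut", mol.id, mol.smiles)
            table.unfragmentable.append(mol.id)
            continue
        for p in pairs:
            bucket = table.entries.setdefault(p.key, [])
            if not any(e.value == p.value and e.parent_id == p.parent_id for e in bucket):
                bucket.append(IndexEntry(value=p.value, parent_id=p.parent_id))
    return table
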