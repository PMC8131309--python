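"""Core grouping, SAR matrix construction, and matrix expansion."""

import copy

import pytest

from dualsarm.fragmentation import (
    IndexEntry,
    IndexTable,
    Molecule,
    attach,
    attach_at,
    build_compound_index,
    canonicalize,
)
from dualsarm.sarm_core import (
    HYDROGEN_VALUE,
    CellStatus,
    Sarm,
    build_sarms,
    enumerate_virtual_cells,
    expand_sarm,
    fragment_cores,
    group_analogous_cores,
)
from dualsarm.synthetic_data import (
    SCAFFOLD_FAMILIES,
    SUBSTITUENTS,
    SyntheticSpec,
    gen_analog_series,
)


def index_of_cores(cores: list[str]) -> IndexTable:
    """Minimal index whose keys are the given cores (one value each)."""
    table = IndexTable()
    for n, core in enumerate(cores):
        table.entries[canonicalize(core)] = [IndexEntry("[*]C", f"p{n}")]
    return table


class TestFragmentCores:
    def test_aryl_fluoride_cut(self):
        core_index = fragment_cores(index_of_cores(["[*]c1ccc(F)cc1"]))
        key2 = canonicalize("[*]c1ccc([*])cc1")
        assert (canonicalize("[*]F"), canonicalize("[*]c1ccc(F)cc1")) in core_index[key2]

    def test_hydrogen_substitution_convention(self):
        core_index = fragment_cores(index_of_cores(["[*]c1ccccc1"]))
        key2 = canonicalize("[*]c1ccc([*])cc1")
        assert (HYDROGEN_VALUE, canonicalize("[*]c1ccccc1")) in core_index[key2]

    def test_methyl_core_has_no_cut(self):
        core_index = fragment_cores(
            index_of_cores(["[*]C"]), include_hydrogen=False
        )
        assert core_index == {}

    def test_key2_reattachment_reconstructs_core(self):
        cores = ["[*]c1ccc(F)cc1", "[*]Cc1ccc(Cl)cc1", "[*]C1CCC(O)CC1"]
        core_index = fragment_cores(index_of_cores(cores))
        for key2, pairs in core_index.items():
            for value2, key1 in pairs:
                rebuilt = {attach_at(key2, value2, 0), attach_at(key2, value2, 1)}
                assert key1 in rebuilt


class TestGroupAnalogousCores:
    def test_halophenyl_family_forms_one_group(self):
        cores = ["[*]c1ccccc1", "[*]c1ccc(F)cc1", "[*]c1ccc(Cl)cc1"]
        groups = group_analogous_cores(fragment_cores(index_of_cores(cores)))
        key2 = canonicalize("[*]c1ccc([*])cc1")
        target = [g for g in groups if g.key2 == key2]
        assert len(target) == 1
        assert set(target[0].members) == {canonicalize(c) for c in cores}
        assert set(target[0].value2_of.values()) == {
            HYDROGEN_VALUE, canonicalize("[*]F"), canonicalize("[*]Cl")
        }

    def test_unrelated_cores_do_not_group(self):
        groups = group_analogous_cores(
            fragment_cores(
                index_of_cores(["[*]c1ccccc1", "[*]CC1CCCCC1"]),
                include_hydrogen=False,
            )
        )
        assert groups == []

    def test_core_may_belong_to_two_groups(self):
        cores = ["[*]Cc1ccc(F)cc1", "[*]Cc1ccccc1", "[*]CC"]
        groups = group_analogous_cores(fragment_cores(index_of_cores(cores)))
        by_key2 = {g.key2: set(g.members) for g in groups}
        shared = canonicalize("[*]Cc1ccccc1")
        holding = [k for k, members in by_key2.items() if shared in members]
        assert len(holding) >= 2

    def test_group_reconstruction_invariant(self):
        cores = [fam[i] for fam in SCAFFOLD_FAMILIES for i in range(3)]
        for g in group_analogous_cores(fragment_cores(index_of_cores(cores))):
            for member in g.members:
                v2 = g.value2_of[member]
                assert member in {attach_at(g.key2, v2, 0), attach_at(g.key2, v2, 1)}

    def test_scaffold_families_never_merge(self):
        """Cores from disjoint ring families stay in disjoint groups."""
        spec = SyntheticSpec(n_scaffolds=20, n_substituents=8,
                             fill_fraction=0.5, seed=4)
        ds = gen_analog_series(spec)
        family_of = {
            canonicalize(s): fi
            for fi, fam in enumerate(SCAFFOLD_FAMILIES)
            for s in fam
        }
        full = build_compound_index(ds.compounds)
        series = IndexTable(
            entries={k: v for k, v in full.entries.items() if k in family_of},
            compounds=full.compounds,
        )
        groups = group_analogous_cores(fragment_cores(series))
        assert groups
        for g in groups:
            families = {family_of[m] for m in g.members}
            assert len(families) == 1, g.key2


def build_4x5_sarm(seed: int = 3):
    """A 4-core x 5-substituent matrix with 10 measured compounds, built
    through the real fragmentation/grouping/construction pipeline."""
    spec = SyntheticSpec(n_scaffolds=4, n_substituents=5,
                         fill_fraction=0.5, seed=seed)
    ds = gen_analog_series(spec)
    full = build_compound_index(ds.compounds, potencies=ds.potency_records())
    scaffolds = set(ds.truth.scaffolds)
    series = IndexTable(
        entries={k: v for k, v in full.entries.items() if k in scaffolds},
        compounds=full.compounds,
        potencies=full.potencies,
    )
    groups = group_analogous_cores(fragment_cores(series))
    sarms = [s for s in build_sarms(groups, series) if s.shape == (4, 5)]
    assert len(sarms) == 1
    return sarms[0], ds


class TestBuildSarms:
    def test_4x5_matrix_with_10_compounds(self):
        sarm, _ = build_4x5_sarm()
        assert sarm.shape == (4, 5)
        assert len(sarm.cells) == 20
        assert sarm.n_existing() == 10

    def test_matrix_is_complete(self):
        sarm, _ = build_4x5_sarm()
        assert set(sarm.cells) == {
            (i, j) for i in range(4) for j in range(5)
        }

    def test_existing_cells_reconstruct_their_compound(self):
        sarm, _ = build_4x5_sarm()
        for (i, j) in sarm.existing_cells():
            cell = sarm.cell(i, j)
            assert attach(sarm.rows[i], sarm.cols[j]) == cell.smiles

    def test_existing_cells_carry_both_target_potencies(self):
        sarm, ds = build_4x5_sarm()
        for (i, j) in sarm.existing_cells():
            assert set(sarm.cell(i, j).potency) == set(ds.spec.targets)

    def test_single_compound_group_is_skipped(self):
        table = IndexTable()
        table.entries = {
            canonicalize("[*]c1ccccc1"): [IndexEntry(canonicalize("[*]C"), "a")],
            canonicalize("[*]c1ccc(F)cc1"): [],
        }
        table.compounds = {"a": Molecule.from_smiles("a", "Cc1ccccc1")}
        groups = group_analogous_cores(fragment_cores(table))
        assert build_sarms(groups, table) == []

    def test_duplicate_measurements_aggregate_by_median(self):
        mols = [
            Molecule.from_smiles("t1", "Cc1ccccc1"),
            Molecule.from_smiles("e1", "CCc1ccccc1"),
            Molecule.from_smiles("f1", "Cc1ccc(F)cc1"),
        ]
        pot = {"t1": {"T": [5.0, 9.0, 6.0]}, "e1": {"T": [7.0]}, "f1": {"T": [6.5]}}
        index = build_compound_index(mols, potencies=pot)
        groups = group_analogous_cores(fragment_cores(index))
        sarms = build_sarms(groups, index)
        toluene_cells = [
            c for s in sarms for c in s.cells.values()
            if c.compound_id == "t1" and c.status is CellStatus.EXISTING
        ]
        assert toluene_cells and all(c.potency["T"] == 6.0 for c in toluene_cells)


class TestVirtualCells:
    def test_virtual_count_identity(self):
        sarm, _ = build_4x5_sarm()
        virtual = enumerate_virtual_cells(sarm)
        assert len(virtual) == 4 * 5 - sarm.n_existing() == 10

    def test_virtual_cells_realize_canonical_smiles(self):
        sarm, _ = build_4x5_sarm()
        for cell in enumerate_virtual_cells(sarm):
            assert cell.smiles == canonicalize(cell.smiles)
            assert cell.smiles == attach(cell.key1, cell.value1)

    def test_full_matrix_has_no_virtual_cells(self):
        sarm, _ = build_4x5_sarm()
        for c in sarm.cells.values():
            c.status = CellStatus.EXISTING
            c.potency = {"T": 5.0}
        assert enumerate_virtual_cells(sarm) == []


def fresh_fragments():
    from dualsarm.synthetic_data import SCAFFOLDS

    keys = [(canonicalize(s), -1.0) for s in SCAFFOLDS[5:17]]
    values = [(canonicalize(s), -0.5) for s in SUBSTITUENTS[5:14]]
    return keys, values


class TestExpandSarm:
    def test_expansion_accounting_16x14_204(self):
        sarm, _ = build_4x5_sarm()
        keys, values = fresh_fragments()
        expanded = expand_sarm(sarm, keys, values)
        assert expanded.shape == (16, 14)
        assert expanded.provenance == "expanded"
        generated = [
            c for c in expanded.cells.values() if c.status is CellStatus.GENERATED
        ]
        assert len(generated) == 204 == 16 * 14 - 4 * 5

    def test_generated_cells_score_is_fragment_sum(self):
        sarm, _ = build_4x5_sarm()
        keys, values = fresh_fragments()
        expanded = expand_sarm(sarm, keys, values)
        key_smiles = {k for k, _ in keys}
        for c in expanded.cells.values():
            if c.status is CellStatus.GENERATED:
                expect = (-1.0 if c.key1 in key_smiles else 0.0) + (
                    -0.5 if c.value1 not in sarm.cols else 0.0
                )
                assert c.ll_score == pytest.approx(expect)

    def test_existing_cells_conserved_bit_identical(self):
        sarm, _ = build_4x5_sarm()
        before = copy.deepcopy(
            {ij: sarm.cells[ij] for ij in sarm.existing_cells()}
        )
        keys, values = fresh_fragments()
        expanded = expand_sarm(sarm, keys, values)
        for ij, cell in before.items():
            assert expanded.cells[ij] == cell

    def test_empty_expansion_is_identity(self):
        sarm, _ = build_4x5_sarm()
        same = expand_sarm(sarm, [], [])
        assert same.shape == sarm.shape
        assert same.provenance == sarm.provenance == "original"
        assert same.cells == sarm.cells

    def test_duplicate_fragments_are_dropped(self):
        sarm, _ = build_4x5_sarm()
        dup_key = (sarm.rows[0], -2.0)
        expanded = expand_sarm(sarm, [dup_key], [])
        assert expanded.shape == sarm.shape

    def test_json_round_trip(self):
        sarm, _ = build_4x5_sarm()
        keys, values = fresh_fragments()
        expanded = expand_sarm(sarm, keys, values)
        text = expanded.to_json()
        assert Sarm.from_json(text).to_json() == text
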