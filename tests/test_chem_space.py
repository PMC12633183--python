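"""Reaction-space model, MEL construction and provenance-tracked enumeration."""

import json

import pytest
from rdkit import Chem

from synthscreen.chem_space import (
    CAP_ISOTOPE,
    IntegrityError,
    LibraryError,
    ChemistryError,
    ReactionLibrary,
    ReactionScaffold,
    Synthon,
    build_mel,
    count_full_space,
    enumerate_at,
    enumerate_full_space,
    parse_reaction_library,
    spawn_count,
    write_reaction_library,
)
from synthscreen.fixtures import LibrarySpec, make_toy_library

from conftest import exhaustive_products


def _lib(synthons, scaffolds):
    return ReactionLibrary(
        scaffolds=scaffolds, synthons={s.id: s for s in synthons}
    ).validate()


def _simple_two_component(n1, n2):
    """2-component amide with alkyl chains of distinct lengths per point."""
    synthons = []
    lists = {"1": [], "2": []}
    for point, n in (("1", n1), ("2", n2)):
        for k in range(n):
            sid = f"s{point}_{k}"
            synthons.append(
                Synthon(
                    id=sid,
                    smiles=f"[*:{point}]" + "C" * (k + 1),
                    compatible_points=(point,),
                )
            )
            lists[point].append(sid)
    scaffold = ReactionScaffold(
        reaction_id="RX",
        n_components=2,
        core_smiles="[*:1]C(=O)N[*:2]",
        points=(("1", "aliphatic"), ("2", "aromatic")),
        synthon_lists={k: tuple(v) for k, v in lists.items()},
    )
    return _lib(synthons, [scaffold])


class TestLibraryParsing:
    def test_round_trip_preserves_structure(self, mixed_library, tmp_path):
        path = tmp_path / "lib.json"
        write_reaction_library(mixed_library, path)
        lib2 = parse_reaction_library(path)
        assert len(lib2.scaffolds) == len(mixed_library.scaffolds)
        assert set(lib2.synthons) == set(mixed_library.synthons)
        for a, b in zip(mixed_library.scaffolds, lib2.scaffolds):
            assert a == b
        assert count_full_space(lib2) == count_full_space(mixed_library)

    def test_dangling_synthon_reference_fails(self, mixed_library, tmp_path):
        path = tmp_path / "lib.json"
        write_reaction_library(mixed_library, path)
        data = json.loads(path.read_text())
        data["reactions"][0]["synthon_lists"]["1"][0] = "S999"
        path.write_text(json.dumps(data))
        with pytest.raises(IntegrityError, match="S999"):
            parse_reaction_library(path)

    def test_duplicate_synthon_id_fails(self, mixed_library, tmp_path):
        path = tmp_path / "lib.json"
        write_reaction_library(mixed_library, path)
        data = json.loads(path.read_text())
        data["synthons"].append(dict(data["synthons"][0]))
        path.write_text(json.dumps(data))
        with pytest.raises(IntegrityError, match="duplicate"):
            parse_reaction_library(path)

    def test_malformed_smiles_names_the_record(self, mixed_library, tmp_path):
        path = tmp_path / "lib.json"
        write_reaction_library(mixed_library, path)
        data = json.loads(path.read_text())
        bad_id = data["synthons"][0]["id"]
        data["synthons"][0]["smiles"] = "C((C"
        path.write_text(json.dumps(data))
        with pytest.raises(LibraryError, match=bad_id):
            parse_reaction_library(path)

    def test_bridge_synthon_with_one_marker_fails(self):
        synthons = [
            Synthon(id="t1", smiles="[*:1]CC", compatible_points=("1",)),
            Synthon(id="t2", smiles="[*:2]CO", compatible_points=("2",)),
            Synthon(id="b1", smiles="[*:1]CC", kind="bridge", compatible_points=("B",)),
        ]
        scaffold = ReactionScaffold(
            reaction_id="RB",
            n_components=3,
            core_smiles="",
            points=(("1", "aliphatic"), ("B", "aliphatic"), ("2", "aliphatic")),
            synthon_lists={"1": ("t1",), "B": ("b1",), "2": ("t2",)},
            is_bridge=True,
        )
        with pytest.raises(LibraryError, match="marker"):
            _lib(synthons, [scaffold])


class TestCountFullSpace:
    def test_product_rule_over_reactions(self):
        lib = _simple_two_component(10, 20)
        assert count_full_space(lib) == 200

    def test_single_combination(self):
        lib = _simple_two_component(1, 1)
        assert count_full_space(lib) == 1

    def test_empty_synthon_list_is_degenerate(self):
        lib = _simple_two_component(2, 2)
        sc = lib.scaffolds[0]
        lib.scaffolds[0] = ReactionScaffold(
            reaction_id=sc.reaction_id,
            n_components=sc.n_components,
            core_smiles=sc.core_smiles,
            points=sc.points,
            synthon_lists={"1": sc.synthon_lists["1"], "2": ()},
        )
        with pytest.raises(LibraryError, match="degenerate"):
            count_full_space(lib)

    def test_matches_brute_force_enumeration(self, mixed_library):
        assert count_full_space(mixed_library) == len(
            enumerate_full_space(mixed_library)
        )


class TestBuildMel:
    def test_one_fragment_per_point_synthon_pair(self):
        lib = _simple_two_component(10, 20)
        assert len(build_mel(lib)) == 30

    def test_bridge_synthons_excluded_from_mel(self):
        lib = make_toy_library(
            LibrarySpec(two_component=(), three_component=(), bridge=((6, 4, 8),))
        )
        mel = build_mel(lib)
        assert len(mel) == 14  # 6 + 8 terminals; 4 bridges not represented
        assert count_full_space(lib) == 6 * 4 * 8
        # every bridge MEL carries exactly one methyl cap at the junction
        for frag in mel:
            assert [c.cap_type for c in frag.cap_atoms.values()] == ["methyl"]

    def test_cap_chemistry_selects_cap_group(self):
        lib = _simple_two_component(2, 2)
        mel = build_mel(lib)
        by_point = {}
        for frag in mel:
            cap = next(iter(frag.cap_atoms.values()))
            by_point.setdefault(frag.enumerated_point, set()).add(cap.cap_type)
        # enumerating point 1 leaves the aromatic point 2 capped and vice versa
        assert by_point == {"1": {"phenyl"}, "2": {"methyl"}}
        for frag in mel:
            cap = next(iter(frag.cap_atoms.values()))
            atom = frag.mol.GetAtomWithIdx(cap.atom_index)
            assert atom.GetIsotope() == CAP_ISOTOPE[cap.cap_type]

    def test_mel_size_scales_with_sum_not_product(self, mixed_library):
        total_list_sizes = sum(
            len(v) for sc in mixed_library.scaffolds for v in sc.synthon_lists.values()
        )
        assert len(build_mel(mixed_library)) <= total_list_sizes

    def test_provenance_covers_all_heavy_atoms(self, mixed_library):
        for frag in build_mel(mixed_library):
            assert set(frag.provenance) == set(range(frag.mol.GetNumAtoms()))


class TestEnumerateAt:
    def test_two_component_full_enumeration(self):
        lib = _simple_two_component(1, 20)
        frag = next(f for f in build_mel(lib) if f.enumerated_point == "1")
        products = enumerate_at(frag, "2", lib)
        assert len(products) == 20
        assert all(not p.remaining_caps for p in products)

    def test_bridge_insertion_adds_new_methyl_cap(self):
        lib = make_toy_library(
            LibrarySpec(two_component=(), three_component=(), bridge=((2, 4, 2),))
        )
        frag = build_mel(lib)[0]
        products = enumerate_at(frag, frag.remaining_caps[0], lib)
        assert len(products) == 4
        for p in products:
            assert len(p.cap_atoms) == 1
            assert next(iter(p.cap_atoms.values())).cap_type == "methyl"

    def test_uncapped_point_is_a_usage_error(self):
        lib = _simple_two_component(2, 2)
        frag = next(f for f in build_mel(lib) if f.enumerated_point == "1")
        with pytest.raises(ChemistryError, match="not capped"):
            enumerate_at(frag, "1", lib)

    def test_exhaustive_enumeration_reproduces_full_space(self, mixed_library):
        brute = {
            Chem.MolToSmiles(m) for _, m in enumerate_full_space(mixed_library)
        }
        assert exhaustive_products(mixed_library) == brute

    def test_provenance_injective_across_iterations(self, mixed_library):
        frag = next(
            f
            for f in build_mel(mixed_library)
            if mixed_library.scaffold(f.reaction_id).is_bridge
        )
        inter = enumerate_at(frag, frag.remaining_caps[0], mixed_library)[0]
        final = enumerate_at(inter, inter.remaining_caps[0], mixed_library)[0]
        noncap = [t for t in frag.provenance.values() if not t.startswith("cap:")]
        targets = list(final.provenance.values())
        for tag in noncap:
            assert targets.count(tag) == 1

    def test_spawn_count_products_of_remaining_points(self, mixed_library):
        bridge_sc = next(sc for sc in mixed_library.scaffolds if sc.is_bridge)
        frag = next(
            f for f in build_mel(mixed_library) if f.reaction_id == bridge_sc.reaction_id
        )
        sizes = {k: len(v) for k, v in bridge_sc.synthon_lists.items()}
        done = frag.enumerated_point
        expected = 1
        for k, v in sizes.items():
            if k != done:
                expected *= v
        assert spawn_count(frag, mixed_library) == expected
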