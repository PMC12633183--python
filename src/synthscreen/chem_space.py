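"""Combinatorial reaction space and minimal-enumeration-library construction.

A make-on-demand chemical space is defined by reactions rather than by an
explicit list of products: each reaction contributes a scaffold (a Markush
core with labelled attachment points) and, per attachment point, a list of
synthons (reactant building blocks).  The number of products is the product
of the synthon-list sizes, which grows combinatorially, while the number of
*fragments* needed to represent the space grows only with the sum of the
list sizes.

The minimal enumeration library (MEL) exploits this: for every attachment
point and every compatible synthon, one fragment is built with that synthon
attached and every other point capped by a minimal placeholder R-group —
methyl where the reaction chemistry is aliphatic, phenyl where it is
aromatic.  The cap's attachment carbon carries an isotope label (13 for
methyl, 14 for the phenyl ipso carbon) so downstream geometry code can find
it in a docked pose; the label is also recorded structurally so toolkit
isotope handling is not load-bearing.

Bridge-type 3-component reactions connect two terminal synthons through a
central bridge synthon that carries two attachment markers.  Bridge synthons
lack pharmacophores and dock unreliably, so they are excluded from the MEL:
bridge-reaction MEL fragments are terminal synthons with a methyl cap at the
future bridge junction, and the bridge synthon is inserted during the first
enumeration round with its far side capped by methyl.

Every heavy atom of every fragment carries a provenance tag (``core:i``,
``syn:<point>:<synthon-id>:i`` or ``cap:<point>:i``) so that atoms of a MEL
fragment can be located again inside any molecule enumerated from it.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger

# Sanitization probes on deliberately pathological inputs are part of normal
# operation; RDKit's own error stream would drown the real log.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

log = logging.getLogger(__name__)

ORIGIN_PROP = "ssOrigin"
CAP_POINT_PROP = "ssCapPoint"
CAP_TYPE_PROP = "ssCapType"
CAP_MAP_PROP = "ssCapMap"

#: isotope mass label on the cap attachment carbon, by cap type
CAP_ISOTOPE = {"methyl": 13, "phenyl": 14}
#: cap group implied by the reaction chemistry of an attachment point
CAP_FOR_CHEMISTRY = {"aliphatic": "methyl", "aromatic": "phenyl"}


class LibraryError(ValueError):
    """Malformed reaction-library input (bad SMILES, bad schema)."""


class IntegrityError(LibraryError):
    """Cross-reference violations: dangling or duplicate identifiers."""


class ChemistryError(ValueError):
    """A structure operation produced an invalid molecule."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Synthon:
    """One reactant building block.

    ``smiles`` must contain exactly one attachment marker (``[*:n]`` dummy
    atom) for a terminal synthon and exactly two for a bridge synthon.
    """

    id: str
    smiles: str
    kind: str = "terminal"  # terminal | bridge
    compatible_points: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("terminal", "bridge"):
            raise LibraryError(f"synthon {self.id!r}: unknown kind {self.kind!r}")

    @property
    def n_markers_required(self) -> int:
        return 2 if self.kind == "bridge" else 1


@dataclass(frozen=True)
class ReactionScaffold:
    """A reaction's Markush core plus per-point synthon lists.

    ``points`` is the ordered list of ``(label, cap_chemistry)`` pairs.
    Labels of points that appear in SMILES markers must parse as integers
    (marker ``[*:k]`` belongs to point label ``str(k)``).  For bridge
    reactions ``core_smiles`` is empty and ``points`` holds the two terminal
    points plus the bridge slot (the point whose synthons are bridges).
    """

    reaction_id: str
    n_components: int
    core_smiles: str
    points: tuple[tuple[str, str], ...]
    synthon_lists: Mapping[str, tuple[str, ...]]
    is_bridge: bool = False

    @property
    def point_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.points)

    def cap_chemistry(self, label: str) -> str:
        for plabel, chem in self.points:
            if plabel == label:
                return chem
        raise KeyError(label)


@dataclass
class ReactionLibrary:
    """Validated collection of scaffolds and an id-indexed synthon store."""

    scaffolds: list[ReactionScaffold]
    synthons: dict[str, Synthon]
    _bridge_slots: dict[str, str] = field(default_factory=dict, repr=False)

    def scaffold(self, reaction_id: str) -> ReactionScaffold:
        for sc in self.scaffolds:
            if sc.reaction_id == reaction_id:
                return sc
        raise KeyError(reaction_id)

    def bridge_slot(self, reaction_id: str) -> str | None:
        return self._bridge_slots.get(reaction_id)

    def validate(self) -> "ReactionLibrary":
        seen_rids: set[str] = set()
        for sid, syn in self.synthons.items():
            if sid != syn.id:
                raise IntegrityError(f"synthon store key {sid!r} != id {syn.id!r}")
            mol = _parse_smiles(syn.smiles, what=f"synthon {sid!r}")
            markers = _marker_map_nums(mol, what=f"synthon {sid!r}")
            if len(markers) != syn.n_markers_required:
                raise LibraryError(
                    f"synthon {sid!r} ({syn.kind}) has {len(markers)} attachment "
                    f"marker(s), expected {syn.n_markers_required}"
                )
        for sc in self.scaffolds:
            if sc.reaction_id in seen_rids:
                raise IntegrityError(f"duplicate reaction id {sc.reaction_id!r}")
            seen_rids.add(sc.reaction_id)
            self._validate_scaffold(sc)
        return self

    def _validate_scaffold(self, sc: ReactionScaffold) -> None:
        rid = sc.reaction_id
        if sc.n_components not in (2, 3):
            raise LibraryError(f"reaction {rid!r}: n_components must be 2 or 3")
        if len(sc.points) != sc.n_components:
            raise LibraryError(
                f"reaction {rid!r}: {len(sc.points)} points for "
                f"{sc.n_components} components"
            )
        if set(sc.synthon_lists) != set(sc.point_labels):
            raise IntegrityError(f"reaction {rid!r}: synthon_lists/points mismatch")
        for label, chem in sc.points:
            if chem not in CAP_FOR_CHEMISTRY:
                raise LibraryError(
                    f"reaction {rid!r} point {label!r}: unknown cap chemistry {chem!r}"
                )
        for label, sids in sc.synthon_lists.items():
            for sid in sids:
                if sid not in self.synthons:
                    raise IntegrityError(
                        f"reaction {rid!r} point {label!r} references unknown "
                        f"synthon {sid!r}"
                    )
                if label not in self.synthons[sid].compatible_points:
                    raise IntegrityError(
                        f"synthon {sid!r} is not declared compatible with point "
                        f"{label!r} of reaction {rid!r}"
                    )
        if sc.is_bridge:
            self._validate_bridge(sc)
        else:
            if not sc.core_smiles:
                raise LibraryError(f"reaction {rid!r}: empty core for non-bridge")
            core = _parse_smiles(sc.core_smiles, what=f"reaction {rid!r} core")
            want = {_point_map_num(lbl) for lbl in sc.point_labels}
            have = set(_marker_map_nums(core, what=f"reaction {rid!r} core"))
            if want != have:
                raise LibraryError(
                    f"reaction {rid!r}: core markers {sorted(have)} do not match "
                    f"point labels {sorted(want)}"
                )
            for label, sids in sc.synthon_lists.items():
                for sid in sids:
                    if self.synthons[sid].kind != "terminal":
                        raise LibraryError(
                            f"reaction {rid!r}: bridge synthon {sid!r} listed on a "
                            "non-bridge reaction"
                        )

    def _validate_bridge(self, sc: ReactionScaffold) -> None:
        rid = sc.reaction_id
        if sc.n_components != 3:
            raise LibraryError(f"bridge reaction {rid!r} must have 3 components")
        if sc.core_smiles:
            raise LibraryError(
                f"bridge reaction {rid!r}: only direct synthon-synthon connection "
                "(empty core) is supported"
            )
        bridge_pts = [
            lbl
            for lbl in sc.point_labels
            if sc.synthon_lists[lbl]
            and all(self.synthons[s].kind == "bridge" for s in sc.synthon_lists[lbl])
        ]
        if len(bridge_pts) != 1:
            raise LibraryError(
                f"bridge reaction {rid!r}: expected exactly one all-bridge synthon "
                f"slot, found {bridge_pts!r}"
            )
        slot = bridge_pts[0]
        self._bridge_slots[rid] = slot
        terminal_maps = {
            _point_map_num(lbl) for lbl in sc.point_labels if lbl != slot
        }
        for lbl in sc.point_labels:
            kinds = {self.synthons[s].kind for s in sc.synthon_lists[lbl]}
            if lbl != slot and kinds - {"terminal"}:
                raise LibraryError(
                    f"bridge reaction {rid!r}: mixed synthon kinds at point {lbl!r}"
                )
        for sid in sc.synthon_lists[slot]:
            mol = _parse_smiles(self.synthons[sid].smiles, what=f"synthon {sid!r}")
            have = set(_marker_map_nums(mol, what=f"synthon {sid!r}"))
            if have != terminal_maps:
                raise LibraryError(
                    f"bridge synthon {sid!r}: markers {sorted(have)} must match the "
                    f"terminal point labels {sorted(terminal_maps)} of {rid!r}"
                )


@dataclass
class MELFragment:
    """A capped minimal-enumeration fragment.

    ``cap_atoms`` maps a point label to its :class:`CapAtom`; ``provenance``
    (property) maps every heavy-atom index to its origin tag.
    """

    mel_id: str
    reaction_id: str
    enumerated_point: str
    enumerated_synthon_ids: tuple[str, ...]
    mol: Chem.Mol
    cap_atoms: dict[str, "CapAtom"]

    @property
    def provenance(self) -> dict[int, str]:
        return _provenance(self.mol)

    @property
    def remaining_caps(self) -> list[str]:
        return list(self.cap_atoms)

    @property
    def enumerated_points(self) -> tuple[str, ...]:
        return (self.enumerated_point,)

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass(frozen=True)
class CapAtom:
    """The labelled attachment carbon of one cap group."""

    cap_type: str  # methyl | phenyl
    atom_index: int
    map_num: int  # attachment-marker map number the cap replaced


@dataclass
class EnumeratedMolecule:
    """A (partially) enumerated product with provenance back to its MEL."""

    mol_id: str
    parent_id: str  # immediate parent (MEL fragment or intermediate)
    parent_mel_id: str  # root MEL fragment
    reaction_id: str
    synthon_ids: dict[str, str]  # point label -> synthon id
    mol: Chem.Mol
    cap_atoms: dict[str, CapAtom]

    @property
    def provenance(self) -> dict[int, str]:
        return _provenance(self.mol)

    @property
    def remaining_caps(self) -> list[str]:
        return list(self.cap_atoms)

    @property
    def enumerated_points(self) -> tuple[str, ...]:
        return tuple(self.synthon_ids)

    @property
    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


# ---------------------------------------------------------------------------
# low-level structure editing
# ---------------------------------------------------------------------------


def _parse_smiles(smiles: str, *, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryError(f"unparseable SMILES for {what}: {smiles!r}")
    return mol


def _marker_map_nums(mol: Chem.Mol, *, what: str) -> list[int]:
    nums = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            n = atom.GetAtomMapNum()
            if n <= 0:
                raise LibraryError(f"{what}: attachment marker without map number")
            nums.append(n)
    if len(set(nums)) != len(nums):
        raise LibraryError(f"{what}: duplicate attachment-marker map numbers")
    return sorted(nums)


def _point_map_num(label: str) -> int:
    try:
        return int(label)
    except ValueError as exc:
        raise LibraryError(
            f"attachment-point label {label!r} must be an integer (matches the "
            "SMILES marker map number)"
        ) from exc


def _tagged_mol(smiles: str, prefix: str, *, what: str) -> Chem.Mol:
    """Parse ``smiles`` and stamp provenance tags ``<prefix>:i`` on real atoms."""
    mol = Chem.Mol(_parse_smiles(smiles, what=what))
    i = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 0:
            atom.SetProp(ORIGIN_PROP, f"{prefix}:{i}")
            i += 1
    return mol


def _retarget_marker(mol: Chem.Mol, map_num: int) -> Chem.Mol:
    """Point a single-marker fragment's dummy atom at ``map_num``."""
    mol = Chem.Mol(mol)
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ChemistryError("retarget requires exactly one attachment marker")
    dummies[0].SetAtomMapNum(map_num)
    return mol


def attach_at(a: Chem.Mol, b: Chem.Mol, map_num: int) -> Chem.Mol:
    """Join two fragments at their ``[*:map_num]`` markers with a single bond."""
    combined = Chem.RWMol(Chem.CombineMols(a, b))
    dummies = [
        atom.GetIdx()
        for atom in combined.GetAtoms()
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == map_num
    ]
    if len(dummies) != 2:
        raise ChemistryError(
            f"attachment needs exactly one [*:{map_num}] marker on each side, "
            f"found {len(dummies)} in the combination"
        )
    neighbors = []
    for idx in dummies:
        nbrs = combined.GetAtomWithIdx(idx).GetNeighbors()
        if len(nbrs) != 1:
            raise ChemistryError(f"marker [*:{map_num}] must have exactly one neighbor")
        neighbors.append(nbrs[0].GetIdx())
    combined.AddBond(neighbors[0], neighbors[1], Chem.BondType.SINGLE)
    for idx in sorted(dummies, reverse=True):
        combined.RemoveAtom(idx)
    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - depends on input chemistry
        raise ChemistryError(f"invalid product after attachment: {exc}") from exc
    return mol


def _cap_fragment(cap_type: str, map_num: int, label: str) -> Chem.Mol:
    if cap_type == "methyl":
        mol = Chem.MolFromSmiles(f"C[*:{map_num}]")
    elif cap_type == "phenyl":
        mol = Chem.MolFromSmiles(f"c1ccccc1[*:{map_num}]")
    else:
        raise ChemistryError(f"unknown cap type {cap_type!r}")
    mol = Chem.Mol(mol)
    dummy = next(a for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    ipso = dummy.GetNeighbors()[0]
    ipso.SetIsotope(CAP_ISOTOPE[cap_type])
    ipso.SetProp(CAP_POINT_PROP, label)
    ipso.SetProp(CAP_TYPE_PROP, cap_type)
    ipso.SetIntProp(CAP_MAP_PROP, map_num)
    i = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 0:
            atom.SetProp(ORIGIN_PROP, f"cap:{label}:{i}")
            i += 1
    return mol


def cap_at(mol: Chem.Mol, map_num: int, cap_type: str, label: str) -> Chem.Mol:
    """Replace the ``[*:map_num]`` marker with a labelled minimal cap group."""
    return attach_at(mol, _cap_fragment(cap_type, map_num, label), map_num)


def _collect_caps(mol: Chem.Mol) -> dict[str, CapAtom]:
    caps: dict[str, CapAtom] = {}
    for atom in mol.GetAtoms():
        if atom.HasProp(CAP_POINT_PROP):
            label = atom.GetProp(CAP_POINT_PROP)
            caps[label] = CapAtom(
                cap_type=atom.GetProp(CAP_TYPE_PROP),
                atom_index=atom.GetIdx(),
                map_num=atom.GetIntProp(CAP_MAP_PROP),
            )
    return caps


def cap_member_atoms(mol: Chem.Mol, label: str) -> list[int]:
    """Atom indices belonging to the cap group at ``label``."""
    out = []
    for atom in mol.GetAtoms():
        if atom.HasProp(ORIGIN_PROP):
            parts = atom.GetProp(ORIGIN_PROP).split(":")
            if parts[0] == "cap" and parts[1] == label:
                out.append(atom.GetIdx())
    return out


def _provenance(mol: Chem.Mol) -> dict[int, str]:
    out = {}
    for atom in mol.GetAtoms():
        if atom.HasProp(ORIGIN_PROP):
            out[atom.GetIdx()] = atom.GetProp(ORIGIN_PROP)
    return out


_ANCHOR_MARK = "ssAnchorMark"


def _remove_cap(mol: Chem.Mol, label: str) -> Chem.Mol:
    """Strip the cap at ``label`` and leave an attachment marker on the anchor."""
    caps = _collect_caps(mol)
    if label not in caps:
        raise ChemistryError(f"point {label!r} is not capped")
    cap = caps[label]
    members = set(cap_member_atoms(mol, label))
    rw = Chem.RWMol(mol)
    cap_atom = rw.GetAtomWithIdx(cap.atom_index)
    anchors = [n for n in cap_atom.GetNeighbors() if n.GetIdx() not in members]
    if len(anchors) != 1:
        raise ChemistryError(f"cap at {label!r} has {len(anchors)} anchors")
    anchors[0].SetBoolProp(_ANCHOR_MARK, True)
    for idx in sorted(members, reverse=True):
        rw.RemoveAtom(idx)
    anchor_idx = next(
        a.GetIdx() for a in rw.GetAtoms() if a.HasProp(_ANCHOR_MARK)
    )
    rw.GetAtomWithIdx(anchor_idx).ClearProp(_ANCHOR_MARK)
    dummy = Chem.Atom(0)
    dummy.SetAtomMapNum(cap.map_num)
    didx = rw.AddAtom(dummy)
    rw.AddBond(anchor_idx, didx, Chem.BondType.SINGLE)
    return rw.GetMol()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def parse_reaction_library(path: str | Path) -> ReactionLibrary:
    """Load and validate a reaction library from its JSON file.

    Schema: top-level ``synthons`` (list of ``{id, smiles, kind,
    compatible_points}``) and ``reactions`` (list of ``{reaction_id,
    n_components, core_smiles, points: [{label, cap_chemistry}],
    synthon_lists, is_bridge}``).  Attachment markers in SMILES are
    atom-map-numbered dummy atoms (``[*:1]``, ``[*:2]``, ...) matching the
    integer point labels.
    """
    path = Path(path)
    data = json.loads(path.read_text())
    synthons: dict[str, Synthon] = {}
    for rec in data.get("synthons", []):
        syn = Synthon(
            id=rec["id"],
            smiles=rec["smiles"],
            kind=rec.get("kind", "terminal"),
            compatible_points=tuple(rec.get("compatible_points", ())),
        )
        if syn.id in synthons:
            raise IntegrityError(f"duplicate synthon id {syn.id!r}")
        synthons[syn.id] = syn
    scaffolds = []
    for rec in data.get("reactions", []):
        scaffolds.append(
            ReactionScaffold(
                reaction_id=rec["reaction_id"],
                n_components=int(rec["n_components"]),
                core_smiles=rec.get("core_smiles", "") or "",
                points=tuple(
                    (p["label"], p["cap_chemistry"]) for p in rec["points"]
                ),
                synthon_lists={
                    k: tuple(v) for k, v in rec["synthon_lists"].items()
                },
                is_bridge=bool(rec.get("is_bridge", False)),
            )
        )
    return ReactionLibrary(scaffolds=scaffolds, synthons=synthons).validate()


def write_reaction_library(lib: ReactionLibrary, path: str | Path) -> None:
    data = {
        "synthons": [
            {
                "id": s.id,
                "smiles": s.smiles,
                "kind": s.kind,
                "compatible_points": list(s.compatible_points),
            }
            for s in lib.synthons.values()
        ],
        "reactions": [
            {
                "reaction_id": sc.reaction_id,
                "n_components": sc.n_components,
                "core_smiles": sc.core_smiles,
                "points": [
                    {"label": lbl, "cap_chemistry": chem} for lbl, chem in sc.points
                ],
                "synthon_lists": {k: list(v) for k, v in sc.synthon_lists.items()},
                "is_bridge": sc.is_bridge,
            }
            for sc in lib.scaffolds
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))


def count_full_space(lib: ReactionLibrary) -> int:
    """Size of the fully enumerated space: sum over reactions of the product
    of synthon-list sizes over attachment points."""
    total = 0
    for sc in lib.scaffolds:
        prod = 1
        for label in sc.point_labels:
            n = len(sc.synthon_lists[label])
            if n == 0:
                raise LibraryError(
                    f"degenerate reaction {sc.reaction_id!r}: empty synthon list "
                    f"at point {label!r}"
                )
            prod *= n
        total += prod
    return total


def _synthon_mol(lib: ReactionLibrary, point: str, sid: str) -> Chem.Mol:
    syn = lib.synthons[sid]
    return _tagged_mol(syn.smiles, f"syn:{point}:{sid}", what=f"synthon {sid!r}")


def build_mel(lib: ReactionLibrary) -> list[MELFragment]:
    """Build the minimal enumeration library for every scaffold.

    One fragment per (reaction, attachment point, compatible synthon), all
    other points capped per their reaction chemistry; bridge synthons are not
    enumerated (bridge-reaction fragments are terminal synthons with a methyl
    cap at the bridge junction).  Fragments are deduplicated by canonical
    isotope-labelled SMILES within each reaction.
    """
    fragments: list[MELFragment] = []
    for sc in lib.scaffolds:
        seen: set[str] = set()
        if sc.is_bridge:
            slot = lib.bridge_slot(sc.reaction_id)
            for label in sc.point_labels:
                if label == slot:
                    continue
                for sid in sc.synthon_lists[label]:
                    mol = _synthon_mol(lib, label, sid)
                    mol = cap_at(mol, _point_map_num(label), "methyl", slot)
                    frag = MELFragment(
                        mel_id=f"{sc.reaction_id}:{label}:{sid}",
                        reaction_id=sc.reaction_id,
                        enumerated_point=label,
                        enumerated_synthon_ids=(sid,),
                        mol=mol,
                        cap_atoms=_collect_caps(mol),
                    )
                    key = frag.canonical_smiles
                    if key not in seen:
                        seen.add(key)
                        fragments.append(frag)
        else:
            core = _tagged_mol(
                sc.core_smiles, "core", what=f"reaction {sc.reaction_id!r} core"
            )
            for label, _chem in sc.points:
                for sid in sc.synthon_lists[label]:
                    syn_mol = _retarget_marker(
                        _synthon_mol(lib, label, sid), _point_map_num(label)
                    )
                    try:
                        mol = attach_at(Chem.Mol(core), syn_mol, _point_map_num(label))
                        for other, chem in sc.points:
                            if other == label:
                                continue
                            mol = cap_at(
                                mol,
                                _point_map_num(other),
                                CAP_FOR_CHEMISTRY[chem],
                                other,
                            )
                    except ChemistryError as exc:
                        log.warning(
                            "skipping MEL %s:%s:%s: %s",
                            sc.reaction_id,
                            label,
                            sid,
                            exc,
                        )
                        continue
                    frag = MELFragment(
                        mel_id=f"{sc.reaction_id}:{label}:{sid}",
                        reaction_id=sc.reaction_id,
                        enumerated_point=label,
                        enumerated_synthon_ids=(sid,),
                        mol=mol,
                        cap_atoms=_collect_caps(mol),
                    )
                    key = frag.canonical_smiles
                    if key not in seen:
                        seen.add(key)
                        fragments.append(frag)
    return fragments


def spawn_count(frag: MELFragment | EnumeratedMolecule, lib: ReactionLibrary) -> int:
    """Number of fully enumerated products this fragment will ultimately spawn
    (product of synthon-list sizes over its not-yet-enumerated points)."""
    sc = lib.scaffold(frag.reaction_id)
    done = set(frag.enumerated_points)
    prod = 1
    for label in sc.point_labels:
        if label not in done:
            prod *= len(sc.synthon_lists[label])
    return prod


def enumerate_at(
    frag: MELFragment | EnumeratedMolecule,
    point: str,
    lib: ReactionLibrary,
) -> list[EnumeratedMolecule]:
    """Replace the cap at ``point`` with every compatible synthon.

    For a bridge reaction's bridge slot, the bridge synthon is inserted and
    its far side re-capped with methyl (labelled by the remaining terminal
    point), so the product is a partially enumerated intermediate.
    Chemically invalid products are skipped with a logged warning.
    """
    if point not in frag.cap_atoms:
        raise ChemistryError(
            f"point {point!r} of {_frag_id(frag)!r} is not capped"
        )
    sc = lib.scaffold(frag.reaction_id)
    slot = lib.bridge_slot(frag.reaction_id)
    cap = frag.cap_atoms[point]
    products: list[EnumeratedMolecule] = []
    n_skipped = 0
    for sid in sc.synthon_lists[point]:
        base = _remove_cap(frag.mol, point)
        syn_mol = _synthon_mol(lib, point, sid)
        if lib.synthons[sid].kind == "terminal":
            syn_mol = _retarget_marker(syn_mol, cap.map_num)
        try:
            mol = attach_at(base, syn_mol, cap.map_num)
            if sc.is_bridge and point == slot:
                # far side of the bridge: cap with methyl, label = the
                # terminal point whose map number is the remaining marker
                remaining = _marker_map_nums(mol, what="bridge intermediate")
                for m in remaining:
                    other = str(m)
                    mol = cap_at(mol, m, "methyl", other)
            elif _marker_map_nums(mol, what="product"):
                raise ChemistryError("unexpected open attachment marker")
        except ChemistryError as exc:
            n_skipped += 1
            log.warning(
                "skipping product %s+%s=%s: %s", _frag_id(frag), point, sid, exc
            )
            continue
        synthon_ids = dict(getattr(frag, "synthon_ids", {}))
        if isinstance(frag, MELFragment):
            synthon_ids = {frag.enumerated_point: frag.enumerated_synthon_ids[0]}
        synthon_ids[point] = sid
        products.append(
            EnumeratedMolecule(
                mol_id=f"{_frag_id(frag)}+{point}={sid}",
                parent_id=_frag_id(frag),
                parent_mel_id=getattr(frag, "parent_mel_id", None)
                or getattr(frag, "mel_id"),
                reaction_id=frag.reaction_id,
                synthon_ids=synthon_ids,
                mol=mol,
                cap_atoms=_collect_caps(mol),
            )
        )
    if n_skipped:
        log.warning(
            "%d invalid products skipped while enumerating %s at %s",
            n_skipped,
            _frag_id(frag),
            point,
        )
    return products


def _frag_id(frag: MELFragment | EnumeratedMolecule) -> str:
    return getattr(frag, "mel_id", None) or getattr(frag, "mol_id")


def enumerate_full_space(lib: ReactionLibrary) -> list[tuple[str, Chem.Mol]]:
    """Brute-force full enumeration (the independent route for conservation
    checks; never used by the hierarchical pipeline itself)."""
    out: list[tuple[str, Chem.Mol]] = []
    for sc in lib.scaffolds:
        labels = sc.point_labels
        if sc.is_bridge:
            slot = lib.bridge_slot(sc.reaction_id)
            terminals = [lbl for lbl in labels if lbl != slot]
            t1, t2 = terminals
            for s1, sb, s2 in itertools.product(
                sc.synthon_lists[t1], sc.synthon_lists[slot], sc.synthon_lists[t2]
            ):
                try:
                    m1 = _retarget_marker(
                        _synthon_mol(lib, t1, s1), _point_map_num(t1)
                    )
                    mol = attach_at(m1, _synthon_mol(lib, slot, sb), _point_map_num(t1))
                    m2 = _retarget_marker(
                        _synthon_mol(lib, t2, s2), _point_map_num(t2)
                    )
                    mol = attach_at(mol, m2, _point_map_num(t2))
                except ChemistryError as exc:
                    log.warning("skipping full-space product: %s", exc)
                    continue
                key = ",".join([f"{t1}={s1}", f"{slot}={sb}", f"{t2}={s2}"])
                out.append((f"{sc.reaction_id}|{key}", mol))
        else:
            core = _tagged_mol(
                sc.core_smiles, "core", what=f"reaction {sc.reaction_id!r} core"
            )
            lists = [sc.synthon_lists[lbl] for lbl in labels]
            for combo in itertools.product(*lists):
                try:
                    mol = Chem.Mol(core)
                    for lbl, sid in zip(labels, combo):
                        syn = _retarget_marker(
                            _synthon_mol(lib, lbl, sid), _point_map_num(lbl)
                        )
                        mol = attach_at(mol, syn, _point_map_num(lbl))
                except ChemistryError as exc:
                    log.warning("skipping full-space product: %s", exc)
                    continue
                key = ",".join(f"{lbl}={sid}" for lbl, sid in zip(labels, combo))
                out.append((f"{sc.reaction_id}|{key}", mol))
    return out


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------


def write_smiles(
    frags: Iterable[MELFragment | EnumeratedMolecule], path: str | Path
) -> None:
    """Tab-separated SMILES/id file (.smi)."""
    with open(path, "w") as fh:
        for f in frags:
            fh.write(f"{f.canonical_smiles}\t{_frag_id(f)}\n")


def write_provenance(
    frags: Iterable[MELFragment | EnumeratedMolecule], path: str | Path
) -> None:
    data = {
        _frag_id(f): [
            f.provenance.get(i, "") for i in range(f.mol.GetNumAtoms())
        ]
        for f in frags
    }
    Path(path).write_text(json.dumps(data))
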