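"""SDF round trip for scored docked poses.

Poses are exchanged as plain SDF with a ``dock_score`` property field.  Cap
bookkeeping travels in a ``cap_info`` JSON property (and redundantly as
isotope labels 13/14 on the cap attachment carbons, so poses exported to
other tools remain interpretable).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .capselect import CapSite, DockedPose
from .chem_space import CAP_ISOTOPE


def pose_to_mol(pose: DockedPose) -> Chem.Mol:
    """Bond-less atom cloud carrying the pose's coordinates and metadata."""
    rw = Chem.RWMol()
    for el in pose.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    conf = Chem.Conformer(len(pose.elements))
    for i, xyz in enumerate(pose.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    for site in pose.caps.values():
        mol.GetAtomWithIdx(site.cap_atom).SetIsotope(CAP_ISOTOPE[site.cap_type])
    mol.SetProp("_Name", pose.fragment_ref)
    mol.SetProp("dock_score", repr(float(pose.dock_score)))
    mol.SetProp(
        "cap_info",
        json.dumps(
            [
                {
                    "label": s.label,
                    "cap_type": s.cap_type,
                    "cap_atom": s.cap_atom,
                    "anchor_atom": s.anchor_atom,
                    "members": list(s.members),
                }
                for s in pose.caps.values()
            ]
        ),
    )
    return mol


def write_poses_sdf(poses: Iterable[DockedPose], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            writer.write(pose_to_mol(pose))
    finally:
        writer.close()


def read_poses_sdf(path: str | Path) -> list[DockedPose]:
    poses = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for mol in supplier:
        if mol is None:
            continue
        conf = mol.GetConformer()
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        caps = {}
        if mol.HasProp("cap_info"):
            for rec in json.loads(mol.GetProp("cap_info")):
                caps[rec["label"]] = CapSite(
                    label=rec["label"],
                    cap_type=rec["cap_type"],
                    cap_atom=int(rec["cap_atom"]),
                    anchor_atom=int(rec["anchor_atom"]),
                    members=tuple(rec["members"]),
                )
        else:
            from .capselect import cap_sites_from_mol

            caps = cap_sites_from_mol(mol)
        score = float(mol.GetProp("dock_score")) if mol.HasProp("dock_score") else 0.0
        poses.append(
            DockedPose(
                fragment_ref=mol.GetProp("_Name") if mol.HasProp("_Name") else "",
                elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
                coords=coords,
                dock_score=score,
                caps=caps,
            )
        )
    return poses
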