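"""Sphere-growth classification of docked fragment poses.

A capped attachment point of a docked minimal-enumeration fragment is
"productive" when the pocket leaves room to grow a real synthon where the
cap sits.  The algorithm estimates that growth capacity geometrically: an
initial sphere is centred on the labelled cap carbon (radius 3.0 A for a
methyl cap, 3.5 A for phenyl), and further 2.0-A spheres are grown one at a
time, each tangent to the previous one.  Candidate directions come from a
5-degree spherical mesh (72 azimuthal x 36 longitudinal angles) restricted
to a 60-degree half-angle cone around the current growth axis; among
candidates whose centres keep >= 2.0 A clearance from every pocket atom and
every non-cap ligand atom, the one farthest from the nearest pocket atom is
taken (greedy).  Growth terminates with ``clash`` when no candidate is
feasible, or with ``exit`` when the chain has travelled more than 10 A while
outside the pocket envelope (nearest pocket atom farther than ``d_solvent``,
default 8 A).

The CapScore of a chain counts the grown spheres whose centres lie inside
the pocket envelope — spheres placed during a solvent excursion are kept in
the chain but do not count toward growth capacity.  A chain is productive
when it grows at least ``n_min`` (default 2) in-pocket spheres; a pose with
several caps is productive when at least one chain is, and its CapScore is
the best chain's.

Hyperparameters were fixed once for all pocket types and live in
:class:`CapSelectParams`; changing them is not recommended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chem_space import (
    CAP_ISOTOPE,
    CAP_POINT_PROP,
    CAP_TYPE_PROP,
    cap_member_atoms,
)


@dataclass(frozen=True)
class CapSelectParams:
    """Frozen sphere-growth hyperparameters (distances in Angstrom)."""

    sphere_radius: float = 2.0
    init_radius_methyl: float = 3.0
    init_radius_phenyl: float = 3.5
    clearance: float = 2.0
    cone_half_angle_deg: float = 60.0
    exit_path_length: float = 10.0
    d_solvent: float = 8.0
    n_min: int = 2
    max_spheres: int = 60
    n_theta: int = 36
    n_phi: int = 72
    angle_step_deg: float = 5.0

    def init_radius(self, cap_type: str) -> float:
        if cap_type == "methyl":
            return self.init_radius_methyl
        if cap_type == "phenyl":
            return self.init_radius_phenyl
        raise ValueError(f"unknown cap type {cap_type!r}")


@dataclass
class Pocket:
    """Receptor pocket heavy atoms in a fixed Cartesian frame.

    Multi-conformer docking models are supported as a plain union of the
    conformers' atom sets (conservative for both clash and envelope tests).
    """

    coords: np.ndarray  # (N, 3) float64, Angstrom
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) == 0:
            raise ValueError("pocket must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pocket coordinates must be finite")
        if not self.elements:
            self.elements = ("C",) * len(self.coords)

    @classmethod
    def from_union(cls, *parts: "Pocket") -> "Pocket":
        return cls(
            coords=np.vstack([p.coords for p in parts]),
            elements=tuple(e for p in parts for e in p.elements),
        )

    @classmethod
    def from_pdb(cls, path: str | Path, include_het: bool = True) -> "Pocket":
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("pocket", str(path))
        coords, elements = [], []
        for atom in structure.get_atoms():
            el = (atom.element or "").strip().upper()
            if el in ("H", "D"):
                continue
            het = atom.get_parent().id[0].strip()
            if het and not include_het:
                continue
            coords.append(atom.coord)
            elements.append(el.capitalize() or "C")
        return cls(coords=np.array(coords, dtype=float), elements=tuple(elements))


@dataclass(frozen=True)
class CapSite:
    """One capped attachment point of a docked pose."""

    label: str
    cap_type: str  # methyl | phenyl
    cap_atom: int  # index of the labelled attachment carbon
    anchor_atom: int  # heavy-atom neighbor outside the cap group
    members: tuple[int, ...]  # all atoms of the cap group


@dataclass
class DockedPose:
    """A scored rigid pose of a fragment in the receptor frame.

    ``dock_score`` follows the lower-is-better docking convention.
    """

    fragment_ref: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3) heavy atoms, same order as the 2D graph
    dock_score: float
    caps: dict[str, CapSite] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")

    def noncap_coords(self) -> np.ndarray:
        members = {i for site in self.caps.values() for i in site.members}
        keep = [i for i in range(len(self.coords)) if i not in members]
        return self.coords[keep]


def cap_sites_from_mol(mol) -> dict[str, CapSite]:
    """Extract cap sites from a labelled fragment graph.

    Prefers the structural bookkeeping (atom properties written at cap
    construction); falls back to isotope inference (13 = methyl carbon,
    14 = phenyl ipso, cap group = the labelled atom or its aromatic ring)
    for molecules read back from plain SDF.
    """
    sites: dict[str, CapSite] = {}
    tagged = [a for a in mol.GetAtoms() if a.HasProp(CAP_POINT_PROP)]
    if tagged:
        for atom in tagged:
            label = atom.GetProp(CAP_POINT_PROP)
            members = tuple(cap_member_atoms(mol, label))
            anchor = [
                n.GetIdx() for n in atom.GetNeighbors() if n.GetIdx() not in members
            ]
            sites[label] = CapSite(
                label=label,
                cap_type=atom.GetProp(CAP_TYPE_PROP),
                cap_atom=atom.GetIdx(),
                anchor_atom=anchor[0],
                members=members,
            )
        return sites
    iso_to_type = {v: k for k, v in CAP_ISOTOPE.items()}
    k = 0
    for atom in mol.GetAtoms():
        cap_type = iso_to_type.get(atom.GetIsotope())
        if cap_type is None or atom.GetAtomicNum() != 6:
            continue
        if cap_type == "phenyl":
            ring_info = mol.GetRingInfo()
            members = next(
                (tuple(r) for r in ring_info.AtomRings() if atom.GetIdx() in r),
                (atom.GetIdx(),),
            )
        else:
            members = (atom.GetIdx(),)
        anchor = [
            n.GetIdx() for n in atom.GetNeighbors() if n.GetIdx() not in members
        ]
        if not anchor:
            continue
        label = str(k)
        sites[label] = CapSite(label, cap_type, atom.GetIdx(), anchor[0], members)
        k += 1
    return sites


@dataclass
class SphereChain:
    """Greedy sphere chain grown from one cap atom.

    ``centers``/``radii`` include the initial cap sphere plus every accepted
    sphere; ``n_grown`` counts the accepted spheres inside the pocket
    envelope (the growth capacity), so ``len(centers) - 1 >= n_grown``.
    """

    cap_point: str
    centers: np.ndarray  # (k+1, 3)
    radii: np.ndarray  # (k+1,)
    termination: str  # clash | exit
    n_grown: int

    @property
    def n_accepted(self) -> int:
        return len(self.centers) - 1


@dataclass
class CapResult:
    """Per-pose productivity verdict."""

    chains: dict[str, SphereChain]
    cap_score: int
    productive: bool


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _local_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0 or not np.all(np.isfinite(a)):
        raise ValueError("axis must be a finite nonzero vector")
    a = a / norm
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return a, e1, e2


def cone_mesh(
    axis: Sequence[float],
    half_angle_deg: float,
    n_theta: int = 36,
    n_phi: int = 72,
    angle_step_deg: float = 5.0,
) -> np.ndarray:
    """Unit directions of the 5-degree spherical mesh within a cone.

    The grid lives in a deterministic axis-aligned local frame: polar angle
    theta in {0, step, ..., (n_theta-1)*step} measured from ``axis``, azimuth
    phi in {0, ..., (n_phi-1)*step}.  The pole theta=0 collapses to a single
    direction.  Directions are returned theta-major then phi (so index order
    is the deterministic tie-break order).
    """
    if not 0 < half_angle_deg <= 180:
        raise ValueError("half_angle_deg must be in (0, 180]")
    a, e1, e2 = _local_frame(np.asarray(axis, dtype=float))
    out = []
    for ti in range(n_theta):
        theta = math.radians(ti * angle_step_deg)
        if math.degrees(theta) > half_angle_deg + 1e-9:
            break
        if ti == 0:
            out.append(a)
            continue
        st, ct = math.sin(theta), math.cos(theta)
        for pi in range(n_phi):
            phi = math.radians(pi * angle_step_deg)
            out.append(st * (math.cos(phi) * e1 + math.sin(phi) * e2) + ct * a)
    return np.array(out)


def grow_chain(
    pose: DockedPose,
    pocket: Pocket,
    cap_point: str,
    params: CapSelectParams = CapSelectParams(),
) -> SphereChain:
    """Grow the greedy sphere chain from one labelled cap atom.

    The first growth axis is the anchor-to-cap bond vector; afterwards it is
    the vector between the two previous centres.  See the module docstring
    for the full rule set.
    """
    if cap_point not in pose.caps:
        raise KeyError(f"pose has no cap at point {cap_point!r}")
    site = pose.caps[cap_point]
    r0 = params.init_radius(site.cap_type)
    c0 = pose.coords[site.cap_atom]
    anchor = pose.coords[site.anchor_atom]
    if not np.all(np.isfinite(c0)):
        raise ValueError("cap atom lacks finite 3D coordinates")
    ligand = pose.noncap_coords()
    have_ligand = len(ligand) > 0
    centers = [c0.copy()]
    radii = [r0]
    axis = c0 - anchor
    out_path = 0.0
    termination = "exit"
    n_grown = 0
    for _ in range(params.max_spheres):
        dirs = cone_mesh(
            axis,
            params.cone_half_angle_deg,
            n_theta=params.n_theta,
            n_phi=params.n_phi,
            angle_step_deg=params.angle_step_deg,
        )
        step = radii[-1] + params.sphere_radius
        cands = centers[-1] + step * dirs
        d_pocket = cdist(cands, pocket.coords).min(axis=1)
        feasible = d_pocket >= params.clearance
        if have_ligand:
            feasible &= cdist(cands, ligand).min(axis=1) >= params.clearance
        if not feasible.any():
            termination = "clash"
            break
        scores = np.where(feasible, d_pocket, -np.inf)
        j = int(np.argmax(scores))  # first maximum = lowest (theta, phi) index
        new_center = cands[j]
        centers.append(new_center)
        radii.append(params.sphere_radius)
        axis = new_center - centers[-2]
        if d_pocket[j] > params.d_solvent:
            out_path += step
            if out_path > params.exit_path_length:
                termination = "exit"
                break
        else:
            out_path = 0.0
            n_grown += 1
    return SphereChain(
        cap_point=cap_point,
        centers=np.array(centers),
        radii=np.array(radii),
        termination=termination,
        n_grown=n_grown,
    )


def cap_result(
    pose: DockedPose,
    pocket: Pocket,
    params: CapSelectParams = CapSelectParams(),
) -> CapResult:
    """Run sphere growth on every cap of a pose and classify productivity.

    A chain is productive when it grows at least ``params.n_min`` in-pocket
    spheres; the pose is productive when any chain is (dual-cap fragments
    stay productive while one growth pathway remains open), and its CapScore
    is the best chain's in-pocket sphere count.
    """
    if not pose.caps:
        raise ValueError("pose has no capped attachment points")
    chains = {
        label: grow_chain(pose, pocket, label, params) for label in sorted(pose.caps)
    }
    cap_score = max(chain.n_grown for chain in chains.values())
    productive = any(chain.n_grown >= params.n_min for chain in chains.values())
    return CapResult(chains=chains, cap_score=cap_score, productive=productive)


def run_capselect(
    poses: Iterable[DockedPose],
    pocket: Pocket,
    params: CapSelectParams = CapSelectParams(),
) -> pd.DataFrame:
    """Tabulate cap growth for many poses (one row per pose/cap pair)."""
    rows = []
    for pose in poses:
        res = cap_result(pose, pocket, params)
        for label, chain in res.chains.items():
            rows.append(
                {
                    "fragment_ref": pose.fragment_ref,
                    "dock_score": pose.dock_score,
                    "cap_point": label,
                    "n_grown": chain.n_grown,
                    "termination": chain.termination,
                    "cap_score": res.cap_score,
                    "productive": res.productive,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PDB helpers
# ---------------------------------------------------------------------------


def write_pocket_pdb(pocket: Pocket, path: str | Path) -> None:
    """Write pocket atoms as HETATM pseudo-atom records."""
    with open(path, "w") as fh:
        for i, (xyz, el) in enumerate(zip(pocket.coords, pocket.elements), start=1):
            fh.write(_pdb_line(i, el, xyz, resname="PKT"))
        fh.write("END\n")


def write_spheres_pdb(
    chains: Mapping[str, SphereChain] | Sequence[SphereChain], path: str | Path
) -> None:
    """Write sphere centres as pseudo-atoms for visual inspection."""
    if isinstance(chains, Mapping):
        chains = list(chains.values())
    with open(path, "w") as fh:
        serial = 1
        for chain in chains:
            for xyz in chain.centers:
                fh.write(_pdb_line(serial, "He", xyz, resname="SPH"))
                serial += 1
        fh.write("END\n")


def _pdb_line(serial: int, element: str, xyz: np.ndarray, resname: str) -> str:
    el = element.strip().capitalize()
    name = el.upper()[:4]
    resseq = ((serial - 1) % 9999) + 1
    return (
        f"HETATM{serial % 100000:5d} {name:<4s} {resname:>3s} A{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {el.upper():>2s}\n"
    )
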