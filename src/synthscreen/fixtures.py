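"""Synthetic inputs: toy pockets, toy reaction libraries and scripted poses.

Everything here is generated from a spec plus a seed, bit-for-bit
reproducibly, so the whole engine can be exercised without external data.

Pockets are pseudo-atom arrangements emulating the binding-site archetypes
that matter for sphere growth — an open tunnel, a dead-end tunnel, a shallow
wall, a hollow shell, a half-space slab.  All wall atoms are carbons: the
growth rules are element-blind (pure distance geometry), so chemical realism
in the pocket would add nothing.  Walls are built as thin slabs (a few
lattice layers) rather than single planes so that a 4-5 A growth step cannot
jump through the wall between lattice points, mirroring the bulk of a real
protein.

Toy libraries emulate reaction-based make-on-demand spaces at desk scale:
amide/ester/urea-style cores with marked attachment points, small
alkyl/aryl terminal synthons from a seeded vocabulary, and two-marker bridge
synthons for bridge-type 3-component chemistry.

Scripted docked poses place a tiny capped fragment in a pocket with a known
geometric outcome (grow freely down a tunnel, hit a dead end, or point out
of the pocket mouth), recording the expected productivity verdict as ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .capselect import CapSite, DockedPose, Pocket
from .chem_space import ReactionLibrary, ReactionScaffold, Synthon
from .scoring import ScoreWeights, ScoredCandidate, merged_score


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PocketSpec:
    kind: str  # tunnel | deadend | shallow | shell | halfspace
    radius: float = 4.0  # tunnel/shell radius, A
    length: float = 16.0  # tunnel length, A
    spacing: float = 1.0  # wall-atom lattice spacing, A
    extent: float = 10.0  # lateral half-width of planar walls, A
    layers: int = 3  # slab thickness in lattice layers
    seed: int = 0


def make_pocket(spec: PocketSpec) -> tuple[Pocket, dict]:
    """Deterministic pseudo-atom pocket plus ground-truth geometry metadata."""
    if spec.spacing <= 0 or spec.radius <= 0:
        raise ValueError("spacing and radius must be positive")
    if spec.kind in ("tunnel", "deadend", "shell") and spec.spacing > spec.radius:
        raise ValueError("degenerate wall: spacing exceeds radius")
    builders = {
        "tunnel": _tunnel,
        "deadend": _deadend,
        "shallow": _wall,
        "halfspace": _halfspace,
        "shell": _shell,
    }
    try:
        coords, meta = builders[spec.kind](spec)
    except KeyError:
        raise ValueError(f"unknown pocket kind {spec.kind!r}") from None
    return Pocket(coords=coords), meta


def _ring(radius: float, z: float, spacing: float) -> np.ndarray:
    n = max(3, int(round(2 * math.pi * radius / spacing)))
    ang = 2 * math.pi * np.arange(n) / n
    return np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)], axis=1
    )


def _tunnel(spec: PocketSpec) -> tuple[np.ndarray, dict]:
    zs = np.arange(0.0, spec.length + 1e-9, spec.spacing)
    coords = np.vstack([_ring(spec.radius, z, spec.spacing) for z in zs])
    meta = {
        "axis": (0.0, 0.0, 1.0),
        "axis_origin": (0.0, 0.0, 0.0),
        "openings": [(0.0, 0.0, 0.0), (0.0, 0.0, spec.length)],
        "radius": spec.radius,
    }
    return coords, meta


def _disk(radius: float, z: float, spacing: float) -> np.ndarray:
    parts = [np.array([[0.0, 0.0, z]])]
    for r in np.arange(spacing, radius + 1e-9, spacing):
        parts.append(_ring(r, z, spacing))
    return np.vstack(parts)


def _deadend(spec: PocketSpec) -> tuple[np.ndarray, dict]:
    tun, meta = _tunnel(spec)
    plug = np.vstack(
        [
            _disk(spec.radius, -k * spec.spacing, spec.spacing)
            for k in range(spec.layers)
        ]
    )
    meta = dict(meta)
    meta["openings"] = [(0.0, 0.0, spec.length)]
    meta["sealed_end"] = (0.0, 0.0, 0.0)
    return np.vstack([tun, plug]), meta


def _plane(extent: float, z: float, spacing: float) -> np.ndarray:
    xs = np.arange(-extent, extent + 1e-9, spacing)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)], axis=1)


def _wall(spec: PocketSpec) -> tuple[np.ndarray, dict]:
    # a slab: top face at z=0, bulk below (layer gap 1.5 * spacing)
    gap = 1.5 * spec.spacing
    coords = np.vstack(
        [_plane(spec.extent, -k * gap, spec.spacing) for k in range(spec.layers)]
    )
    meta = {"normal": (0.0, 0.0, 1.0), "surface_z": 0.0, "extent": spec.extent}
    return coords, meta


def _halfspace(spec: PocketSpec) -> tuple[np.ndarray, dict]:
    thick = PocketSpec(
        kind="shallow",
        spacing=spec.spacing,
        extent=spec.extent * 1.5,
        layers=max(spec.layers, 4),
    )
    return _wall(thick)


def _shell(spec: PocketSpec) -> tuple[np.ndarray, dict]:
    pts = []
    n_lat = max(3, int(round(math.pi * spec.radius / spec.spacing)))
    for i in range(n_lat + 1):
        theta = math.pi * i / n_lat
        ring_r = spec.radius * math.sin(theta)
        z = spec.radius * math.cos(theta)
        if ring_r < spec.spacing / 2:
            pts.append(np.array([[0.0, 0.0, z]]))
        else:
            pts.append(_ring(ring_r, z, spec.spacing))
    meta = {"center": (0.0, 0.0, 0.0), "radius": spec.radius}
    return np.vstack(pts), meta


# ---------------------------------------------------------------------------
# toy reaction libraries
# ---------------------------------------------------------------------------

# seeded vocabulary of single-attachment substituents (attachment marker is
# added programmatically)
_TERMINAL_VOCAB = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "C(C)C", "CCO", "CO", "COC", "CCOC",
    "CCN", "CN", "CC(C)O", "CCF", "CC(F)F", "CCCl", "C=C", "CC=C", "CC#N",
    "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "c1ccncc1", "c1cccnc1", "c1ccoc1",
    "c1ccsc1", "C1CC1", "CC1CC1", "C1CCC1", "C1CCCC1", "CC(=O)C", "CC(=O)N",
    "CCCN", "CCCO", "CCCF", "CCCCC", "CC(C)CC", "CCNC", "Cc1ccco1",
    "Cc1ccncc1", "CCC#N", "C(F)(F)F", "CCS", "CSC", "CC(=O)O", "OCC",
)

_BRIDGE_VOCAB = (
    "CC", "CCC", "COC", "CNC", "CCOC", "CCNC", "c1ccc(cc1)", "CC(C)C",
)

_CORES_2 = (
    "[*:1]C(=O)N[*:2]",
    "[*:1]C(=O)O[*:2]",
    "[*:1]NC(=O)N[*:2]",
    "[*:1]S(=O)(=O)N[*:2]",
)

_CORES_3 = (
    "O=C([*:1])N([*:3])CC(=O)N[*:2]",
    "O=C([*:1])N([*:3])CCN[*:2]",
    "O=S(=O)([*:1])N([*:3])CC(=O)N[*:2]",
)


@dataclass(frozen=True)
class LibrarySpec:
    """Shape of a toy library: per-reaction synthon-list sizes."""

    two_component: tuple[tuple[int, int], ...] = ((12, 12),)
    three_component: tuple[tuple[int, int, int], ...] = ((12, 12, 12),)
    bridge: tuple[tuple[int, int, int], ...] = ()  # (|t1|, |bridge|, |t2|)
    seed: int = 0


def make_toy_library(spec: LibrarySpec) -> ReactionLibrary:
    """Seeded toy reaction library with valid SMILES throughout."""
    for sizes in spec.two_component + spec.three_component + spec.bridge:
        if any(s < 1 for s in sizes):
            raise ValueError("synthon-list sizes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    synthons: dict[str, Synthon] = {}
    scaffolds: list[ReactionScaffold] = []
    rid_counter = 0

    def shuffled_vocab() -> list[str]:
        vocab = list(_TERMINAL_VOCAB)
        rng.shuffle(vocab)
        return vocab

    def add_terminals(rid: str, point: str, k: int, pool: list[str]) -> tuple[str, ...]:
        if k > len(pool):
            raise ValueError(
                f"synthon-list size {k} exceeds remaining vocabulary ({len(pool)})"
            )
        ids = []
        for _ in range(k):
            body = pool.pop(0)
            sid = f"{rid}.p{point}.s{len(synthons)}"
            synthons[sid] = Synthon(
                id=sid,
                smiles=f"[*:{point}]{body}",
                kind="terminal",
                compatible_points=(point,),
            )
            ids.append(sid)
        return tuple(ids)

    for sizes in spec.two_component:
        rid = f"R{rid_counter}"
        rid_counter += 1
        core = _CORES_2[int(rng.integers(len(_CORES_2)))]
        pool = shuffled_vocab()
        lists = {
            "1": add_terminals(rid, "1", sizes[0], pool),
            "2": add_terminals(rid, "2", sizes[1], pool),
        }
        scaffolds.append(
            ReactionScaffold(
                reaction_id=rid,
                n_components=2,
                core_smiles=core,
                points=(("1", "aliphatic"), ("2", "aromatic")),
                synthon_lists=lists,
            )
        )

    for sizes in spec.three_component:
        rid = f"R{rid_counter}"
        rid_counter += 1
        core = _CORES_3[int(rng.integers(len(_CORES_3)))]
        pool = shuffled_vocab()
        lists = {
            "1": add_terminals(rid, "1", sizes[0], pool),
            "2": add_terminals(rid, "2", sizes[1], pool),
            "3": add_terminals(rid, "3", sizes[2], pool),
        }
        scaffolds.append(
            ReactionScaffold(
                reaction_id=rid,
                n_components=3,
                core_smiles=core,
                points=(("1", "aliphatic"), ("2", "aromatic"), ("3", "aliphatic")),
                synthon_lists=lists,
            )
        )

    for t1, nb, t2 in spec.bridge:
        rid = f"R{rid_counter}"
        rid_counter += 1
        pool = shuffled_vocab()
        lists = {
            "1": add_terminals(rid, "1", t1, pool),
            "2": add_terminals(rid, "2", t2, pool),
        }
        bridge_ids = []
        bvocab = list(_BRIDGE_VOCAB)
        rng.shuffle(bvocab)
        if nb > len(bvocab):
            raise ValueError(
                f"bridge-list size {nb} exceeds bridge vocabulary ({len(bvocab)})"
            )
        for _ in range(nb):
            body = bvocab.pop(0)
            sid = f"{rid}.pB.s{len(synthons)}"
            if body == "c1ccc(cc1)":
                smiles = "[*:1]c1ccc([*:2])cc1"
            else:
                smiles = f"[*:1]{body}[*:2]"
            synthons[sid] = Synthon(
                id=sid, smiles=smiles, kind="bridge", compatible_points=("B",)
            )
            bridge_ids.append(sid)
        lists["B"] = tuple(bridge_ids)
        scaffolds.append(
            ReactionScaffold(
                reaction_id=rid,
                n_components=3,
                core_smiles="",
                points=(("1", "aliphatic"), ("B", "aliphatic"), ("2", "aliphatic")),
                synthon_lists=lists,
                is_bridge=True,
            )
        )

    return ReactionLibrary(scaffolds=scaffolds, synthons=synthons).validate()


# ---------------------------------------------------------------------------
# scripted docked poses with known growth outcomes
# ---------------------------------------------------------------------------


@dataclass
class DockedFixture:
    pocket: Pocket
    pose: DockedPose
    expected_productive: bool
    expected_terminations: dict[str, str]  # cap label -> clash|exit ("" = either)
    meta: dict


def _two_atom_pose(
    caps: Sequence[tuple[str, np.ndarray, np.ndarray]], ref: str
) -> DockedPose:
    """Pose made of one anchor atom plus one methyl cap carbon per cap site."""
    coords = []
    sites = {}
    # single shared anchor = first entry's anchor position
    anchor_xyz = caps[0][1]
    coords.append(anchor_xyz)
    for label, _anchor, cap_xyz in caps:
        idx = len(coords)
        coords.append(cap_xyz)
        sites[label] = CapSite(
            label=label,
            cap_type="methyl",
            cap_atom=idx,
            anchor_atom=0,
            members=(idx,),
        )
    return DockedPose(
        fragment_ref=ref,
        elements=("C",) * len(coords),
        coords=np.array(coords, dtype=float),
        dock_score=-20.0,
        caps=sites,
    )


def make_docked_fixture(scenario: str) -> DockedFixture:
    """Pocket-plus-pose scenarios with recorded expected growth outcomes.

    ``cap_into_tunnel``: cap points down an open channel -> productive.
    ``cap_into_wall``: cap points into a dead-end slab -> clash, unproductive.
    ``cap_at_opening``: cap points out of the pocket mouth -> exit with fewer
    than two in-pocket spheres, unproductive.
    ``dual_cap_mixed``: one cap down the channel, one into the sealed end ->
    productive, CapScore taken from the open pathway.
    """
    if scenario == "cap_into_tunnel":
        pocket, meta = make_pocket(PocketSpec(kind="deadend", radius=4.0, length=16.0))
        pose = _two_atom_pose(
            [("1", np.array([0.0, 0.0, 2.0]), np.array([0.0, 0.0, 3.5]))],
            ref="fixture:cap_into_tunnel",
        )
        return DockedFixture(pocket, pose, True, {"1": "exit"}, meta)
    if scenario == "cap_into_wall":
        pocket, meta = make_pocket(PocketSpec(kind="shallow", extent=10.0, layers=3))
        pose = _two_atom_pose(
            [("1", np.array([0.0, 0.0, 4.5]), np.array([0.0, 0.0, 3.0]))],
            ref="fixture:cap_into_wall",
        )
        return DockedFixture(pocket, pose, False, {"1": "clash"}, meta)
    if scenario == "cap_at_opening":
        pocket, meta = make_pocket(PocketSpec(kind="shallow", extent=10.0, layers=3))
        pose = _two_atom_pose(
            [("1", np.array([0.0, 0.0, 2.5]), np.array([0.0, 0.0, 4.0]))],
            ref="fixture:cap_at_opening",
        )
        return DockedFixture(pocket, pose, False, {"1": "exit"}, meta)
    if scenario == "dual_cap_mixed":
        pocket, meta = make_pocket(
            PocketSpec(kind="deadend", radius=4.0, length=16.0, layers=3)
        )
        pose = _two_atom_pose(
            [
                ("A", np.array([0.0, 0.0, 3.5]), np.array([0.0, 0.0, 5.0])),
                ("B", np.array([0.0, 0.0, 3.5]), np.array([0.0, 0.0, 2.0])),
            ],
            ref="fixture:dual_cap_mixed",
        )
        return DockedFixture(pocket, pose, True, {"A": "exit", "B": "clash"}, meta)
    raise ValueError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# packaged desk-scale screen conditions
# ---------------------------------------------------------------------------


def toy_screen_config(seed: int, workdir: str | None = None):
    """The package's default desk-scale screen: library, pocket and budgets.

    One 2-component reaction (12 x 12) plus one 3-component reaction
    (12 x 12 x 12) give a full space of 1872 products represented by ~60
    MEL fragments; the pocket is a dead-end tunnel (radius 4.5 A, length
    14 A, wall spacing 1.5 A); the toy docker runs on a 2 A translation
    lattice with all 24 octahedral orientations; the enumeration budget is
    40 products per selection round and the final set keeps the top 25.

    With ``workdir`` set, the library JSON and pocket PDB are written there
    and the config references them by path (so the run is reproducible from
    files alone); otherwise in-memory objects are used.
    """
    from .capselect import write_pocket_pdb
    from .chem_space import write_reaction_library
    from .pipeline import ScreenConfig

    lib = make_toy_library(
        LibrarySpec(
            two_component=((12, 12),),
            three_component=((12, 12, 12),),
            bridge=(),
            seed=7,
        )
    )
    pocket, _ = make_pocket(
        PocketSpec(kind="deadend", radius=4.5, length=14.0, spacing=1.5, layers=3)
    )
    library = lib
    pocket_arg = pocket
    if workdir is not None:
        from pathlib import Path

        wd = Path(workdir)
        wd.mkdir(parents=True, exist_ok=True)
        write_reaction_library(lib, wd / "library.json")
        write_pocket_pdb(pocket, wd / "pocket.pdb")
        library = str(wd / "library.json")
        pocket_arg = str(wd / "pocket.pdb")
    return ScreenConfig(
        library=library,
        pocket=pocket_arg,
        backend="toy",
        target_enum_count=40,
        top_final=25,
        grid_step=2.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dead-end decoy benchmark (synthetic scores)
# ---------------------------------------------------------------------------


@dataclass
class DecoyScreen:
    """Synthetic selection benchmark with dead-end decoys among the top dockers.

    All scores are synthetic draws, not docking output: decoy fragments get
    slightly *better* docking scores but no growth capacity, and the
    molecules enumerated from them score much worse (the pose flips once the
    cap is replaced by a bulky synthon); productive fragments' products
    retain or improve their scores.
    """

    candidates: list[ScoredCandidate]
    children: Callable[[str], np.ndarray]
    all_children: np.ndarray


def make_decoy_screen(
    seed: int,
    n_mel: int = 150,
    n_children: int = 20,
    decoy_frac: float = 0.4,
    weights: ScoreWeights = ScoreWeights(),
) -> DecoyScreen:
    rng = np.random.default_rng(seed)
    candidates = []
    child_map: dict[str, np.ndarray] = {}
    for i in range(n_mel):
        ref = f"mel{i:04d}"
        decoy = rng.random() < decoy_frac
        dock = float(rng.normal(-25.0, 2.0) - (3.0 if decoy else 0.0))
        cap = int(rng.integers(0, 2)) if decoy else int(2 + rng.poisson(3))
        candidates.append(
            ScoredCandidate(
                fragment_ref=ref,
                dock_score=dock,
                cap_score=cap,
                merged_score=merged_score(dock, cap, weights),
                productive=cap >= 2,
            )
        )
        if decoy:
            kids = dock + rng.uniform(4.0, 9.0, size=n_children)
        else:
            kids = dock - rng.uniform(0.0, 3.0, size=n_children)
        child_map[ref] = kids
    all_children = np.concatenate([child_map[c.fragment_ref] for c in candidates])
    return DecoyScreen(
        candidates=candidates,
        children=lambda ref: child_map[ref],
        all_children=all_children,
    )
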