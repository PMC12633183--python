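"""Docking-backend contract, a deterministic toy rigid docker, and the
merged docking/growth score used to rank fragments.

The production docking engine is pluggable: any object exposing
``name``, ``deterministic`` and ``dock(mol, pocket, ...) -> [DockedPose]``
(scores lower-is-better) can be registered.  The built-in toy docker is an
exhaustive rigid-body search over a translation lattice anchored to the
pocket bounding box crossed with the 24 proper rotations of the octahedral
group, scored by a contact-counting function:

    score = 10 * #(ligand-pocket pairs closer than 2.5 A)
          -  1 * #(pairs with distance in [2.5, 4.5] A)

It exists so that the whole pipeline runs deterministically on synthetic
fixtures at desk scale; it does not model electrostatics, hydrogen bonding
or ligand flexibility.

Ranking combines the docking score with the growth capacity (CapScore) as

    MergedScore = -dock_score + w_cap * ln(1 + cap_score)

(higher is better; the sign flip keeps the lower-is-better docking
convention everywhere else).  With ``w_cap = 0`` and all candidates
productive, the MergedScore ordering reduces to the plain docking-score
("greedy") ordering.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from typing import Protocol, Sequence

import numpy as np

from .capselect import CapSite, DockedPose, Pocket

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreWeights:
    """CapScore weight in the merged ranking score."""

    w_cap: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.w_cap) or self.w_cap < 0:
            raise ValueError("w_cap must be finite and >= 0")


def merged_score(dock_score: float, cap_score: int, w: ScoreWeights = ScoreWeights()) -> float:
    """Weighted logarithmic combination of docking score and CapScore."""
    if cap_score < 0:
        raise ValueError("cap_score must be >= 0")
    if not (math.isfinite(dock_score) and math.isfinite(cap_score)):
        raise ValueError("scores must be finite")
    return -dock_score + w.w_cap * math.log1p(cap_score)


@dataclass
class ScoredCandidate:
    """One fragment with its docking, growth and merged scores."""

    fragment_ref: str
    dock_score: float
    cap_score: int
    merged_score: float
    productive: bool
    rank: int | None = None


def rank_candidates(
    cands: Sequence[ScoredCandidate], mode: str = "capselect"
) -> list[ScoredCandidate]:
    """Rank candidates for enumeration.

    ``capselect`` drops unproductive fragments and sorts by MergedScore
    descending; ``greedy`` sorts by docking score ascending and ignores
    productivity.  Ties break on ``fragment_ref`` for determinism.
    """
    if not cands:
        raise ValueError("cannot rank an empty candidate list")
    if mode == "capselect":
        pool = [c for c in cands if c.productive]
        if not pool:
            log.warning("all %d candidates are unproductive", len(cands))
            return []
        key = lambda c: (-c.merged_score, c.fragment_ref)
    elif mode == "greedy":
        pool = list(cands)
        key = lambda c: (c.dock_score, c.fragment_ref)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    ranked = sorted(pool, key=key)
    return [replace(c, rank=i + 1) for i, c in enumerate(ranked)]


# ---------------------------------------------------------------------------
# toy rigid docker
# ---------------------------------------------------------------------------


class DockingBackend(Protocol):
    """Minimal docking-engine contract."""

    name: str
    deterministic: bool

    def dock(
        self,
        mol,
        pocket: Pocket,
        fragment_ref: str = "",
        caps: dict[str, CapSite] | None = None,
    ) -> list[DockedPose]: ...


def octahedral_rotations() -> np.ndarray:
    """The 24 proper rotations of the octahedral group, in a fixed order."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1.0, -1.0), repeat=3):
            m = np.zeros((3, 3))
            for i in range(3):
                m[i, perm[i]] = signs[i]
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    mats.sort(key=lambda m: tuple(m.ravel()))
    return np.array(mats)


_CONTACT_LO2 = 2.5**2
_CONTACT_HI2 = 4.5**2


def toy_dock(
    mol,
    pocket: Pocket,
    grid_step: float = 1.0,
    n_orientations: int = 24,
    top_k: int = 1,
    fragment_ref: str = "",
    caps: dict[str, CapSite] | None = None,
    padding: float = 2.0,
) -> list[DockedPose]:
    """Exhaustive deterministic rigid docking of one conformer.

    Translations cover the pocket bounding box padded by ``padding`` at
    ``grid_step`` spacing; orientations are the first ``n_orientations``
    octahedral rotations applied about the ligand centroid.  Poses are
    returned sorted by ``(score, grid index, orientation index)``.
    """
    if mol.GetNumAtoms() == 0 or mol.GetNumConformers() == 0:
        raise ValueError("molecule must have atoms and a 3D conformer")
    conf = mol.GetConformer()
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())], dtype=float
    )
    lig0 = coords - coords.mean(axis=0)
    pk = pocket.coords
    lo = pk.min(axis=0) - padding
    hi = pk.max(axis=0) + padding
    axes = [np.arange(lo[d], hi[d] + 1e-9, grid_step) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    rots = octahedral_rotations()[:n_orientations]

    n_grid = len(grid)
    g2 = (grid**2).sum(axis=1)  # (G,)
    all_scores = np.empty((len(rots), n_grid), dtype=np.int64)
    chunk = max(1, int(8_000_000 // max(1, len(lig0) * len(pk))))
    for oi, rot in enumerate(rots):
        rl = lig0 @ rot.T  # (L, 3)
        diff = (rl[:, None, :] - pk[None, :, :]).reshape(-1, 3)  # (L*P, 3)
        diff2 = (diff**2).sum(axis=1)  # (L*P,)
        for start in range(0, n_grid, chunk):
            g = grid[start : start + chunk]
            # |g + a - p|^2 = |g|^2 + 2 g.(a-p) + |a-p|^2, via one matmul
            d2 = g @ diff.T
            d2 *= 2.0
            d2 += diff2[None, :]
            d2 += g2[start : start + len(g), None]
            clash = (d2 < _CONTACT_LO2).sum(axis=1)
            contact = ((d2 >= _CONTACT_LO2) & (d2 <= _CONTACT_HI2)).sum(axis=1)
            all_scores[oi, start : start + len(g)] = 10 * clash - contact
    flat = all_scores.ravel()
    orient_idx = np.repeat(np.arange(len(rots)), n_grid)
    grid_idx = np.tile(np.arange(n_grid), len(rots))
    order = np.lexsort((orient_idx, grid_idx, flat))[:top_k]
    poses = []
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    for k in order:
        oi, gi = int(orient_idx[k]), int(grid_idx[k])
        pose_coords = lig0 @ rots[oi].T + grid[gi]
        poses.append(
            DockedPose(
                fragment_ref=fragment_ref,
                elements=elements,
                coords=pose_coords,
                dock_score=float(flat[k]),
                caps=dict(caps or {}),
            )
        )
    return poses


@dataclass
class ToyDocker:
    """Deterministic exhaustive rigid-body backend for desk-scale runs."""

    grid_step: float = 1.0
    n_orientations: int = 24
    top_k: int = 1
    name: str = "toy"
    deterministic: bool = True

    def dock(
        self,
        mol,
        pocket: Pocket,
        fragment_ref: str = "",
        caps: dict[str, CapSite] | None = None,
    ) -> list[DockedPose]:
        return toy_dock(
            mol,
            pocket,
            grid_step=self.grid_step,
            n_orientations=self.n_orientations,
            top_k=self.top_k,
            fragment_ref=fragment_ref,
            caps=caps,
        )


BACKENDS: dict[str, type] = {"toy": ToyDocker}


def get_backend(name: str, **kwargs) -> DockingBackend:
    try:
        cls = BACKENDS[name]
    except KeyError as exc:
        raise KeyError(
            f"unknown docking backend {name!r}; registered: {sorted(BACKENDS)}"
        ) from exc
    return cls(**kwargs)
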