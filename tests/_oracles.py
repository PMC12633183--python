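"""Independently coded reference implementations used only by the tests.

These re-derive the published geometric rules with explicit loops and plain
math so the package's vectorized greedy search can be checked against an
exhaustive scan that shares no code with it (the deterministic local-frame
convention of the direction grid is part of the algorithm definition and is
therefore shared).
"""

from __future__ import annotations

import math

import numpy as np


def oracle_mesh(axis, half_angle_deg: float) -> list[np.ndarray]:
    ax = np.asarray(axis, dtype=float)
    ax = ax / math.sqrt(float((ax**2).sum()))
    ref = np.array([0.0, 0.0, 1.0]) if abs(ax[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, ax)
    e1 = e1 / math.sqrt(float((e1**2).sum()))
    e2 = np.cross(ax, e1)
    dirs = []
    for t in range(36):
        theta_deg = 5.0 * t
        if theta_deg > half_angle_deg + 1e-9:
            break
        if t == 0:
            dirs.append(ax.copy())
            continue
        theta = math.radians(theta_deg)
        for p in range(72):
            phi = math.radians(5.0 * p)
            v = (
                math.sin(theta) * math.cos(phi) * e1
                + math.sin(theta) * math.sin(phi) * e2
                + math.cos(theta) * ax
            )
            dirs.append(v)
    return dirs


def _min_dist(point: np.ndarray, atoms: np.ndarray) -> float:
    return float(np.sqrt(((atoms - point) ** 2).sum(axis=1)).min())


def oracle_grow(
    cap_xyz,
    anchor_xyz,
    cap_type: str,
    pocket_xyz,
    ligand_xyz,
    sphere_radius: float = 2.0,
    clearance: float = 2.0,
    half_angle: float = 60.0,
    d_solvent: float = 8.0,
    exit_path: float = 10.0,
    max_spheres: int = 60,
):
    """Exhaustive-scan re-implementation of greedy sphere growth.

    Returns ``(centers, termination, n_grown)`` where ``centers`` includes
    the initial cap sphere.
    """
    pocket_xyz = np.asarray(pocket_xyz, dtype=float)
    ligand_xyz = np.asarray(ligand_xyz, dtype=float).reshape(-1, 3)
    c = np.asarray(cap_xyz, dtype=float)
    r = 3.0 if cap_type == "methyl" else 3.5
    centers = [c.copy()]
    axis = c - np.asarray(anchor_xyz, dtype=float)
    out_path = 0.0
    n_grown = 0
    termination = "exit"
    for _ in range(max_spheres):
        step = r + sphere_radius
        best = None
        best_dist = -1.0
        for u in oracle_mesh(axis, half_angle):
            cand = centers[-1] + step * u
            dp = _min_dist(cand, pocket_xyz)
            if dp < clearance:
                continue
            if len(ligand_xyz) and _min_dist(cand, ligand_xyz) < clearance:
                continue
            if dp > best_dist:  # strict: first maximum wins
                best_dist = dp
                best = cand
        if best is None:
            termination = "clash"
            break
        axis = best - centers[-1]
        centers.append(best)
        r = sphere_radius
        if best_dist > d_solvent:
            out_path += step
            if out_path > exit_path:
                termination = "exit"
                break
        else:
            out_path = 0.0
            n_grown += 1
    return centers, termination, n_grown


def oracle_rmsd(xa, xb, pairs) -> float:
    """Plain sum-of-squares RMSD over mapped index pairs."""
    total = 0.0
    for i, j in pairs:
        d = 0.0
        for k in range(3):
            d += (xa[i][k] - xb[j][k]) ** 2
        total += d
    return math.sqrt(total / len(pairs))


def random_growth_case(seed: int):
    """A seeded random pocket cloud plus a random capped two-atom pose."""
    rng = np.random.default_rng(seed)
    n_atoms = int(rng.integers(40, 90))
    pocket = rng.uniform(-8.0, 8.0, size=(n_atoms, 3))
    anchor = rng.uniform(-2.0, 2.0, size=3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    cap = anchor + 1.5 * direction
    cap_type = "methyl" if rng.random() < 0.5 else "phenyl"
    n_extra = int(rng.integers(0, 4))
    extra = anchor + rng.uniform(-2.0, 2.0, size=(n_extra, 3))
    ligand = np.vstack([anchor[None, :], extra])
    return pocket, anchor, cap, cap_type, ligand
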