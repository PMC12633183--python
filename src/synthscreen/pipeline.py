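"""Hierarchical screen orchestration.

The four stages — dock the minimal enumeration library, classify pose
productivity by sphere growth, enumerate the selected fragments, re-dock —
run once for 2-component chemistry and iterate for 3-component chemistry
(the selection/enumeration cycle repeats until no partially enumerated
intermediates remain).  Selection walks the ranked fragment list and stops
at the first fragment whose eventual spawn brings the cumulative product
count to the enumeration budget.

The point of the hierarchy is the resource reduction: the number of
molecules ever docked is |MEL| plus the budgeted enumerations, while the
space represented is the full combinatorial product; the ratio is reported
as ``reduction_factor``.

Post-processing applies physicochemical windows, an optional PAINS
substructure list, and leader-style Tanimoto diversity clustering to the
final scored set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdMolDescriptors
from rdkit.DataStructs import TanimotoSimilarity

from .capselect import CapSelectParams, DockedPose, Pocket, cap_result, cap_sites_from_mol
from .chem_space import (
    EnumeratedMolecule,
    MELFragment,
    ReactionLibrary,
    build_mel,
    count_full_space,
    enumerate_at,
    parse_reaction_library,
    spawn_count,
    write_smiles,
)
from .evaluation import PoseRecord
from .scoring import ScoreWeights, ScoredCandidate, get_backend, merged_score, rank_candidates

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class FilterRules:
    """Post-processing filter windows (all optional)."""

    mw_min: float | None = None
    mw_max: float | None = None
    heavy_atoms_max: int | None = None
    hbd_max: int | None = None
    hba_max: int | None = None
    rotatable_max: int | None = None
    pains_path: str | None = None  # file of SMARTS patterns, one per line
    diversity_threshold: float | None = None  # Tanimoto similarity cutoff

    def is_empty(self) -> bool:
        return all(
            getattr(self, f.name) is None for f in dataclasses.fields(self)
        )


@dataclass
class ScreenConfig:
    """Configuration of one hierarchical screen."""

    library: str | ReactionLibrary
    pocket: str | Pocket
    backend: str = "toy"
    target_enum_count: int = 1_000_000
    top_final: int = 10_000
    capselect: CapSelectParams = field(default_factory=CapSelectParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    rank_mode: str = "capselect"
    capselect_first_round: bool = True
    grid_step: float = 1.0
    n_orientations: int = 24
    filters: FilterRules | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.target_enum_count <= 0 or self.top_final <= 0:
            raise ValueError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "capselect" in data:
            data["capselect"] = CapSelectParams(**data["capselect"])
        if "weights" in data:
            data["weights"] = ScoreWeights(**data["weights"])
        if "filters" in data and data["filters"] is not None:
            data["filters"] = FilterRules(**data["filters"])
        return cls(**data)


@dataclass
class EnumerationPlan:
    """Ranked fragments chosen for enumeration, with spawn accounting."""

    selected: list[str]
    spawn_counts: dict[str, int]
    cumulative_total: int


@dataclass
class ScreenResult:
    mel_table: pd.DataFrame
    round_tables: list[pd.DataFrame]
    final_table: pd.DataFrame
    plans: list[EnumerationPlan]
    stats: dict
    fragments: dict[str, MELFragment]
    molecules: dict[str, EnumeratedMolecule]
    poses: dict[str, DockedPose]
    rejections: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_mels(
    ranked: Sequence[ScoredCandidate],
    lib: ReactionLibrary,
    target: int,
    fragments: Mapping[str, MELFragment | EnumeratedMolecule],
) -> EnumerationPlan:
    """Walk the ranked list, accumulating spawn counts until the budget.

    Each fragment's spawn count is the product of synthon-list sizes over
    its not-yet-enumerated attachment points; selection stops at the first
    fragment whose inclusion reaches ``target``.
    """
    if not ranked:
        raise ValueError("empty ranked candidate list")
    selected: list[str] = []
    spawns: dict[str, int] = {}
    total = 0
    for cand in ranked:
        frag = fragments[cand.fragment_ref]
        k = spawn_count(frag, lib)
        selected.append(cand.fragment_ref)
        spawns[cand.fragment_ref] = k
        total += k
        if total >= target:
            break
    else:
        log.warning(
            "budget %d exceeds the library's remaining output (%d); "
            "all ranked fragments selected",
            target,
            total,
        )
    return EnumerationPlan(selected=selected, spawn_counts=spawns, cumulative_total=total)


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------


def _mol_seed(base_seed: int, mol_id: str) -> int:
    return (zlib.crc32(mol_id.encode()) ^ base_seed) & 0x7FFFFFFF


def embed_3d(mol: Chem.Mol, seed: int) -> Chem.Mol | None:
    """Deterministic single-conformer embedding (heavy atoms)."""
    m = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(m, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(m, params) != 0:
            return None
    return Chem.RemoveHs(m)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def run_screen(cfg: ScreenConfig) -> ScreenResult:
    """Execute the full hierarchical screen described by ``cfg``."""
    lib = (
        cfg.library
        if isinstance(cfg.library, ReactionLibrary)
        else parse_reaction_library(cfg.library)
    )
    pocket = cfg.pocket if isinstance(cfg.pocket, Pocket) else Pocket.from_pdb(cfg.pocket)
    backend = get_backend(
        cfg.backend, grid_step=cfg.grid_step, n_orientations=cfg.n_orientations
    )

    full_space = count_full_space(lib)
    mels = build_mel(lib)
    fragments: dict[str, MELFragment] = {f.mel_id: f for f in mels}
    poses: dict[str, DockedPose] = {}
    molecules: dict[str, EnumeratedMolecule] = {}

    def dock_and_classify(frags, with_capselect=True):
        rows, cands, failures = [], [], 0
        for frag in frags:
            ref = _ref(frag)
            mol3d = embed_3d(frag.mol, _mol_seed(cfg.seed, ref))
            if mol3d is None:
                failures += 1
                log.warning("embedding failed for %s", ref)
                continue
            try:
                pose_list = backend.dock(
                    mol3d, pocket, fragment_ref=ref, caps=cap_sites_from_mol(frag.mol)
                )
            except Exception as exc:
                failures += 1
                log.warning("docking failed for %s: %s", ref, exc)
                continue
            if not pose_list:
                failures += 1
                continue
            pose = pose_list[0]
            poses[ref] = pose
            if with_capselect and frag.remaining_caps:
                res = cap_result(pose, pocket, cfg.capselect)
                cap_score, productive = res.cap_score, res.productive
            else:
                cap_score, productive = 0, True
            cands.append(
                ScoredCandidate(
                    fragment_ref=ref,
                    dock_score=pose.dock_score,
                    cap_score=cap_score,
                    merged_score=merged_score(pose.dock_score, cap_score, cfg.weights),
                    productive=productive,
                )
            )
            rows.append(
                {
                    "id": ref,
                    "dock_score": pose.dock_score,
                    "cap_score": cap_score,
                    "merged_score": cands[-1].merged_score,
                    "productive": productive,
                }
            )
        if frags and failures > 0.5 * len(list(frags)):
            raise RuntimeError(
                f"{failures}/{len(list(frags))} molecules failed docking; aborting"
            )
        return pd.DataFrame(rows), cands, failures

    mel_table, cands, _ = dock_and_classify(mels)
    n_docked = len(mel_table)

    current_cands = cands
    current_frags: dict[str, MELFragment | EnumeratedMolecule] = dict(fragments)
    round_tables: list[pd.DataFrame] = []
    plans: list[EnumerationPlan] = []
    finals: dict[str, EnumeratedMolecule] = {}
    round_idx = 0
    while True:
        mode = cfg.rank_mode
        if round_idx == 0 and not cfg.capselect_first_round:
            mode = "greedy"
        ranked = rank_candidates(current_cands, mode)
        if not ranked:
            log.warning("no productive candidates at round %d; stopping", round_idx)
            break
        plan = select_mels(ranked, lib, cfg.target_enum_count, current_frags)
        plans.append(plan)
        products: list[EnumeratedMolecule] = []
        for ref in plan.selected:
            frag = current_frags[ref]
            products.extend(enumerate_at(frag, frag.remaining_caps[0], lib))
        for p in products:
            molecules[p.mol_id] = p
        intermediates = [p for p in products if p.remaining_caps]
        finals.update({p.mol_id: p for p in products if not p.remaining_caps})
        if not intermediates:
            break
        table, current_cands, _ = dock_and_classify(intermediates)
        n_docked += len(table)
        table.insert(0, "round", round_idx + 1)
        round_tables.append(table)
        current_frags = {p.mol_id: p for p in intermediates}
        round_idx += 1

    final_list = [finals[k] for k in sorted(finals)]
    final_table, final_cands, _ = dock_and_classify(final_list, with_capselect=False)
    n_docked += len(final_table)
    if len(final_table):
        final_table = final_table.sort_values(
            ["dock_score", "id"], kind="stable"
        ).reset_index(drop=True)
        final_table["rank"] = np.arange(1, len(final_table) + 1)
        final_table = final_table.head(cfg.top_final)
        final_table["parent_id"] = [
            molecules[i].parent_id for i in final_table["id"]
        ]
        final_table["mel_id"] = [
            molecules[i].parent_mel_id for i in final_table["id"]
        ]

    rejections = None
    if cfg.filters is not None and len(final_table):
        entries = [
            (row["id"], molecules[row["id"]].mol, row["merged_score"])
            for _, row in final_table.iterrows()
        ]
        kept_ids, rej = postprocess_filter(entries, cfg.filters)
        rejections = rej
        final_table = final_table[final_table["id"].isin(kept_ids)].reset_index(
            drop=True
        )

    stats = {
        "full_space": full_space,
        "n_mel": len(mels),
        "n_mel_docked": int(len(mel_table)),
        "n_docked_total": int(n_docked),
        "plan_totals": [p.cumulative_total for p in plans],
        "n_rounds": len(plans),
        "n_final_docked": int(len(final_cands)),
        "reduction_factor": full_space / max(n_docked, 1),
    }

    result = ScreenResult(
        mel_table=mel_table,
        round_tables=round_tables,
        final_table=final_table,
        plans=plans,
        stats=stats,
        fragments=fragments,
        molecules=molecules,
        poses=poses,
        rejections=rejections,
    )
    if cfg.out_dir:
        persist_result(result, cfg.out_dir)
    return result


def _ref(frag) -> str:
    return getattr(frag, "mel_id", None) or getattr(frag, "mol_id")


# ---------------------------------------------------------------------------
# result persistence & pose records
# ---------------------------------------------------------------------------


def persist_result(result: ScreenResult, out_dir: str | Path) -> None:
    """Write stage tables, SMILES, poses (SDF) and provenance sidecars."""
    from .poseio import write_poses_sdf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.mel_table.to_csv(out / "mel_table.csv", index=False)
    for i, table in enumerate(result.round_tables, start=1):
        table.to_csv(out / f"round{i}_table.csv", index=False)
    result.final_table.to_csv(out / "final_table.csv", index=False)
    with open(out / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=1)
    with open(out / "plans.json", "w") as fh:
        json.dump(
            [dataclasses.asdict(p) for p in result.plans], fh, indent=1
        )
    write_smiles(result.fragments.values(), out / "mel.smi")
    if result.molecules:
        write_smiles(result.molecules.values(), out / "enumerated.smi")

    mel_ids = set(result.fragments)
    inter_ids = {
        i for i, m in result.molecules.items() if m.remaining_caps
    }
    final_ids = set(result.final_table["id"]) if len(result.final_table) else set()
    write_poses_sdf(
        [result.poses[i] for i in sorted(mel_ids) if i in result.poses],
        out / "mel_poses.sdf",
    )
    if inter_ids:
        write_poses_sdf(
            [result.poses[i] for i in sorted(inter_ids) if i in result.poses],
            out / "round1_poses.sdf",
        )
    write_poses_sdf(
        [result.poses[i] for i in sorted(final_ids) if i in result.poses],
        out / "final_poses.sdf",
    )
    origins = {}
    parents = {}
    for ref, frag in result.fragments.items():
        origins[ref] = _origin_list(frag)
        parents[ref] = {"parent": None, "root": ref}
    for ref, m in result.molecules.items():
        origins[ref] = _origin_list(m)
        parents[ref] = {"parent": m.parent_id, "root": m.parent_mel_id}
    (out / "origins.json").write_text(json.dumps(origins))
    (out / "parents.json").write_text(json.dumps(parents))


def _origin_list(frag) -> list[str]:
    prov = frag.provenance
    return [prov.get(i, "") for i in range(frag.mol.GetNumAtoms())]


def pose_records(result: ScreenResult, stage: str) -> dict[str, PoseRecord]:
    """PoseRecords for one stage of an in-memory screen result.

    ``stage`` is ``mel``, ``round1`` (partially enumerated intermediates) or
    ``final``.
    """
    if stage == "mel":
        ids = [i for i in result.fragments if i in result.poses]
        meta = {i: (None, i) for i in ids}
    elif stage.startswith("round"):
        ids = [
            i
            for i, m in result.molecules.items()
            if m.remaining_caps and i in result.poses
        ]
        meta = {
            i: (result.molecules[i].parent_id, result.molecules[i].parent_mel_id)
            for i in ids
        }
    elif stage == "final":
        ids = (
            [i for i in result.final_table["id"] if i in result.poses]
            if len(result.final_table)
            else []
        )
        meta = {
            i: (result.molecules[i].parent_id, result.molecules[i].parent_mel_id)
            for i in ids
        }
    else:
        raise ValueError(f"unknown stage {stage!r}")
    records = {}
    for i in ids:
        frag = result.fragments.get(i) or result.molecules[i]
        parent, root = meta[i]
        records[i] = PoseRecord(
            ref=i,
            parent=parent,
            root=root,
            origins=_origin_list(frag),
            coords=result.poses[i].coords,
            dock_score=result.poses[i].dock_score,
        )
    return records


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def postprocess_filter(
    entries: Sequence[tuple[str, Chem.Mol, float]],
    rules: FilterRules,
) -> tuple[list[str], pd.DataFrame]:
    """Apply physicochemical windows, PAINS patterns and diversity selection.

    ``entries`` are ``(id, molecule, score)`` with score higher-is-better.
    Returns the surviving ids (input order) and a table of rejections tagged
    with the rule that fired.
    """
    rejections: list[dict] = []
    pains = _load_pains(rules.pains_path) if rules.pains_path else []
    survivors: list[tuple[str, Chem.Mol, float]] = []
    for mol_id, mol, score in entries:
        reason = _physchem_reason(mol, rules)
        if reason is None:
            for name, patt in pains:
                if mol.HasSubstructMatch(patt):
                    reason = f"PAINS:{name}"
                    break
        if reason is not None:
            rejections.append({"id": mol_id, "reason": reason})
        else:
            survivors.append((mol_id, mol, score))
    if rules.diversity_threshold is not None and survivors:
        kept, dropped = diversity_cluster(survivors, rules.diversity_threshold)
        rejections.extend({"id": i, "reason": "diversity"} for i in dropped)
        survivors = kept
    return [s[0] for s in survivors], pd.DataFrame(
        rejections, columns=["id", "reason"]
    )


def _physchem_reason(mol: Chem.Mol, rules: FilterRules) -> str | None:
    mw = Descriptors.MolWt(mol)
    if rules.mw_min is not None and mw < rules.mw_min:
        return "MW"
    if rules.mw_max is not None and mw > rules.mw_max:
        return "MW"
    if (
        rules.heavy_atoms_max is not None
        and mol.GetNumHeavyAtoms() > rules.heavy_atoms_max
    ):
        return "heavy_atoms"
    if rules.hbd_max is not None and rdMolDescriptors.CalcNumHBD(mol) > rules.hbd_max:
        return "HBD"
    if rules.hba_max is not None and rdMolDescriptors.CalcNumHBA(mol) > rules.hba_max:
        return "HBA"
    if (
        rules.rotatable_max is not None
        and rdMolDescriptors.CalcNumRotatableBonds(mol) > rules.rotatable_max
    ):
        return "rotatable"
    return None


def _load_pains(path: str) -> list[tuple[str, Chem.Mol]]:
    patterns = []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smarts, name = parts[0], (parts[1] if len(parts) > 1 else f"p{k}")
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"malformed PAINS pattern on line {k + 1}: {smarts!r}")
        patterns.append((name, patt))
    return patterns


def diversity_cluster(
    entries: Sequence[tuple[str, Chem.Mol, float]],
    similarity_threshold: float,
) -> tuple[list[tuple[str, Chem.Mol, float]], list[str]]:
    """Leader clustering on Morgan fingerprints (Tanimoto).

    Entries are processed best-score-first, so every cluster leader is its
    cluster's top scorer; deterministic for a fixed input.
    """
    if not 0 < similarity_threshold < 1:
        raise ValueError("similarity_threshold must be in (0, 1)")
    from rdkit.Chem import rdFingerprintGenerator

    morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    gen_fp = morgan.GetFingerprint
    ordered = sorted(entries, key=lambda e: (-e[2], e[0]))
    leaders: list[tuple[str, Chem.Mol, float]] = []
    leader_fps = []
    dropped: list[str] = []
    for mol_id, mol, score in ordered:
        fp = gen_fp(mol)
        if any(
            TanimotoSimilarity(fp, lfp) >= similarity_threshold for lfp in leader_fps
        ):
            dropped.append(mol_id)
        else:
            leaders.append((mol_id, mol, score))
            leader_fps.append(fp)
    return leaders, dropped
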