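"""Internal assessments: pose reproducibility (RMSD) and enrichment factors.

Pose reproducibility asks whether the placement of a minimal-enumeration
fragment survives enumeration: the RMSD between a fragment pose and the
matching moiety of its enumerated product is computed **in place** (both
poses share the receptor frame; no superposition), over heavy atoms matched
by provenance tags and excluding the isotope-labelled cap groups of the
smaller fragment.  Summaries report the median, quartiles (linear
interpolation), and the percentage of pairs with RMSD strictly below 3 A; a
"flip" — the product adopting a different orientation — surfaces as a value
well above 3 A.

The enrichment factor EF_T compares the hierarchical screen's final set
against an equally sized property-matched random sample of the full space:
with the score cutoff set at the T-th best score of the test set,

    EF_T = (hits_test / n_test) / (hits_baseline / n_baseline).

When the baseline contains no hits at the cutoff the EF is computed with a
baseline count of one and flagged ``censored`` (a finite lower bound rather
than infinity).  Property matching uses heavy-atom-count bins of width 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .capselect import DockedPose
from .chem_space import ReactionLibrary, enumerate_full_space

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RMSD machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomMapping:
    """Injective heavy-atom index pairs between two poses."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        a_idx = [i for i, _ in self.pairs]
        b_idx = [j for _, j in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise ValueError("atom mapping must be injective")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_origins(
        cls, origins_a: Sequence[str], origins_b: Sequence[str]
    ) -> "AtomMapping":
        """Match atoms by provenance tag, excluding A's cap-group atoms."""
        b_index = {tag: j for j, tag in enumerate(origins_b) if tag}
        pairs = []
        for i, tag in enumerate(origins_a):
            if not tag or tag.startswith("cap:"):
                continue
            j = b_index.get(tag)
            if j is not None:
                pairs.append((i, j))
        return cls(pairs=tuple(pairs))


def pose_rmsd(
    a: DockedPose | np.ndarray, b: DockedPose | np.ndarray, m: AtomMapping
) -> float:
    """In-place heavy-atom RMSD over mapped pairs (no superposition)."""
    xa = a.coords if isinstance(a, DockedPose) else np.asarray(a, dtype=float)
    xb = b.coords if isinstance(b, DockedPose) else np.asarray(b, dtype=float)
    if len(m) < 3:
        raise ValueError("need at least 3 mapped atom pairs")
    ia = np.array([i for i, _ in m.pairs])
    ib = np.array([j for _, j in m.pairs])
    if ia.max() >= len(xa) or ib.max() >= len(xb):
        raise IndexError("mapping index out of range")
    d2 = ((xa[ia] - xb[ib]) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


@dataclass(frozen=True)
class RmsdSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    pct_below_3A: float
    n: int


def rmsd_stats(values: Sequence[float]) -> RmsdSummary:
    """Median/quartiles (linear interpolation) and % strictly below 3 A."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty RMSD list")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return RmsdSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        pct_below_3A=float(100.0 * (v < 3.0).sum() / v.size),
        n=int(v.size),
    )


@dataclass
class PoseRecord:
    """One pose plus the provenance needed to match it across stages."""

    ref: str
    parent: str | None  # immediate parent fragment id
    root: str | None  # originating MEL fragment id
    origins: list[str]  # provenance tag per heavy atom (pose atom order)
    coords: np.ndarray
    dock_score: float


def rmsd_stage_report(
    mel: Mapping[str, PoseRecord],
    enum1: Mapping[str, PoseRecord],
    enum2: Mapping[str, PoseRecord] | None = None,
    top_k: int | None = None,
) -> dict[str, list[float]]:
    """Per-stage pose-reproducibility RMSD lists.

    For two-stage (2-component) data the single comparison is
    ``mel_vs_enum1``; with a second enumeration stage the three standard
    comparisons are reported (fragment vs intermediate, intermediate vs
    full, fragment vs full).  ``top_k`` restricts each comparison to the
    top-k poses of the later stage by docking score.  Records with broken
    provenance are skipped with a warning.
    """
    report: dict[str, list[float]] = {}
    report["mel_vs_enum1"] = _stage_rmsds(mel, enum1, top_k, link="root_or_parent")
    if enum2 is not None:
        report["enum1_vs_enum2"] = _stage_rmsds(enum1, enum2, top_k, link="parent")
        report["mel_vs_enum2"] = _stage_rmsds(mel, enum2, top_k, link="root")
    return report


def _stage_rmsds(
    early: Mapping[str, PoseRecord],
    late: Mapping[str, PoseRecord],
    top_k: int | None,
    link: str,
) -> list[float]:
    records = sorted(late.values(), key=lambda r: (r.dock_score, r.ref))
    if top_k is not None:
        records = records[:top_k]
    out = []
    n_skipped = 0
    for rec in records:
        if link == "parent":
            key = rec.parent
        elif link == "root":
            key = rec.root
        else:
            key = rec.root if rec.root in early else rec.parent
        src = early.get(key) if key else None
        if src is None:
            n_skipped += 1
            continue
        m = AtomMapping.from_origins(src.origins, rec.origins)
        if len(m) < 3:
            n_skipped += 1
            continue
        out.append(pose_rmsd(src.coords, rec.coords, m))
    if n_skipped:
        log.warning("%d poses skipped for broken provenance links", n_skipped)
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EFResult:
    T: int
    score_cutoff: float
    hits_test: int
    hits_baseline: int
    ef: float
    censored: bool


def enrichment_factor(
    test_scores: Sequence[float], baseline_scores: Sequence[float], T: int
) -> EFResult:
    """Enrichment factor at the cutoff of the T-th best test score."""
    if T < 1:
        raise ValueError("T must be >= 1")
    test = np.sort(np.asarray(test_scores, dtype=float))
    base = np.asarray(baseline_scores, dtype=float)
    if len(test) < T:
        raise ValueError(f"need at least T={T} test scores, got {len(test)}")
    if len(base) == 0:
        raise ValueError("baseline must be non-empty")
    cutoff = float(test[T - 1])
    hits_test = int((test <= cutoff).sum())
    hits_base = int((base <= cutoff).sum())
    censored = hits_base == 0
    denom = max(hits_base, 1) / len(base)
    ef = (hits_test / len(test)) / denom
    return EFResult(
        T=T,
        score_cutoff=cutoff,
        hits_test=hits_test,
        hits_baseline=hits_base,
        ef=float(ef),
        censored=censored,
    )


def sample_baseline(
    lib: ReactionLibrary,
    n: int,
    reference,
    seed: int,
    bin_width: int = 2,
) -> list[tuple[str, object]]:
    """Property-matched random sample of the fully enumerated space.

    Stratified on heavy-atom count (bins of width ``bin_width``) to match
    the reference set's histogram; exact size ``n``; reproducible for a
    fixed seed.  ``reference`` is a sequence of RDKit molecules (or objects
    with a ``mol`` attribute).  When a stratum cannot be filled, the deficit
    spills into the nearest populated bin with a warning.
    """
    if n == 0:
        return []
    ref_mols = [getattr(m, "mol", m) for m in reference]
    if not ref_mols:
        raise ValueError("reference set must be non-empty")
    pool = enumerate_full_space(lib)
    pool_bins = np.array([m.GetNumHeavyAtoms() // bin_width for _, m in pool])
    ref_bins = np.array([m.GetNumHeavyAtoms() // bin_width for m in ref_mols])
    bins, ref_counts = np.unique(ref_bins, return_counts=True)
    # largest-remainder allocation of n over reference bins
    shares = ref_counts * n / ref_counts.sum()
    alloc = np.floor(shares).astype(int)
    remainder = n - alloc.sum()
    order = np.argsort(-(shares - alloc), kind="stable")
    alloc[order[:remainder]] += 1

    rng = np.random.default_rng(seed)
    taken = np.zeros(len(pool), dtype=bool)
    out_idx: list[int] = []

    def draw(bin_value: int, k: int) -> int:
        avail = np.flatnonzero((pool_bins == bin_value) & ~taken)
        pick = rng.choice(avail, size=min(k, len(avail)), replace=False)
        taken[pick] = True
        out_idx.extend(int(i) for i in np.sort(pick))
        return k - len(pick)

    deficits: list[tuple[int, int]] = []
    for b, k in zip(bins, alloc):
        short = draw(int(b), int(k))
        if short:
            deficits.append((int(b), short))
    for b, short in deficits:
        log.warning(
            "baseline stratum (heavy-atom bin %d) short by %d; using nearest bins",
            b,
            short,
        )
        open_bins = np.unique(pool_bins[~taken])
        while short and len(open_bins):
            nearest = int(open_bins[np.argmin(np.abs(open_bins - b))])
            short = draw(nearest, short)
            open_bins = np.unique(pool_bins[~taken])
    if len(out_idx) < n:
        raise ValueError(
            f"full space too small for a baseline of size {n} "
            f"(only {len(out_idx)} available)"
        )
    return [pool[i] for i in out_idx]


# ---------------------------------------------------------------------------
# run-directory evaluation
# ---------------------------------------------------------------------------


def load_pose_records(run_dir: str | Path, stage: str) -> dict[str, PoseRecord]:
    """Load one stage's persisted poses (SDF + provenance sidecar)."""
    from .poseio import read_poses_sdf

    run_dir = Path(run_dir)
    origins = json.loads((run_dir / "origins.json").read_text())
    parents = json.loads((run_dir / "parents.json").read_text())
    records = {}
    for pose in read_poses_sdf(run_dir / f"{stage}_poses.sdf"):
        ref = pose.fragment_ref
        par = parents.get(ref, {})
        records[ref] = PoseRecord(
            ref=ref,
            parent=par.get("parent"),
            root=par.get("root"),
            origins=origins.get(ref, []),
            coords=pose.coords,
            dock_score=pose.dock_score,
        )
    return records


def evaluate_run(run_dir: str | Path, top_k: int | None = None) -> dict:
    """Pose-reproducibility summary for a persisted screen run."""
    run_dir = Path(run_dir)
    mel = load_pose_records(run_dir, "mel")
    stages = sorted(
        p.name.removesuffix("_poses.sdf")
        for p in run_dir.glob("round*_poses.sdf")
    )
    final = load_pose_records(run_dir, "final")
    enum1 = load_pose_records(run_dir, stages[0]) if stages else final
    enum2 = final if stages else None
    report = rmsd_stage_report(mel, enum1, enum2, top_k=top_k)
    return {
        key: rmsd_stats(vals).__dict__ if vals else None
        for key, vals in report.items()
    }
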