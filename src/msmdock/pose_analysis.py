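"""Docked-pose contact analysis, site classification and MSM weighting.

Given docked ligand poses (heavy-atom coordinates plus a docking score, a
[0, 1] pose-quality score and optionally a predicted pKi), this module
computes residue contacts at a 4 Å heavy-atom cutoff, classifies each pose
into one of five site categories (flap only, hinge only, flap–hinge
interface, active site, other), filters high-quality poses (quality ≥ 0.5),
selects the best pose per compound/state, summarizes per-residue contact
frequencies, averages site scores under the MSM equilibrium distribution,
and computes the ensemble pocket-probability enrichment table that locates
a cryptic pocket relative to a reference conformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures_io import ProteinStructure, RegionDefinition, SelectionError
from .ligsite import ResiduePocketScore

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0      # Å, ligand heavy atom to protein heavy atom
DEFAULT_QUALITY_THRESHOLD = 0.5   # "high quality" pose-probability threshold

SITE_CATEGORIES = ("flap_only", "hinge_only", "flap_hinge_interface", "active_site", "other")


@dataclass
class PoseRecord:
    """One docked ligand pose with its scores."""

    compound_id: str
    state_id: int
    site_label: str                    # identity of the docking box used
    ligand_atoms: np.ndarray           # (n, 3) heavy-atom coordinates, Å
    docking_score: float               # kcal/mol, more negative = better
    quality_score: float               # [0, 1] pose-quality probability
    predicted_pki: float | None = None

    def __post_init__(self) -> None:
        self.ligand_atoms = np.atleast_2d(np.asarray(self.ligand_atoms, float))
        if self.ligand_atoms.shape[0] < 1 or self.ligand_atoms.shape[1] != 3:
            raise ValueError("pose needs at least one (x, y, z) ligand atom")
        if not 0.0 <= self.quality_score <= 1.0:
            raise ValueError("quality score must lie in [0, 1]")


@dataclass(frozen=True)
class SiteAssignment:
    category: str

    def __post_init__(self) -> None:
        if self.category not in SITE_CATEGORIES:
            raise ValueError(f"unknown site category {self.category!r}")


def find_contacts(
    pose: PoseRecord, s: ProteinStructure, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> set[int]:
    """Residues with a protein heavy atom within ``cutoff`` Å of the ligand."""
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    mask = s.heavy_mask & s.protein_mask
    tree = cKDTree(s.coord[mask])
    res_ids = s.res_id[mask]
    hits: set[int] = set()
    for near in tree.query_ball_point(pose.ligand_atoms, cutoff):
        hits.update(int(r) for r in res_ids[near])
    return hits


def classify_pose(
    contacts: Iterable[int],
    flap: RegionDefinition,
    hinge: RegionDefinition,
    active_site: RegionDefinition,
) -> SiteAssignment:
    """Assign a pose's contact set to exactly one site category.

    Contacting both a flap and a hinge residue means the pose sits in the
    flap–hinge interface, which takes precedence over everything else.
    Otherwise a pose touching any catalytic residue is an active-site pose
    (the co-occurrence with a single flap or hinge contact is logged, since
    the two readings are ambiguous); then flap-only, hinge-only, and
    finally ``other``.  Every contact set maps to exactly one category.
    """
    c = set(int(r) for r in contacts)
    in_flap = bool(c & flap.residue_numbers)
    in_hinge = bool(c & hinge.residue_numbers)
    in_active = bool(c & active_site.residue_numbers)
    if in_flap and in_hinge:
        return SiteAssignment("flap_hinge_interface")
    if in_active:
        if in_flap or in_hinge:
            logger.info(
                "pose contacts the active site and the %s; labeling active_site",
                "flap" if in_flap else "hinge",
            )
        return SiteAssignment("active_site")
    if in_flap:
        return SiteAssignment("flap_only")
    if in_hinge:
        return SiteAssignment("hinge_only")
    return SiteAssignment("other")


def filter_high_quality(
    poses: Sequence[PoseRecord], threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> list[PoseRecord]:
    """Poses with ``quality_score >= threshold`` (inclusive), order kept."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [p for p in poses if p.quality_score >= threshold]


def best_pose_per_state(
    poses: Sequence[PoseRecord],
) -> dict[tuple[str, int], PoseRecord]:
    """Best pose per (compound, state): max quality, ties by docking score.

    The tie-break prefers the more negative (better) docking score, then
    input order.
    """
    best: dict[tuple[str, int], PoseRecord] = {}
    for pose in poses:
        key = (pose.compound_id, pose.state_id)
        cur = best.get(key)
        if cur is None:
            best[key] = pose
        elif pose.quality_score > cur.quality_score or (
            pose.quality_score == cur.quality_score
            and pose.docking_score < cur.docking_score
        ):
            best[key] = pose
    return best


def residue_contact_frequency(
    poses: Sequence[PoseRecord],
    s: ProteinStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[int, float]:
    """Fraction of poses whose contact set contains each residue.

    Intended for the high-quality subset; painting the result into the
    B-factor column visualizes where crystal-like poses concentrate.
    """
    if not poses:
        raise ValueError("no poses to analyze")
    counts: dict[int, int] = {int(r): 0 for r in s.residue_ids()}
    for pose in poses:
        for r in find_contacts(pose, s, cutoff=cutoff):
            counts[r] = counts.get(r, 0) + 1
    n = len(poses)
    return {r: c / n for r, c in counts.items()}


def write_contact_frequency_pdb(
    s: ProteinStructure, frequency: Mapping[int, float], path
) -> None:
    """Write the structure with per-residue contact frequency as B-factors."""
    from .structures_io import write_structure

    b = np.array([frequency.get(int(r), 0.0) for r in s.res_id])
    write_structure(s, path, b_factor=b)


def msm_weighted_site_score(
    site_scores: Mapping[str, Mapping[int, float]],
    pi: np.ndarray,
) -> dict[str, float]:
    """Equilibrium-weighted average score per site category.

    ``site_scores[category][state_id]`` is the best pose-quality score for
    that category in that state; states where the category has no pose (the
    pocket was absent, so docking there was omitted) contribute 0.  ``pi``
    must be a probability vector aligned to state ids ``0..n-1``.
    """
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise ValueError("pi must be a probability vector summing to 1")
    out: dict[str, float] = {}
    for category, per_state in site_scores.items():
        total = 0.0
        for state, score in per_state.items():
            if not 0 <= int(state) < pi.size:
                raise ValueError(f"state id {state} outside 0..{pi.size - 1}")
            total += pi[int(state)] * float(score)
        out[category] = total
    return out


def enrichment_analysis(
    per_state_scores: Mapping[int, Sequence[ResiduePocketScore]],
    reference_scores: Sequence[ResiduePocketScore],
) -> tuple[pd.DataFrame, int]:
    """Ensemble pocket-score enrichment relative to a reference conformation.

    For every residue: the maximum score across the ensemble, the reference
    score, their difference (``delta``) and the state achieving the maximum.
    Also returns the id of the single state with the largest summed positive
    delta — the most "opened" structure relative to the reference.  All
    states and the reference must share one residue set.
    """
    ref = {r.residue_number: r.score for r in reference_scores}
    residues = sorted(ref)
    state_ids = sorted(per_state_scores)
    if not state_ids:
        raise ValueError("no ensemble states given")
    score_matrix = np.empty((len(state_ids), len(residues)))
    for i, sid in enumerate(state_ids):
        scores = {r.residue_number: r.score for r in per_state_scores[sid]}
        if set(scores) != set(residues):
            raise ValueError(f"state {sid} residue set differs from the reference")
        score_matrix[i] = [scores[r] for r in residues]
    ref_vec = np.array([ref[r] for r in residues])
    argmax = score_matrix.argmax(axis=0)
    ens_max = score_matrix.max(axis=0)
    table = pd.DataFrame(
        {
            "residue_number": residues,
            "reference_score": ref_vec,
            "ensemble_max_score": ens_max,
            "delta": ens_max - ref_vec,
            "argmax_state_id": [state_ids[i] for i in argmax],
        }
    )
    per_state_gain = np.clip(score_matrix - ref_vec, 0.0, None).sum(axis=1)
    open_state = state_ids[int(np.argmax(per_state_gain))]
    return table, open_state


# --------------------------------------------------------------------------
# Tabular pose I/O (CSV, one row per ligand atom)
# --------------------------------------------------------------------------

_POSE_COLUMNS = [
    "compound_id", "state_id", "site_label", "atom_index",
    "x", "y", "z", "docking_score", "quality_score", "predicted_pki",
]


def poses_to_frame(poses: Sequence[PoseRecord]) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(poses):
        for j, (x, y, z) in enumerate(p.ligand_atoms):
            rows.append(
                {
                    "compound_id": p.compound_id,
                    "state_id": p.state_id,
                    "site_label": p.site_label,
                    "pose_index": i,
                    "atom_index": j,
                    "x": x, "y": y, "z": z,
                    "docking_score": p.docking_score,
                    "quality_score": p.quality_score,
                    "predicted_pki": np.nan if p.predicted_pki is None else p.predicted_pki,
                }
            )
    return pd.DataFrame(rows)


def poses_from_frame(df: pd.DataFrame) -> list[PoseRecord]:
    poses = []
    for (_, _, _, _), grp in df.groupby(
        ["pose_index", "compound_id", "state_id", "site_label"], sort=True
    ):
        first = grp.iloc[0]
        pki = first["predicted_pki"]
        poses.append(
            PoseRecord(
                compound_id=str(first["compound_id"]),
                state_id=int(first["state_id"]),
                site_label=str(first["site_label"]),
                ligand_atoms=grp.sort_values("atom_index")[["x", "y", "z"]].to_numpy(),
                docking_score=float(first["docking_score"]),
                quality_score=float(first["quality_score"]),
                predicted_pki=None if pd.isna(pki) else float(pki),
            )
        )
    return poses


def write_poses_csv(poses: Sequence[PoseRecord], path) -> None:
    poses_to_frame(poses).to_csv(path, index=False)


def read_poses_csv(path) -> list[PoseRecord]:
    return poses_from_frame(pd.read_csv(path))
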