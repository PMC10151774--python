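"""Grid-based cryptic-pocket detection (LIGSITE protein–solvent–protein scan).

The detector lays a cubic grid over the structure, marks grid points within
one probe radius of any heavy atom's van der Waals sphere as protein, and
counts, for every solvent point, along how many of seven scan directions
(the three axes and the four cube diagonals) the point is enclosed by
protein on both sides — a protein–solvent–protein (PSP) event.  Solvent
points enclosed along at least ``min_psp`` directions are clustered by face
adjacency; clusters of at least ``min_cluster_size`` points are pockets.

The total pocket volume is the reward used by the adaptive-sampling ranker,
and per-residue pocket scores derived from pocket-point counts stand behind
the generic "pocket score" interface used by the enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures_io import DegenerateStructureError, ProteinStructure

# Fixed element van der Waals radii (Å); unlisted elements fall back to carbon.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_VDW_RADIUS = 1.7

DEFAULT_GRID_SPACING = 1.0       # Å
DEFAULT_PROBE_RADIUS = 1.4       # Å (0.14 nm)
DEFAULT_MIN_PSP = 7              # fully enclosed along all 7 scan directions
DEFAULT_MIN_CLUSTER_SIZE = 3     # grid points
DEFAULT_LINING_CUTOFF = 4.0      # Å, pocket point -> residue heavy atom
DEFAULT_SCORE_RATE = 0.05        # per pocket point, in the residue score map

# 3 axes + 4 cube diagonals.  Each direction is scanned in both senses.
SCAN_DIRECTIONS = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class PocketGrid:
    """Occupancy grid plus (after scanning) per-point PSP counts."""

    origin: np.ndarray           # (3,) Å, coordinate of grid index (0,0,0)
    spacing: float               # Å
    occupancy: np.ndarray        # bool, shape dims; True = protein
    psp_count: np.ndarray | None = None   # int8, defined on solvent points

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.occupancy.shape)

    def point_coords(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (Å) of grid points given (n, 3) indices."""
        return self.origin + np.asarray(indices, float) * self.spacing


@dataclass
class Pocket:
    """One connected cluster of buried solvent grid points."""

    point_indices: np.ndarray            # (n, 3) int grid indices
    volume: float                        # ų = n_points * spacing**3
    lining_residues: dict[int, int]      # residue number -> nearby-point count

    @property
    def n_points(self) -> int:
        return int(self.point_indices.shape[0])


@dataclass(frozen=True)
class ResiduePocketScore:
    residue_number: int
    score: float                         # in [0, 1]


def _atom_radii(elements: np.ndarray) -> np.ndarray:
    return np.array([VDW_RADII.get(e, DEFAULT_VDW_RADIUS) for e in elements])


def build_grid(
    s: ProteinStructure,
    spacing: float = DEFAULT_GRID_SPACING,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> PocketGrid:
    """Occupancy grid for a structure.

    A grid point is protein-occupied iff it lies within
    ``vdW(element) + probe_radius`` of any protein heavy atom.  The grid
    extends past the structure by at least the largest influence radius plus
    one probe diameter, so no occupied point can touch the boundary.  The
    origin is snapped to a multiple of the spacing, which makes the digital
    geometry reproducible under integer-Å translations of the input.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    mask = s.heavy_mask & s.protein_mask
    if not np.any(mask):
        raise DegenerateStructureError("no protein heavy atoms to grid")
    coords = s.coord[mask]
    radii = _atom_radii(s.element[mask].astype(str)) + probe_radius
    margin = float(radii.max()) + 2.0 * probe_radius + spacing
    lo = np.floor((coords.min(axis=0) - margin) / spacing) * spacing
    hi = coords.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    occ = np.zeros(tuple(dims), dtype=bool)
    # Per-atom local window; cheap at the scales this detector is used at.
    for center, radius in zip(coords, radii):
        ilo = np.maximum(np.floor((center - radius - lo) / spacing).astype(int), 0)
        ihi = np.minimum(np.ceil((center + radius - lo) / spacing).astype(int), dims - 1)
        axes = [np.arange(ilo[k], ihi[k] + 1) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        px = lo[0] + gx * spacing - center[0]
        py = lo[1] + gy * spacing - center[1]
        pz = lo[2] + gz * spacing - center[2]
        inside = px * px + py * py + pz * pz <= radius * radius
        occ[gx[inside], gy[inside], gz[inside]] = True
    return PocketGrid(origin=lo, spacing=float(spacing), occupancy=occ)


def _reach(occ: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """``True`` where some occupied point lies strictly ahead along ``d``."""
    reach = np.zeros_like(occ)
    for _ in range(max(occ.shape)):
        updated = _shift(occ | reach, d)
        if np.array_equal(updated, reach):
            break
        reach = updated
    return reach


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Shift so that out[p] = a[p + d], zero-filled at the boundary."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, step in enumerate(d):
        if step == 1:
            src[k], dst[k] = slice(1, None), slice(None, -1)
        elif step == -1:
            src[k], dst[k] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = a[tuple(src)]
    return out


def psp_scan(grid: PocketGrid) -> PocketGrid:
    """Count protein–solvent–protein enclosure directions per solvent point.

    For each of the seven scan directions a solvent point scores one PSP
    event iff protein occupancy exists somewhere along the ray on *both*
    sides of it.  The count is stored in ``grid.psp_count`` (protein points
    hold 0) and the same grid is returned.
    """
    occ = grid.occupancy
    psp = np.zeros(occ.shape, dtype=np.int8)
    for d in SCAN_DIRECTIONS:
        neg = tuple(-c for c in d)
        enclosed = _reach(occ, d) & _reach(occ, neg)
        psp[enclosed & ~occ] += 1
    grid.psp_count = psp
    return grid


_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


def detect_pockets(
    grid: PocketGrid,
    min_psp: int = DEFAULT_MIN_PSP,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    structure: ProteinStructure | None = None,
    lining_cutoff: float = DEFAULT_LINING_CUTOFF,
) -> list[Pocket]:
    """Cluster buried solvent points into pockets.

    Pocket points are solvent points with ``psp_count >= min_psp``; clusters
    are connected components under 6-connectivity (shared faces), and
    clusters smaller than ``min_cluster_size`` are discarded.  Pockets are
    sorted by volume descending (ties by smallest flat grid index).  When
    ``structure`` is given, residues with a heavy atom within
    ``lining_cutoff`` Å of any pocket point are recorded as pocket lining.
    """
    if grid.psp_count is None:
        psp_scan(grid)
    mask = (~grid.occupancy) & (grid.psp_count >= min_psp)
    labels, n_labels = ndimage.label(mask, structure=_FACE_CONNECTIVITY)
    pockets: list[Pocket] = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < min_cluster_size:
            continue
        volume = idx.shape[0] * grid.spacing ** 3
        lining: dict[int, int] = {}
        if structure is not None:
            lining = _lining_residues(grid, idx, structure, lining_cutoff)
        pockets.append(Pocket(point_indices=idx, volume=float(volume), lining_residues=lining))
    dims = grid.occupancy.shape
    pockets.sort(
        key=lambda p: (
            -p.volume,
            int(np.ravel_multi_index(p.point_indices.T, dims).min()),
        )
    )
    return pockets


def _lining_residues(
    grid: PocketGrid, idx: np.ndarray, s: ProteinStructure, cutoff: float
) -> dict[int, int]:
    mask = s.heavy_mask & s.protein_mask
    tree = cKDTree(s.coord[mask])
    res_ids = s.res_id[mask]
    counts: dict[int, int] = {}
    for point in grid.point_coords(idx):
        near = tree.query_ball_point(point, cutoff)
        for rid in np.unique(res_ids[near]):
            counts[int(rid)] = counts.get(int(rid), 0) + 1
    return counts


def total_pocket_volume(pockets: Sequence[Pocket]) -> float:
    """Sum of pocket volumes in ų (0 for no pockets) — the FAST reward."""
    return float(sum(p.volume for p in pockets))


def residue_pocket_scores(
    s: ProteinStructure,
    grid: PocketGrid,
    pockets: Sequence[Pocket],
    lining_cutoff: float = DEFAULT_LINING_CUTOFF,
    rate: float = DEFAULT_SCORE_RATE,
) -> list[ResiduePocketScore]:
    """Per-residue pocket scores in [0, 1].

    ``score(r) = 1 - exp(-rate * n_r)`` where ``n_r`` counts pocket grid
    points within ``lining_cutoff`` Å of residue ``r``'s heavy atoms.  The
    map saturates (27 nearby points give ~0.74 at the default rate) and is 0
    for residues with no pocket in reach.  This is a generic stand-in for a
    per-residue ligand-binding probability from an external pocket scorer.
    """
    counts = {int(r): 0 for r in s.residue_ids()}
    if pockets:
        all_points = np.vstack([grid.point_coords(p.point_indices) for p in pockets])
        mask = s.heavy_mask & s.protein_mask
        res_ids = s.res_id[mask]
        tree = cKDTree(all_points)
        near = tree.query_ball_point(s.coord[mask], lining_cutoff)
        per_residue_points: dict[int, set[int]] = {}
        for rid, hits in zip(res_ids, near):
            per_residue_points.setdefault(int(rid), set()).update(hits)
        for rid, pts in per_residue_points.items():
            counts[rid] = len(pts)
    return [
        ResiduePocketScore(residue_number=r, score=float(1.0 - np.exp(-rate * n)))
        for r, n in sorted(counts.items())
    ]


def filter_pockets(
    pockets_with_scores: Sequence[tuple[Pocket, float]], min_score: float
) -> list[tuple[Pocket, float]]:
    """Keep pockets whose scalar score strictly exceeds ``min_score``.

    Mirrors the permissive pocket-probability filter applied to an external
    pocket scorer's output (default threshold 0.2 upstream); order is kept.
    """
    return [(p, s) for p, s in pockets_with_scores if s > min_score]


def pocket_points_structure(grid: PocketGrid, pockets: Sequence[Pocket]) -> ProteinStructure:
    """Pocket grid points as dummy pseudo-atoms (HETATM, element DU).

    Convenient for visualizing pockets as spheres alongside the protein.
    """
    points = (
        np.vstack([grid.point_coords(p.point_indices) for p in pockets])
        if pockets
        else np.zeros((0, 3))
    )
    n = points.shape[0]
    if n == 0:
        raise DegenerateStructureError("no pocket points to export")
    return ProteinStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "DU"),
        element=np.full(n, "DU"),
        res_id=np.concatenate(
            [np.full(p.n_points, i + 1) for i, p in enumerate(pockets)]
        ),
        res_name=np.full(n, "PKT"),
        chain_id=np.full(n, "P"),
        coord=points,
        hetero=np.ones(n, dtype=bool),
    )
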