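"""Protein structure I/O, residue regions, and region-distance observables.

This module holds the geometric substrate of the pipeline: a light
:class:`ProteinStructure` container backed by numpy arrays (read from and
written to PDB via biotite), named residue regions such as the PPM1D flap and
hinge domains, inter-region distance observables, and docking-box
construction from padded coordinate extrema.

Residue numbering is taken verbatim from the PDB record (author numbering).
Insertion codes are rejected: all region definitions used here assume plain
integer numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence
from urllib.request import urlopen

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class StructureError(ValueError):
    """Base class for structure-related errors."""


class FormatError(StructureError):
    """The input file could not be parsed as the expected format."""


class ModelIndexError(StructureError, IndexError):
    """The requested model does not exist in the file."""


class SelectionError(StructureError):
    """An atom/residue selection matched nothing."""


class TopologyError(StructureError):
    """Two structures that must share a topology do not."""


class DegenerateStructureError(StructureError):
    """An operation produced or received a structure with no atoms."""


# --------------------------------------------------------------------------
# Core container
# --------------------------------------------------------------------------

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

ATOM_SUBSETS = ("all_heavy", "backbone", "sidechain", "c_alpha")


@dataclass
class ProteinStructure:
    """Atoms of one model of a protein structure.

    All per-atom annotations are parallel numpy arrays.  ``hetero`` marks
    HETATM records (non-protein atoms); hydrogens are retained on input but
    every distance/contact computation downstream works on heavy atoms only.
    """

    serial: np.ndarray          # int, unique within the model
    atom_name: np.ndarray       # str
    element: np.ndarray         # str, upper case
    res_id: np.ndarray          # int, author numbering
    res_name: np.ndarray        # str
    chain_id: np.ndarray        # str
    coord: np.ndarray           # (n, 3) float, Å
    hetero: np.ndarray          # bool
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise StructureError("coordinates must have shape (n, 3)")
        if self.coord.shape[0] == 0:
            raise DegenerateStructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        serial = np.asarray(self.serial)
        if len(np.unique(serial)) != len(serial):
            raise StructureError("atom serial numbers are not unique")

    @property
    def n_atoms(self) -> int:
        return self.coord.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) != "H"

    @property
    def protein_mask(self) -> np.ndarray:
        return ~self.hetero

    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue numbers of the protein atoms."""
        return np.unique(self.res_id[self.protein_mask])

    def subset(self, mask: np.ndarray) -> "ProteinStructure":
        if not np.any(mask):
            raise DegenerateStructureError("selection removed every atom")
        return ProteinStructure(
            serial=self.serial[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            res_id=self.res_id[mask],
            res_name=self.res_name[mask],
            chain_id=self.chain_id[mask],
            coord=self.coord[mask],
            hetero=self.hetero[mask],
            model_id=self.model_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigidly move the whole structure (used by tests and generators)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        return replace(self, coord=self.coord @ rotation.T + translation)


@dataclass(frozen=True)
class RegionDefinition:
    """A named set of residues with an atom-subset policy.

    ``atom_subset`` is one of ``all_heavy``, ``backbone`` (N, CA, C, O),
    ``sidechain`` (heavy atoms not in the backbone) or ``c_alpha``.
    """

    name: str
    residue_numbers: frozenset[int]
    atom_subset: str = "all_heavy"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_numbers", frozenset(int(r) for r in self.residue_numbers))
        if not self.residue_numbers:
            raise SelectionError(f"region {self.name!r} has no residues")
        if self.atom_subset not in ATOM_SUBSETS:
            raise SelectionError(
                f"atom_subset must be one of {ATOM_SUBSETS}, got {self.atom_subset!r}"
            )

    def atom_mask(self, s: ProteinStructure, chain: str | None = None) -> np.ndarray:
        """Boolean mask of the structure's atoms selected by this region."""
        mask = np.isin(s.res_id, sorted(self.residue_numbers)) & s.protein_mask & s.heavy_mask
        if chain is not None:
            mask &= s.chain_id == chain
        names = s.atom_name.astype(str)
        if self.atom_subset == "backbone":
            mask &= np.isin(names, sorted(BACKBONE_ATOMS))
        elif self.atom_subset == "sidechain":
            mask &= ~np.isin(names, sorted(BACKBONE_ATOMS))
        elif self.atom_subset == "c_alpha":
            mask &= names == "CA"
        return mask

    def coords(self, s: ProteinStructure, chain: str | None = None) -> np.ndarray:
        mask = self.atom_mask(s, chain=chain)
        if not np.any(mask):
            raise SelectionError(
                f"region {self.name!r} ({self.atom_subset}) selects no atoms"
            )
        return s.coord[mask]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box used as a docking search volume."""

    min_corner: tuple[float, float, float]
    max_corner: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, float)
        hi = np.asarray(self.max_corner, float)
        if np.any(lo > hi):
            raise StructureError("box min corner exceeds max corner")
        if np.any(lo == hi):
            raise StructureError("box has zero extent along an axis")

    @property
    def volume(self) -> float:
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        return float(np.prod(hi - lo))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        lo = np.asarray(self.min_corner)
        hi = np.asarray(self.max_corner)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


# --------------------------------------------------------------------------
# PPM1D region catalogue
#
# Two slightly different flap/hinge extents are in common use for this
# system (one from the pose-classification protocol, one from the figure
# analyses); both are exposed and callers choose explicitly.
# --------------------------------------------------------------------------

FLAP_REGION = RegionDefinition("flap", frozenset(range(219, 289)))
FLAP_REGION_WIDE = RegionDefinition("flap_wide", frozenset(range(219, 296)))
HINGE_REGION = RegionDefinition("hinge", frozenset(range(150, 168)))
HINGE_REGION_NARROW = RegionDefinition("hinge_narrow", frozenset(range(150, 167)))
ACTIVE_SITE_REGION = RegionDefinition(
    "active_site", frozenset({18, 22, 23, 105, 106, 192, 218, 314, 366})
)
ACTIVE_SITE_CORE_REGION = RegionDefinition(
    "active_site_core", frozenset({105, 192, 314, 366})
)
PHOTOLABEL_REGION = RegionDefinition("photolabel", frozenset({219, 236}))
HELIX_346_361_REGION = RegionDefinition("helix_346_361", frozenset(range(346, 362)))

DEFAULT_REGIONS = {
    r.name: r
    for r in (
        FLAP_REGION,
        FLAP_REGION_WIDE,
        HINGE_REGION,
        HINGE_REGION_NARROW,
        ACTIVE_SITE_REGION,
        ACTIVE_SITE_CORE_REGION,
        PHOTOLABEL_REGION,
        HELIX_346_361_REGION,
    )
}

ALPHAFOLD_PPM1D_ACCESSION = "AF-O15297"
_ALPHAFOLD_URL = "https://alphafold.ebi.ac.uk/files/{accession}-F1-model_v4.pdb"


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def _from_atom_array(arr: bst.AtomArray, model_id: int) -> ProteinStructure:
    ins = getattr(arr, "ins_code", None)
    if ins is not None and np.any(np.asarray(ins).astype(str) != ""):
        raise FormatError(
            "structure contains residue insertion codes; renumber the input "
            "to plain integer numbering before use"
        )
    serial = (
        arr.atom_id if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    return ProteinStructure(
        serial=np.asarray(serial, int),
        atom_name=np.asarray(arr.atom_name).astype(str),
        element=np.char.upper(np.asarray(arr.element).astype(str)),
        res_id=np.asarray(arr.res_id, int),
        res_name=np.asarray(arr.res_name).astype(str),
        chain_id=np.asarray(arr.chain_id).astype(str),
        coord=np.asarray(arr.coord, float),
        hetero=np.asarray(arr.hetero, bool),
        model_id=model_id,
    )


def _to_atom_array(s: ProteinStructure, b_factor: np.ndarray | None = None) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coord, np.float32)
    arr.atom_name = s.atom_name.astype(str)
    arr.element = s.element.astype(str)
    arr.res_id = np.asarray(s.res_id, int)
    arr.res_name = s.res_name.astype(str)
    arr.chain_id = s.chain_id.astype(str)
    arr.hetero = np.asarray(s.hetero, bool)
    arr.set_annotation("atom_id", np.asarray(s.serial, int))
    if b_factor is not None:
        arr.set_annotation("b_factor", np.asarray(b_factor, float))
    return arr


def read_structure(path: str | Path, model_index: int = 1) -> ProteinStructure:
    """Read one model of a PDB file.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM records; MODEL/ENDMDL blocks supported.
    model_index
        1-based model number, as printed in the MODEL record.
    """
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    if not 1 <= model_index <= n_models:
        raise ModelIndexError(
            f"model {model_index} not present in {path} ({n_models} model(s))"
        )
    arr = pdb.get_structure(model=model_index, extra_fields=["atom_id"])
    return _from_atom_array(arr, model_index)


def read_ensemble(path: str | Path) -> list[ProteinStructure]:
    """Read every model of a multi-model PDB as a conformational ensemble."""
    pdb = PDBFile.read(str(path))
    return [
        _from_atom_array(pdb.get_structure(model=m, extra_fields=["atom_id"]), m)
        for m in range(1, pdb.get_model_count() + 1)
    ]


def write_structure(
    s: ProteinStructure, path: str | Path, b_factor: np.ndarray | None = None
) -> None:
    """Write a structure as PDB.  ``b_factor`` optionally paints per-atom values."""
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s, b_factor=b_factor))
    pdb.write(str(path))


def write_ensemble(frames: Sequence[ProteinStructure], path: str | Path) -> None:
    """Write frames sharing one topology as a multi-model PDB."""
    if not frames:
        raise DegenerateStructureError("no frames to write")
    stack = bst.stack([_to_atom_array(f) for f in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def fetch_alphafold_model(
    accession: str = ALPHAFOLD_PPM1D_ACCESSION,
    cache_dir: str | Path = ".",
    timeout: float = 60.0,
) -> Path:
    """Download an AlphaFold DB model PDB (cached), returning the local path.

    Requires network access; a previously downloaded copy in ``cache_dir``
    is reused without contacting the server.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    dest = cache_dir / f"{accession}-F1-model_v4.pdb"
    if dest.exists():
        return dest
    url = _ALPHAFOLD_URL.format(accession=accession)
    with urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest


# --------------------------------------------------------------------------
# Construct preparation
# --------------------------------------------------------------------------

def truncate_construct(
    s: ProteinStructure, remove_ranges: Iterable[tuple[int, int]]
) -> ProteinStructure:
    """Remove residue ranges (inclusive) from a structure.

    Mirrors simulation-construct preparation in which disordered segments
    (e.g. an internal loop and the C-terminal tail) are cut out.  Numbering
    of the remaining residues is untouched.  Ranges that match no residue
    raise a warning rather than an error.
    """
    remove_ranges = list(remove_ranges)
    if not remove_ranges:
        return s
    present = set(int(r) for r in np.unique(s.res_id))
    drop: set[int] = set()
    for lo, hi in remove_ranges:
        lo, hi = int(lo), int(hi)
        if lo > hi:
            raise StructureError(f"invalid residue range {lo}-{hi}")
        members = set(range(lo, hi + 1)) & present
        if not members:
            warnings.warn(f"residue range {lo}-{hi} matches no residues", stacklevel=2)
        drop |= set(range(lo, hi + 1))
    keep = ~np.isin(s.res_id, sorted(drop))
    if not np.any(keep):
        raise DegenerateStructureError("truncation removed every residue")
    return s.subset(keep)


# --------------------------------------------------------------------------
# Distances and boxes
# --------------------------------------------------------------------------

DISTANCE_MODES = ("centroid", "mean_pairwise", "minimum")


def region_distance(
    s: ProteinStructure,
    a: RegionDefinition,
    b: RegionDefinition,
    mode: str = "centroid",
    chain: str | None = None,
) -> float:
    """Distance in Å between two regions of one structure.

    ``centroid`` is the distance between the unweighted centroids of the two
    selections; ``mean_pairwise`` averages over all cross pairs; ``minimum``
    is the smallest cross-pair distance.  An "average distance" between two
    large atom sets is reported as the centroid separation by default.
    """
    if mode not in DISTANCE_MODES:
        raise SelectionError(f"mode must be one of {DISTANCE_MODES}, got {mode!r}")
    xa = a.coords(s, chain=chain)
    xb = b.coords(s, chain=chain)
    if mode == "centroid":
        return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    diffs = xa[:, None, :] - xb[None, :, :]
    dists = np.linalg.norm(diffs, axis=-1)
    return float(dists.mean() if mode == "mean_pairwise" else dists.min())


def region_distance_table(
    frames: Sequence[ProteinStructure],
    pairs: Sequence[tuple[RegionDefinition, RegionDefinition, str]],
):
    """Per-frame distance observables as a tidy table.

    Returns a :class:`pandas.DataFrame` with columns
    ``state_id, region_a, region_b, mode, distance_A``.
    """
    import pandas as pd

    rows = []
    for i, f in enumerate(frames):
        for a, b, mode in pairs:
            rows.append(
                {
                    "state_id": i,
                    "region_a": a.name,
                    "region_b": b.name,
                    "mode": mode,
                    "distance_A": region_distance(f, a, b, mode=mode),
                }
            )
    return pd.DataFrame(rows)


def make_docking_box(points: np.ndarray, padding: float = 5.0) -> BoundingBox:
    """Axis-aligned box around ``points`` padded by ``padding`` Å per dimension.

    This is how docking search volumes are built from pocket grid points or
    from the atoms of site-defining residues (photolabeling or catalytic).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise SelectionError("cannot build a box around zero points")
    if pts.shape[1] != 3:
        raise StructureError("points must be (n, 3)")
    if padding < 0:
        raise StructureError("padding must be non-negative")
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    return BoundingBox(tuple(lo), tuple(hi))


def region_docking_box(
    s: ProteinStructure, region: RegionDefinition, padding: float = 5.0
) -> BoundingBox:
    """Docking box around all heavy atoms a region selects."""
    return make_docking_box(region.coords(s), padding=padding)
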