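"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators cover the pipeline end to end with no external data:

* :func:`make_toy_protein` — a pseudo-atom cavity toy: the *open* form is a
  hollow cubic shell enclosing an empty cavity (optionally with part of one
  wall removed), the *closed* form is the same shell contracted until the
  interior clearance drops below the probe-inflated atom radius, so the
  cavity collapses.  This emulates a ground-state structure that lacks the
  pocket versus excited conformations that present it, with identical
  topology so the pair can serve as conformations of one Markov ensemble.
* :func:`make_markov_ensemble` — state trajectories drawn from a known
  transition matrix, mapped to conformations with sub-cluster-radius
  jitter, for parameter-recovery tests of the MSM stage.
* :func:`make_synthetic_screen` — a small compound screen with known true
  affinities: per-state pose-quality scores and predicted pKi values are
  generated from the true affinities plus state-dependent pocket
  availability and noise, and docking scores are pure decoys uncorrelated
  with potency.  Compound-specific binding signal is carried only by
  open-pocket states: closed states see the signal attenuated toward the
  screen mean (a pose-sensitive predictor falling back to a ligand-only
  baseline) plus a constant loss.  Measured potencies equal the true pKi.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structures_io import (
    ACTIVE_SITE_REGION,
    FLAP_REGION,
    HINGE_REGION,
    ProteinStructure,
    RegionDefinition,
)
from .pose_analysis import PoseRecord
from .msm import _stationary_distribution


# --------------------------------------------------------------------------
# Cavity toy proteins
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyProteinSpec:
    """Parameters of the hollow-cavity toy protein.

    ``cavity_edge`` is the nominal edge (Å) of the enclosed empty region of
    the open form; the wall is a single-layer shell of carbon pseudo-atoms,
    ``wall_atoms_per_edge`` per cube edge.  ``open_fraction`` removes that
    fraction of one wall's atoms (those nearest the wall center) from the
    open form; 0 keeps the cavity sealed.  ``jitter_sd`` adds isotropic
    Gaussian noise to every atom.
    """

    wall_atoms_per_edge: int = 11
    cavity_edge: float = 8.0
    open_fraction: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0
    closed_edge: float = 6.0   # shell side of the collapsed (closed) form

    def __post_init__(self) -> None:
        if self.wall_atoms_per_edge < 3:
            raise ValueError("need at least 3 wall atoms per edge")
        if not 0.0 <= self.open_fraction <= 1.0:
            raise ValueError("open_fraction must lie in [0, 1]")
        if self.cavity_edge <= 0:
            raise ValueError("cavity edge must be positive")


def _shell_lattice(n_per_edge: int, side: float) -> np.ndarray:
    """Atoms on the surface of a cube [0, side]^3, n_per_edge per edge."""
    ticks = np.linspace(0.0, side, n_per_edge)
    pts = np.stack(np.meshgrid(ticks, ticks, ticks, indexing="ij"), axis=-1).reshape(-1, 3)
    on_shell = np.any((pts == 0.0) | (pts == side), axis=1)
    return pts[on_shell]


def _as_structure(coords: np.ndarray, model_id: int = 1) -> ProteinStructure:
    n = coords.shape[0]
    return ProteinStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "GLY"),
        chain_id=np.full(n, "A"),
        coord=coords,
        hetero=np.zeros(n, dtype=bool),
    )


def make_toy_protein(spec: ToyProteinSpec) -> tuple[ProteinStructure, ProteinStructure]:
    """Closed (collapsed-cavity) and open (hollow) toy conformations.

    Both structures share one topology: atom ``i`` of the closed form is
    atom ``i`` of the open form, moved radially inward.  The default open
    form encloses a cavity that the grid detector resolves as a single
    27-point pocket at 1 Å spacing with default parameters.
    """
    side_open = spec.cavity_edge + 2.0
    shell = _shell_lattice(spec.wall_atoms_per_edge, side_open)
    if shell.shape[0] == 0:
        raise ValueError("degenerate toy: no wall atoms")
    rng = np.random.default_rng(spec.seed)

    open_coords = shell.copy()
    if spec.open_fraction > 0.0:
        # Remove the fraction of the +x wall nearest the wall center.
        wall = np.flatnonzero(open_coords[:, 0] == side_open)
        center = np.array([side_open, side_open / 2.0, side_open / 2.0])
        order = wall[np.argsort(np.linalg.norm(open_coords[wall] - center, axis=1), kind="stable")]
        n_remove = int(round(spec.open_fraction * wall.size))
        keep = np.ones(open_coords.shape[0], dtype=bool)
        keep[order[:n_remove]] = False
        open_coords = open_coords[keep]

    closed_coords = shell * (spec.closed_edge / side_open)
    # Keep topologies aligned when a wall section was removed.
    if open_coords.shape[0] != shell.shape[0]:
        closed_coords = closed_coords[keep]

    if spec.jitter_sd > 0.0:
        closed_coords = closed_coords + rng.normal(0.0, spec.jitter_sd, closed_coords.shape)
        open_coords = open_coords + rng.normal(0.0, spec.jitter_sd, open_coords.shape)

    return _as_structure(closed_coords), _as_structure(open_coords)


# --------------------------------------------------------------------------
# Markov-chain ensembles
# --------------------------------------------------------------------------

def sample_chain(
    transition_matrix: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    start: int | None = None,
) -> np.ndarray:
    """Sample a state sequence from a row-stochastic transition matrix.

    The start state is drawn from the stationary distribution unless given.
    """
    tmat = np.asarray(transition_matrix, dtype=float)
    if tmat.ndim != 2 or tmat.shape[0] != tmat.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(tmat < 0) or not np.allclose(tmat.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("rows of the transition matrix must sum to 1")
    n = tmat.shape[0]
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pi = _stationary_distribution(tmat)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(n, p=pi) if start is None else int(start)
    for t in range(1, n_steps):
        states[t] = rng.choice(n, p=tmat[states[t - 1]])
    return states


def make_markov_ensemble(
    transition_matrix: np.ndarray,
    n_steps: int,
    conformation_map: Mapping[int, ProteinStructure],
    seed: int = 0,
    jitter_sd: float = 0.3,
) -> tuple[list[ProteinStructure], np.ndarray]:
    """Frames of a known Markov chain over mapped conformations.

    Each frame is the conformation of its state plus isotropic Gaussian
    jitter (default well below the 2 Å cluster radius), so clustering can
    recover the state partition and transition statistics.
    """
    tmat = np.asarray(transition_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    missing = set(range(tmat.shape[0])) - set(conformation_map)
    if missing:
        raise ValueError(f"conformation_map lacks states {sorted(missing)}")
    states = sample_chain(tmat, n_steps, rng)
    frames = []
    for t, s in enumerate(states):
        base = conformation_map[int(s)]
        coord = base.coord + (
            rng.normal(0.0, jitter_sd, base.coord.shape) if jitter_sd > 0 else 0.0
        )
        frame = _as_structure(coord, model_id=t + 1)
        frames.append(frame)
    return frames, states


# --------------------------------------------------------------------------
# Synthetic compound screen
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Ground-truth parameters of the synthetic allosteric-compound screen.

    Defaults mirror the scale of the motivating study: nine compounds
    spanning four pKi units, twenty conformational states of which a
    quarter present the cryptic interface pocket, per-state predictor noise
    of one pKi unit, and decoy docking scores carrying no potency signal.
    """

    n_compounds: int = 9
    true_pki: tuple[float, ...] | None = None    # default: evenly spaced 4..8
    n_states: int = 20
    open_state_ids: frozenset[int] | None = None  # default: 25% of states, drawn
    open_fraction: float = 0.25
    pki_noise_sd: float = 1.0
    signal_loss: float = 1.5          # pKi units lost in closed states
    signal_attenuation: float = 0.5   # closed-state shrink of compound signal
    quality_open_mean: float = 0.75
    quality_closed_mean: float = 0.30
    quality_sd: float = 0.15
    decoy_dock_mean: float = -7.0     # kcal/mol
    decoy_dock_noise_sd: float = 1.5
    seed: int = 11

    def __post_init__(self) -> None:
        if self.n_compounds < 2:
            raise ValueError("need at least two compounds to rank")
        if self.n_states < 2:
            raise ValueError("need at least two states")
        if not 0.0 < self.open_fraction < 1.0 and self.open_state_ids is None:
            raise ValueError("open_fraction must lie in (0, 1)")
        if self.open_state_ids is not None:
            bad = set(self.open_state_ids) - set(range(self.n_states))
            if bad:
                raise ValueError(f"open_state_ids outside the state range: {sorted(bad)}")

    def resolved_true_pki(self) -> np.ndarray:
        if self.true_pki is not None:
            if len(self.true_pki) != self.n_compounds:
                raise ValueError("true_pki length must equal n_compounds")
            return np.asarray(self.true_pki, dtype=float)
        return np.linspace(4.0, 8.0, self.n_compounds)


# Pose site anchors of the screen receptor, chosen so a three-atom ligand at
# each anchor contacts exactly the intended region(s) at the 4 Å cutoff.
_SITE_ANCHORS = {
    "flap_hinge_interface": np.array([3.75, 0.0, 0.0]),
    "flap_only": np.array([11.5, 0.0, 0.0]),
    "hinge_only": np.array([-3.0, 0.0, 0.0]),
    "active_site": np.array([0.0, 17.5, 0.0]),
}
_LIGAND_OFFSETS = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.6], [0.0, 0.6, 0.0]])


def make_screen_receptor() -> ProteinStructure:
    """Pseudo-atom receptor whose residue numbering matches the PPM1D regions.

    Hinge residues (150–167) form a compact blob at the origin, flap
    residues (219–288) a larger blob 8 Å away along +x, and the nine
    catalytic residues a blob 20 Å away along +y, so poses planted at the
    region anchors classify into the intended site categories.
    """
    coords = []
    res_ids = []

    def blob(center, res_numbers, nx, ny, nz):
        xs = np.arange(nx) - (nx - 1) / 2.0
        ys = np.arange(ny) - (ny - 1) / 2.0
        zs = np.arange(nz) - (nz - 1) / 2.0
        pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
        for rid, p in zip(res_numbers, pts):
            coords.append(np.asarray(center) + p)
            res_ids.append(rid)

    blob((0.0, 0.0, 0.0), sorted(HINGE_REGION.residue_numbers), 3, 3, 2)
    blob((8.0, 0.0, 0.0), sorted(FLAP_REGION.residue_numbers), 4, 4, 5)
    blob((0.0, 20.0, 0.0), sorted(ACTIVE_SITE_REGION.residue_numbers), 3, 3, 1)

    coords = np.asarray(coords)
    n = coords.shape[0]
    return ProteinStructure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        res_id=np.asarray(res_ids, int),
        res_name=np.full(n, "ALA"),
        chain_id=np.full(n, "A"),
        coord=coords,
        hetero=np.zeros(n, dtype=bool),
    )


@dataclass
class SyntheticScreen:
    """Everything the downstream pipeline consumes, with ground truth."""

    spec: ScreenSpec
    receptor: ProteinStructure
    poses: list[PoseRecord]
    measured: pd.DataFrame            # compound_id, measured_pki, potency_type
    pi: np.ndarray                    # ground-truth equilibrium distribution
    open_state_ids: list[int]
    reference_state: int = 0          # a closed, ground-state-like reference

    @property
    def compound_ids(self) -> list[str]:
        return list(self.measured["compound_id"])


def make_synthetic_screen(spec: ScreenSpec = ScreenSpec()) -> SyntheticScreen:
    """Generate the synthetic screen (poses, potency table, true weights).

    For every compound x state, one pose is planted at each of the four
    site anchors of the screen receptor.  Pose quality is drawn around
    ``quality_open_mean`` for interface poses in open-pocket states and
    around ``quality_closed_mean`` everywhere else (clipped to [0, 1] by
    truncation).  The per-state predicted pKi is ``true + noise`` in open
    states and ``mean + attenuation*(true - mean) - signal_loss + noise``
    in closed states; docking scores are decoy draws uncorrelated with
    potency.  State 0 is always closed and serves as the static reference.
    """
    rng = np.random.default_rng(spec.seed)
    true_pki = spec.resolved_true_pki()
    base = float(true_pki.mean())
    compounds = [f"CAA-{i + 1}" for i in range(spec.n_compounds)]

    if spec.open_state_ids is None:
        n_open = max(1, round(spec.open_fraction * spec.n_states))
        open_ids = set(
            int(s) for s in rng.choice(np.arange(1, spec.n_states), size=n_open, replace=False)
        )
    else:
        open_ids = set(int(s) for s in spec.open_state_ids)
    # State 0 is never drawn open, so by default it is a closed,
    # ground-state-like reference; explicit open_state_ids may override.

    pi = rng.dirichlet(np.full(spec.n_states, 2.0))
    receptor = make_screen_receptor()

    poses: list[PoseRecord] = []
    for c, t in zip(compounds, true_pki):
        for s in range(spec.n_states):
            is_open = s in open_ids
            mu = t if is_open else base + spec.signal_attenuation * (t - base) - spec.signal_loss
            state_pki = float(mu + rng.normal(0.0, spec.pki_noise_sd))
            for site, anchor in _SITE_ANCHORS.items():
                hot = site == "flap_hinge_interface" and is_open
                q_mean = spec.quality_open_mean if hot else spec.quality_closed_mean
                quality = float(np.clip(rng.normal(q_mean, spec.quality_sd), 0.0, 1.0))
                jitter = rng.normal(0.0, 0.1, size=3)
                poses.append(
                    PoseRecord(
                        compound_id=c,
                        state_id=s,
                        site_label=site,
                        ligand_atoms=anchor + jitter + _LIGAND_OFFSETS,
                        docking_score=float(
                            rng.normal(spec.decoy_dock_mean, spec.decoy_dock_noise_sd)
                        ),
                        quality_score=quality,
                        predicted_pki=state_pki,
                    )
                )

    measured = pd.DataFrame(
        {
            "compound_id": compounds,
            "measured_pki": true_pki,
            "potency_type": "pKi",
        }
    )
    return SyntheticScreen(
        spec=spec,
        receptor=receptor,
        poses=poses,
        measured=measured,
        pi=pi,
        open_state_ids=sorted(open_ids),
    )
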