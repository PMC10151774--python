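"""Conformational clustering and Markov state model construction.

An ensemble of frames sharing one topology is clustered with greedy
k-centers under the Cα-RMSD metric (minimized over rigid superposition)
until every frame lies within a target cover radius (2 Å by default) of its
center.  Transitions between cluster assignments are counted at a fixed lag
(sliding window), a uniform pseudocount of 1/n_states is added to every
element of the count matrix, rows are normalized to give the transition
matrix, and the equilibrium distribution π is the leading left eigenvector.

Row normalization of pseudocounted counts does not enforce detailed
balance, so π is computed from the left eigenproblem rather than by count
symmetrization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eig
from scipy.spatial.transform import Rotation

from .structures_io import ProteinStructure, TopologyError

DEFAULT_CLUSTER_RADIUS = 2.0   # Å, k-centers cover radius
DEFAULT_LAG = 1                # frames


@dataclass
class ClusterModel:
    """k-centers clustering of a frame ensemble under Cα RMSD."""

    center_frame_indices: list[int]
    assignments: np.ndarray          # per-frame center index (0-based)
    distances: np.ndarray            # per-frame distance to assigned center, Å
    cluster_radius: float
    metric: str = "c_alpha_rmsd"

    @property
    def n_states(self) -> int:
        return len(self.center_frame_indices)


@dataclass
class TransitionModel:
    """Pseudocounted row-stochastic transition matrix with equilibrium π."""

    counts: np.ndarray
    pseudocount: float
    transition_matrix: np.ndarray
    equilibrium: np.ndarray

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


# --------------------------------------------------------------------------
# Cα RMSD
# --------------------------------------------------------------------------

def _ca_coords(s: ProteinStructure) -> np.ndarray:
    mask = (s.atom_name.astype(str) == "CA") & s.protein_mask
    if not np.any(mask):
        raise TopologyError("structure has no C-alpha atoms")
    return s.coord[mask]


def ca_rmsd(a: ProteinStructure, b: ProteinStructure) -> float:
    """Minimum Cα RMSD (Å) between two conformations of one topology.

    The RMSD is minimized over rigid rotation and translation (Kabsch
    superposition); it is symmetric and zero iff the Cα sets are congruent.
    """
    xa = _ca_coords(a)
    xb = _ca_coords(b)
    if xa.shape != xb.shape:
        raise TopologyError(
            f"C-alpha count mismatch: {xa.shape[0]} vs {xb.shape[0]}"
        )
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    if xa.shape[0] == 1:
        return 0.0
    _, rssd = Rotation.align_vectors(xa, xb)
    return float(rssd / np.sqrt(xa.shape[0]))


# --------------------------------------------------------------------------
# k-centers
# --------------------------------------------------------------------------

def kcenters_cluster(
    frames: Sequence[ProteinStructure],
    radius: float = DEFAULT_CLUSTER_RADIUS,
    first_center: int = 0,
) -> ClusterModel:
    """Greedy k-centers clustering to a target cover radius.

    The first center is frame ``first_center`` (frame 0 by default, for
    reproducibility); each subsequent center is the frame currently farthest
    from its nearest center, and centers are added until the maximum
    frame-to-center distance is at most ``radius``.  Ties in assignment are
    broken toward the lowest center index.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("cannot cluster an empty ensemble")
    if radius <= 0:
        raise ValueError("cluster radius must be positive")
    centers = [int(first_center)]
    dist = np.array([ca_rmsd(frames[first_center], f) for f in frames])
    assign = np.zeros(n, dtype=int)
    while True:
        farthest = int(np.argmax(dist))
        if dist[farthest] <= radius:
            break
        centers.append(farthest)
        new = np.array([ca_rmsd(frames[farthest], f) for f in frames])
        closer = new < dist   # strict: ties stay with the earlier center
        assign[closer] = len(centers) - 1
        dist = np.where(closer, new, dist)
    return ClusterModel(
        center_frame_indices=centers,
        assignments=assign,
        distances=dist,
        cluster_radius=float(radius),
    )


# --------------------------------------------------------------------------
# Transition counting and MSM
# --------------------------------------------------------------------------

def count_transitions(
    assignments: Sequence[Sequence[int]] | Sequence[int],
    lag: int = DEFAULT_LAG,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts at a fixed lag.

    ``assignments`` is one state sequence or a list of them; pairs are never
    counted across trajectory boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    seqs = _as_sequences(assignments)
    flat = np.concatenate([np.asarray(s, dtype=int) for s in seqs])
    if flat.size == 0:
        raise ValueError("no states in assignments")
    if np.any(flat < 0):
        raise ValueError("negative state id")
    n = int(flat.max()) + 1 if n_states is None else int(n_states)
    if flat.max() >= n:
        raise ValueError(f"state id {flat.max()} outside 0..{n - 1}")
    counts = np.zeros((n, n), dtype=float)
    for seq in seqs:
        seq = np.asarray(seq, dtype=int)
        if seq.size <= lag:
            raise ValueError(
                f"trajectory of length {seq.size} shorter than lag+1={lag + 1}"
            )
        np.add.at(counts, (seq[:-lag], seq[lag:]), 1.0)
    return counts


def _as_sequences(assignments) -> list[Sequence[int]]:
    first = assignments[0] if len(assignments) else None
    if np.ndim(first) == 0:
        return [assignments]
    return list(assignments)


def build_msm(counts: np.ndarray, pseudocount: float | str = "auto") -> TransitionModel:
    """Transition matrix and equilibrium distribution from raw counts.

    ``T[i, j] = (counts[i, j] + a) / sum_k (counts[i, k] + a)`` with the
    uniform pseudocount ``a = 1/n_states`` when ``pseudocount="auto"``.  π
    is the left eigenvector of T for the eigenvalue closest to 1, with a
    power-iteration fallback, normalized to sum to 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n = counts.shape[0]
    alpha = 1.0 / n if pseudocount == "auto" else float(pseudocount)
    if alpha <= 0:
        raise ValueError("pseudocount must be positive")
    pseudo = counts + alpha
    tmat = pseudo / pseudo.sum(axis=1, keepdims=True)
    pi = _stationary_distribution(tmat)
    return TransitionModel(
        counts=counts, pseudocount=alpha, transition_matrix=tmat, equilibrium=pi
    )


def _stationary_distribution(tmat: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    vals, vecs = eig(tmat, left=True, right=False)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.max(np.abs(pi @ tmat - pi)) > 1e-8:
        # Fall back to power iteration on T^T (strictly positive matrix,
        # so convergence to the unique stationary vector is guaranteed).
        pi = np.full(tmat.shape[0], 1.0 / tmat.shape[0])
        for _ in range(100_000):
            nxt = pi @ tmat
            if np.max(np.abs(nxt - pi)) < tol:
                pi = nxt
                break
            pi = nxt
        pi = pi / pi.sum()
    return pi
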