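"""FAST-style adaptive-sampling state ranking and seed selection.

States are scored by a reward that combines (after min–max normalization)
the pocket volume of each state's representative conformation with an
undersampling bonus ``1/(visit_count + 1)``, so large cryptic pockets and
rarely visited conformations both raise a state's priority.  Seeds for the
next sampling generation are picked greedily, deflating the score of
candidates conformationally similar to already-selected seeds with a
Gaussian penalty of width 1.5× the cluster radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_ALPHA = 1.0
DEFAULT_SEED_COUNT = 10
DEFAULT_SIMILARITY_WIDTH = 3.0   # Å = 1.5 x the 2 Å cluster radius


@dataclass
class StateFeatures:
    """Per-state inputs to the ranking objective."""

    state_id: int
    pocket_volume: float          # ų
    visit_count: int
    # pairwise Cα RMSD (Å) from this state's center to every state's center,
    # in state order; symmetric with zero diagonal across the feature list
    pairwise_distance: np.ndarray

    def __post_init__(self) -> None:
        if self.pocket_volume < 0:
            raise ValueError("pocket volume must be non-negative")
        if self.visit_count < 0:
            raise ValueError("visit count must be non-negative")
        self.pairwise_distance = np.asarray(self.pairwise_distance, dtype=float)


@dataclass
class SelectionResult:
    selected_state_ids: list[int]
    scores_at_selection: list[float]


def normalize_feature(values: Sequence[float]) -> np.ndarray:
    """Min–max normalize to [0, 1]; a constant list maps to all 0.5."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full(v.shape, 0.5)
    return (v - lo) / (hi - lo)


def fast_scores(features: Sequence[StateFeatures], alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Ranking scores: ``alpha * norm(volume) + norm(1 / (count + 1))``.

    Higher pocket volume (exploitation) and lower visit count (exploration)
    both increase the score; ``alpha`` weights exploitation.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    volumes = [f.pocket_volume for f in features]
    undersampled = [1.0 / (f.visit_count + 1.0) for f in features]
    return alpha * normalize_feature(volumes) + normalize_feature(undersampled)


def select_seeds(
    features: Sequence[StateFeatures],
    k: int = DEFAULT_SEED_COUNT,
    width: float = DEFAULT_SIMILARITY_WIDTH,
    alpha: float = DEFAULT_ALPHA,
) -> SelectionResult:
    """Greedy top-k seed selection with similarity deflation.

    Repeatedly picks the state maximizing
    ``score_i * prod_{j selected} (1 - exp(-d_ij^2 / (2 width^2)))``;
    a state at zero distance from a selected seed is annihilated (factor 0),
    so duplicates are never enriched.  Ties break toward the lowest
    state id.  ``k`` larger than the number of states returns all states
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if width <= 0:
        raise ValueError("similarity width must be positive")
    n = len(features)
    if n == 0:
        raise ValueError("no states to select from")
    if k > n:
        warnings.warn(f"requested {k} seeds from {n} states; returning all", stacklevel=2)
        k = n
    base = fast_scores(features, alpha=alpha)
    state_ids = np.array([f.state_id for f in features])
    dmat = np.vstack([f.pairwise_distance for f in features])
    if dmat.shape != (n, n):
        raise ValueError("pairwise_distance vectors must form an n x n matrix")
    deflation = np.ones(n)
    available = np.ones(n, dtype=bool)
    selected: list[int] = []
    scores_at: list[float] = []
    for _ in range(k):
        eff = np.where(available, base * deflation, -np.inf)
        best = int(np.lexsort((state_ids, -eff))[0])
        selected.append(int(state_ids[best]))
        scores_at.append(float(eff[best]))
        available[best] = False
        deflation *= 1.0 - np.exp(-dmat[best] ** 2 / (2.0 * width ** 2))
    return SelectionResult(selected_state_ids=selected, scores_at_selection=scores_at)
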