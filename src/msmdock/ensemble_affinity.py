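"""MSM-weighted macro-affinity aggregation and compound-ranking evaluation.

Per-state affinity predictions (predicted pKi values, or docking free
energies in kcal/mol) are converted to association constants, combined into
a macro association constant with the equilibrium weights of the Markov
state model,

    Ka = sum_i pi_i * Ka_i,          Ka_i = 10**pKi_i  or  exp(-dG_i / RT),

and converted back to a macro pKi by taking −log10 of the inverse of Ka.
Because the sum runs over association constants, states contribute in
proportion to both their equilibrium probability and how strongly they bind
— a rare high-affinity (open-pocket) state can dominate the macroscopic
affinity.  Ranking quality against measured potencies is scored with the
tie-corrected Kendall τ_b, with bootstrap confidence bands for the fitted
predicted-vs-measured line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

GAS_CONSTANT_KCAL = 1.98720425864083e-3   # kcal/(mol*K)
DEFAULT_TEMPERATURE = 310.0               # K, the simulation temperature

AFFINITY_SOURCES = ("pki_predictor", "docking")


class AffinityError(ValueError):
    pass


@dataclass(frozen=True)
class AffinityPrediction:
    """A per-state affinity prediction for one compound.

    Exactly one of ``pki`` (log10 scale) or ``delta_g`` (kcal/mol) is set,
    matching ``source``.
    """

    compound_id: str
    state_id: int
    source: str
    pki: float | None = None
    delta_g: float | None = None

    def __post_init__(self) -> None:
        if self.source not in AFFINITY_SOURCES:
            raise AffinityError(f"unknown source {self.source!r}")
        if self.source == "pki_predictor" and (self.pki is None or self.delta_g is not None):
            raise AffinityError("pki_predictor predictions carry pki only")
        if self.source == "docking" and (self.delta_g is None or self.pki is not None):
            raise AffinityError("docking predictions carry delta_g only")


@dataclass(frozen=True)
class MacroAffinity:
    compound_id: str
    macro_ka: float
    macro_pki: float


@dataclass(frozen=True)
class RankingResult:
    tau_b: float
    n_compounds: int
    bootstrap_ci: tuple[float, float] | None = None


# --------------------------------------------------------------------------
# Unit conversions
# --------------------------------------------------------------------------

def pki_to_ka(pki: float) -> float:
    """Association constant from pKi: ``Ka = 1/Ki = 10**pKi``."""
    return float(10.0 ** np.asarray(pki, dtype=float))


def ka_to_pki(ka: float) -> float:
    """pKi from an association constant: ``-log10(1/Ka) = log10(Ka)``."""
    ka = float(ka)
    if ka <= 0:
        raise AffinityError("association constant must be positive")
    return float(-np.log10(1.0 / ka))


def dock_to_ka(delta_g: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Association constant from a docking free energy (kcal/mol)."""
    if temperature <= 0:
        raise AffinityError("temperature must be positive")
    return float(np.exp(-float(delta_g) / (GAS_CONSTANT_KCAL * temperature)))


# --------------------------------------------------------------------------
# Macro aggregation
# --------------------------------------------------------------------------

def macro_ka(
    pi: np.ndarray,
    ka_per_state: np.ndarray,
    present_mask: np.ndarray | None = None,
) -> float:
    """Equilibrium-weighted macro association constant ``sum_i pi_i Ka_i``.

    States where no pose exists (``present_mask`` False) contribute 0; π is
    never renormalized over the present subset.  All-absent input is an
    error because the macro affinity is then undefined.
    """
    pi = np.asarray(pi, dtype=float)
    ka = np.asarray(ka_per_state, dtype=float)
    if pi.shape != ka.shape:
        raise AffinityError("pi and ka_per_state must be aligned")
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
        raise AffinityError("pi must be a probability vector summing to 1")
    mask = (
        np.ones_like(pi, dtype=bool)
        if present_mask is None
        else np.asarray(present_mask, dtype=bool)
    )
    if not np.any(mask):
        raise AffinityError("affinity undefined: compound absent in every state")
    if np.any(ka[mask] <= 0):
        raise AffinityError("association constants must be positive")
    return float(np.sum(pi[mask] * ka[mask]))


def aggregate_compound(
    predictions: Sequence[AffinityPrediction],
    pi: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
) -> MacroAffinity:
    """Macro affinity of one compound from its per-state predictions.

    Predictions must all come from one source (pKi predictor or docking —
    the two scales are aggregated separately, never mixed), at most one per
    state; states without a prediction are treated as absent.
    """
    if not predictions:
        raise AffinityError("no predictions to aggregate")
    compound_ids = {p.compound_id for p in predictions}
    if len(compound_ids) != 1:
        raise AffinityError(f"predictions span several compounds: {sorted(compound_ids)}")
    sources = {p.source for p in predictions}
    if len(sources) != 1:
        raise AffinityError("mixed prediction sources; aggregate docking and pKi separately")
    source = sources.pop()
    pi = np.asarray(pi, dtype=float)
    ka = np.zeros_like(pi)
    present = np.zeros_like(pi, dtype=bool)
    for p in predictions:
        if not 0 <= p.state_id < pi.size:
            raise AffinityError(f"state id {p.state_id} outside 0..{pi.size - 1}")
        if present[p.state_id]:
            raise AffinityError(f"duplicate prediction for state {p.state_id}")
        present[p.state_id] = True
        ka[p.state_id] = (
            pki_to_ka(p.pki)
            if source == "pki_predictor"
            else dock_to_ka(p.delta_g, temperature=temperature)
        )
    macro = macro_ka(pi, ka, present_mask=present)
    return MacroAffinity(
        compound_id=compound_ids.pop(), macro_ka=macro, macro_pki=ka_to_pki(macro)
    )


# --------------------------------------------------------------------------
# Ranking evaluation
# --------------------------------------------------------------------------

def kendall_tau_b(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 0,
    seed: int | None = None,
) -> RankingResult:
    """Tie-corrected Kendall rank correlation τ_b between two value lists.

    ``n_boot > 0`` adds a percentile 95% bootstrap confidence interval over
    resampled compound pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AffinityError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise AffinityError("need at least two compounds to rank")
    tau = float(stats.kendalltau(x, y, variant="b").statistic)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        taus = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            t = stats.kendalltau(x[idx], y[idx], variant="b").statistic
            if np.isfinite(t):
                taus.append(t)
        ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))
    return RankingResult(tau_b=tau, n_compounds=n, bootstrap_ci=ci)


def bootstrap_fit(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Least-squares line with percentile-bootstrap 95% bands.

    Resamples (x, y) pairs with replacement; returns the point estimates and
    the 2.5/97.5 percentile interval for slope and intercept.  Reproducible
    for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise AffinityError("need at least three paired points")
    if n_boot < 100:
        raise AffinityError("n_boot must be at least 100")
    if np.ptp(x) == 0:
        raise AffinityError("x has zero variance; line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        while np.ptp(x[idx]) == 0:   # degenerate resample; redraw
            idx = rng.integers(0, x.size, size=x.size)
        slopes[i], intercepts[i] = np.polyfit(x[idx], y[idx], 1)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "slope_ci": (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5))),
        "intercept_ci": (
            float(np.percentile(intercepts, 2.5)),
            float(np.percentile(intercepts, 97.5)),
        ),
        "n_boot": int(n_boot),
    }


def pic50_from_ic50(ic50_molar: float) -> float:
    """pIC50 from an IC50 in mol/L, for rank-only comparisons."""
    if ic50_molar <= 0:
        raise AffinityError("IC50 must be positive")
    return float(-np.log10(ic50_molar))
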