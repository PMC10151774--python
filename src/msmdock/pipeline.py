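"""End-to-end orchestration of the cryptic-pocket / MSM-docking analysis.

The pipeline chains the stages of the ensemble virtual-screening method:

1. obtain a conformational ensemble (from file, or the synthetic generator);
2. cluster it with k-centers under Cα RMSD and build the Markov state model,
   giving equilibrium weights π over cluster states;
3. detect pockets on the closed and open conformations and build padded
   docking boxes around pocket points;
4. obtain per-state docked poses (from file, or planted by the generator),
   classify them by region contacts and compute MSM-weighted site scores;
5. aggregate per-state affinity predictions into macro pKi values and score
   the compound ranking against measured potencies with Kendall τ_b,
   comparing the MSM-weighted route against a single closed reference state
   and against raw (decoy) docking scores.

Configuration is a flat YAML-serializable dataclass whose defaults are the
method's published parameter choices (1.4 Å probe, PSP rank 7, minimum
cluster of 3 grid points, 2 Å cluster radius, 1/n pseudocount, 4 Å contact
cutoff, 0.5 quality threshold, 5 Å box padding, 10 seeds at 3 Å similarity
width).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ligsite, structures_io
from .ensemble_affinity import (
    AffinityPrediction,
    aggregate_compound,
    bootstrap_fit,
    kendall_tau_b,
)
from .fast_ranking import StateFeatures, select_seeds
from .msm import build_msm, ca_rmsd, count_transitions, kcenters_cluster
from .pose_analysis import (
    PoseRecord,
    best_pose_per_state,
    classify_pose,
    filter_high_quality,
    find_contacts,
    msm_weighted_site_score,
    read_poses_csv,
    residue_contact_frequency,
    write_poses_csv,
)
from .structures_io import (
    ACTIVE_SITE_REGION,
    FLAP_REGION,
    FLAP_REGION_WIDE,
    HINGE_REGION,
    HINGE_REGION_NARROW,
    make_docking_box,
    read_ensemble,
)
from .synthetic_data import (
    ScreenSpec,
    SyntheticScreen,
    ToyProteinSpec,
    make_markov_ensemble,
    make_synthetic_screen,
    make_toy_protein,
)

logger = logging.getLogger("msmdock.pipeline")


@dataclass
class PipelineConfig:
    """All stage parameters plus input locations.

    ``mode`` is ``synthetic`` (generate every input from ``seed``) or
    ``files`` (read the ensemble, poses and potency table from the given
    paths).  Parameter defaults follow the published protocol wherever the
    protocol states one.
    """

    mode: str = "synthetic"
    out_dir: str = "msmdock_out"
    seed: int = 11

    # pocket detection
    grid_spacing: float = ligsite.DEFAULT_GRID_SPACING
    probe_radius: float = ligsite.DEFAULT_PROBE_RADIUS
    min_psp: int = ligsite.DEFAULT_MIN_PSP
    min_cluster_size: int = ligsite.DEFAULT_MIN_CLUSTER_SIZE
    pocket_score_min: float = 0.2

    # clustering / MSM
    cluster_radius: float = 2.0
    lag: int = 1
    pseudocount: str | float = "auto"

    # seed ranking
    n_seeds: int = 10
    similarity_width: float = 3.0   # 1.5 x the 2 Å cluster radius

    # pose analysis / aggregation
    contact_cutoff: float = 4.0
    quality_threshold: float = 0.5
    temperature: float = 310.0
    box_padding: float = 5.0
    flap_variant: str = "methods"    # "methods" (219-288) or "wide" (219-295)
    hinge_variant: str = "methods"   # "methods" (150-167) or "narrow" (150-166)

    # synthetic mode
    n_states: int = 20
    open_fraction: float = 0.25
    chain_steps: int = 600
    frame_jitter_sd: float = 0.08
    state_deform_sd: float = 0.5
    synthetic_cluster_radius: float = 0.3
    self_transition: float = 0.7

    # file mode
    ensemble_pdb: str | None = None
    receptor_pdb: str | None = None
    poses_csv: str | None = None
    measured_csv: str | None = None
    reference_state: int = 0

    def regions(self) -> dict:
        flap = FLAP_REGION if self.flap_variant == "methods" else FLAP_REGION_WIDE
        hinge = HINGE_REGION if self.hinge_variant == "methods" else HINGE_REGION_NARROW
        return {"flap": flap, "hinge": hinge, "active_site": ACTIVE_SITE_REGION}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


# --------------------------------------------------------------------------
# Site scoring
# --------------------------------------------------------------------------

def site_quality_by_state(
    poses, receptor, regions: dict, cutoff: float = 4.0
) -> dict[str, dict[int, float]]:
    """Best pose-quality score per (site category, state) from contacts.

    Every pose is classified by the residues it contacts; within each
    category and state the highest quality score is kept.  Categories a
    state never presents are simply absent (they weigh 0 downstream).
    """
    out: dict[str, dict[int, float]] = {}
    for pose in poses:
        contacts = find_contacts(pose, receptor, cutoff=cutoff)
        cat = classify_pose(
            contacts, regions["flap"], regions["hinge"], regions["active_site"]
        ).category
        per_state = out.setdefault(cat, {})
        if pose.quality_score > per_state.get(pose.state_id, -1.0):
            per_state[pose.state_id] = pose.quality_score
    return out


def site_scores_per_compound(
    poses, receptor, regions: dict, pi: np.ndarray, cutoff: float = 4.0
) -> pd.DataFrame:
    """MSM-weighted site score per compound and site category.

    For each compound, poses are classified by contacts, the best-quality
    pose per (category, state) is kept, and scores are averaged under π —
    one row per compound, one column per category observed (NaN where a
    compound never posed in a category).  Comparing the per-compound
    distributions across categories is how the preferred binding site is
    read off.
    """
    by_compound: dict[str, list] = {}
    for pose in poses:
        by_compound.setdefault(pose.compound_id, []).append(pose)
    rows = []
    for compound, group in sorted(by_compound.items()):
        scores = msm_weighted_site_score(
            site_quality_by_state(group, receptor, regions, cutoff=cutoff), pi
        )
        rows.append({"compound_id": compound, **scores})
    return pd.DataFrame(rows).set_index("compound_id")


# --------------------------------------------------------------------------
# Ranking evaluation
# --------------------------------------------------------------------------

def evaluate_screen(
    poses,
    measured: pd.DataFrame,
    pi: np.ndarray,
    reference_state: int = 0,
    temperature: float = 310.0,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """The three ranking routes of the method, scored with Kendall τ_b.

    * MSM-weighted: per-state predicted pKi of the best pose per state,
      aggregated into a macro pKi with weights π;
    * single-reference: the predicted pKi at the closed reference state
      alone (what a static ground-state structure would give);
    * docking: decoy docking free energies aggregated the same way.

    Returns the per-compound macro table and the three τ_b values plus a
    bootstrap band for the MSM-weighted predicted-vs-measured line.
    """
    best = best_pose_per_state(poses)
    measured = measured.set_index("compound_id")
    compounds = list(measured.index)

    macro_rows = []
    for c in compounds:
        pki_preds = []
        dock_preds = []
        ref_pki = np.nan
        for (cid, state), pose in best.items():
            if cid != c:
                continue
            if pose.predicted_pki is not None:
                pki_preds.append(
                    AffinityPrediction(
                        compound_id=c, state_id=state, source="pki_predictor",
                        pki=float(pose.predicted_pki),
                    )
                )
                if state == reference_state:
                    ref_pki = float(pose.predicted_pki)
            dock_preds.append(
                AffinityPrediction(
                    compound_id=c, state_id=state, source="docking",
                    delta_g=float(pose.docking_score),
                )
            )
        if not pki_preds:
            raise PipelineError(f"compound {c} has no pKi predictions")
        macro = aggregate_compound(pki_preds, pi, temperature=temperature)
        macro_dock = aggregate_compound(dock_preds, pi, temperature=temperature)
        macro_rows.append(
            {
                "compound_id": c,
                "measured_pki": float(measured.loc[c, "measured_pki"]),
                "macro_pki": macro.macro_pki,
                "macro_pki_docking": macro_dock.macro_pki,
                "reference_state_pki": ref_pki,
            }
        )
    table = pd.DataFrame(macro_rows)
    if table["reference_state_pki"].isna().any():
        raise PipelineError(
            f"reference state {reference_state} lacks predictions for some compounds"
        )

    x = table["measured_pki"].to_numpy()
    result = {
        "macro_table": table,
        "tau_msm_weighted": kendall_tau_b(x, table["macro_pki"].to_numpy()).tau_b,
        "tau_single_reference": kendall_tau_b(
            x, table["reference_state_pki"].to_numpy()
        ).tau_b,
        "tau_docking": kendall_tau_b(x, table["macro_pki_docking"].to_numpy()).tau_b,
        "n_compounds": len(compounds),
        "potency_type": str(measured["potency_type"].iloc[0])
        if "potency_type" in measured
        else "pKi",
    }
    if n_boot > 0:
        result["fit_msm_weighted"] = bootstrap_fit(
            x, table["macro_pki"].to_numpy(), n_boot=n_boot, seed=seed
        )
    return result


# --------------------------------------------------------------------------
# Synthetic ensemble with designed state structures
# --------------------------------------------------------------------------

def _synthetic_ensemble(config: PipelineConfig, rng: np.random.Generator):
    """A Markov ensemble over toy conformations, 25% presenting the cavity.

    Each designed state is the open (cavity-bearing) or closed (collapsed)
    toy shell plus a fixed per-state deformation; the chain mixes with a
    fixed self-transition probability toward a Dirichlet-drawn target
    distribution, whose stationary vector is that target exactly.  State 0
    is closed and starts the chain, so the first cluster center — the
    static reference — is a closed conformation.
    """
    closed, open_ = make_toy_protein(ToyProteinSpec())
    n = config.n_states
    n_open = max(1, round(config.open_fraction * n))
    open_states = set(
        int(s) for s in rng.choice(np.arange(1, n), size=n_open, replace=False)
    )
    from dataclasses import replace

    conformations = {}
    for s in range(n):
        base = open_ if s in open_states else closed
        deform = rng.normal(0.0, config.state_deform_sd, base.coord.shape)
        conformations[s] = replace(base, coord=base.coord + deform)

    pi_target = rng.dirichlet(np.full(n, 2.0))
    tmat = config.self_transition * np.eye(n) + (1 - config.self_transition) * np.tile(
        pi_target, (n, 1)
    )
    frames, true_states = make_markov_ensemble(
        tmat,
        config.chain_steps,
        conformations,
        seed=int(rng.integers(2**31 - 1)),
        jitter_sd=config.frame_jitter_sd,
    )
    # Make sure the trajectory starts in a closed state: the first k-centers
    # center is frame 0, and that cluster serves as the static reference.
    closed_frames = np.flatnonzero(~np.isin(true_states, sorted(open_states)))
    if true_states[0] in open_states and closed_frames.size:
        j = int(closed_frames[0])
        frames[0], frames[j] = frames[j], frames[0]
        true_states = true_states.copy()
        true_states[0], true_states[j] = true_states[j], true_states[0]
    return frames, true_states, open_states, pi_target, closed, open_


# --------------------------------------------------------------------------
# run_pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write per-stage artifacts plus a summary JSON.

    Returns the summary dictionary (also written to ``summary.json`` in
    ``config.out_dir``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"mode": config.mode, "seed": config.seed}
    regions = config.regions()

    if config.mode == "synthetic":
        frames, true_states, open_states, pi_target, closed, open_ = _stage(
            "ensemble"
        )(_synthetic_ensemble)(config, rng)
        cluster_radius = config.synthetic_cluster_radius
    elif config.mode == "files":
        frames = _stage("ensemble")(_read_frames)(config)
        true_states = None
        cluster_radius = config.cluster_radius
    else:
        raise PipelineError(f"stage 'config' failed: unknown mode {config.mode!r}")

    # ---- pockets on the reference (frame 0) and the most open conformation
    @_stage("pockets")
    def _pockets():
        if config.mode == "synthetic":
            pairs = {"closed": closed, "open": open_}
        else:
            pairs = {"reference": frames[0]}
        volumes = {}
        boxes = {}
        pocket_rows = []
        for name, s in pairs.items():
            grid = ligsite.build_grid(
                s, spacing=config.grid_spacing, probe_radius=config.probe_radius
            )
            pockets = ligsite.detect_pockets(
                grid,
                min_psp=config.min_psp,
                min_cluster_size=config.min_cluster_size,
                structure=s,
            )
            volumes[name] = ligsite.total_pocket_volume(pockets)
            for i, p in enumerate(pockets):
                pocket_rows.append(
                    {
                        "conformation": name,
                        "pocket_id": i,
                        "n_points": p.n_points,
                        "volume_A3": p.volume,
                        "lining_residues": ";".join(map(str, sorted(p.lining_residues))),
                    }
                )
            if pockets:
                points = np.vstack(
                    [grid.point_coords(p.point_indices) for p in pockets]
                )
                boxes[name] = make_docking_box(points, padding=config.box_padding)
        pd.DataFrame(pocket_rows).to_csv(out / "pockets.csv", index=False)
        return volumes, boxes

    volumes, boxes = _pockets()
    summary["total_pocket_volume_A3"] = volumes
    summary["docking_boxes"] = {
        k: {"min_corner": list(b.min_corner), "max_corner": list(b.max_corner)}
        for k, b in boxes.items()
    }

    # ---- clustering + MSM
    @_stage("msm")
    def _msm():
        model = kcenters_cluster(frames, radius=cluster_radius)
        counts = count_transitions(model.assignments, lag=config.lag)
        tm = build_msm(counts, pseudocount=config.pseudocount)
        pd.DataFrame(
            {"frame_id": np.arange(len(frames)), "state_id": model.assignments}
        ).to_csv(out / "assignments.csv", index=False)
        np.savetxt(out / "transition_matrix.csv", tm.transition_matrix, delimiter=",")
        np.savetxt(out / "equilibrium.csv", tm.equilibrium, delimiter=",")
        return model, tm

    cluster_model, tmodel = _msm()
    summary["n_msm_states"] = cluster_model.n_states
    pi_hat = tmodel.equilibrium

    # ---- FAST-style seed ranking over cluster states
    @_stage("rank_states")
    def _rank():
        centers = [frames[i] for i in cluster_model.center_frame_indices]
        n = len(centers)
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = ca_rmsd(centers[i], centers[j])
        feats = []
        visits = np.bincount(cluster_model.assignments, minlength=n)
        for i, c in enumerate(centers):
            grid = ligsite.build_grid(
                c, spacing=config.grid_spacing, probe_radius=config.probe_radius
            )
            pockets = ligsite.detect_pockets(
                grid, min_psp=config.min_psp, min_cluster_size=config.min_cluster_size
            )
            feats.append(
                StateFeatures(
                    state_id=i,
                    pocket_volume=ligsite.total_pocket_volume(pockets),
                    visit_count=int(visits[i]),
                    pairwise_distance=dmat[i],
                )
            )
        sel = select_seeds(
            feats,
            k=min(config.n_seeds, n),
            width=config.similarity_width
            if config.mode == "files"
            else 1.5 * cluster_radius,
        )
        pd.DataFrame(
            {
                "rank": np.arange(len(sel.selected_state_ids)),
                "state_id": sel.selected_state_ids,
                "score_at_selection": sel.scores_at_selection,
            }
        ).to_csv(out / "fast_seeds.csv", index=False)
        return feats, sel

    features, selection = _rank()
    summary["fast_seed_states"] = selection.selected_state_ids

    # ---- poses and potencies
    @_stage("poses")
    def _poses():
        if config.mode == "synthetic":
            open_clusters = frozenset(
                i
                for i, f in enumerate(cluster_model.center_frame_indices)
                if int(true_states[f]) in open_states
            )
            screen = make_synthetic_screen(
                ScreenSpec(
                    n_states=cluster_model.n_states,
                    open_state_ids=open_clusters,
                    open_fraction=config.open_fraction,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            write_poses_csv(screen.poses, out / "poses.csv")
            screen.measured.to_csv(out / "measured.csv", index=False)
            return screen.receptor, screen.poses, screen.measured
        receptor = structures_io.read_structure(_required(config.receptor_pdb, "receptor_pdb"))
        poses = read_poses_csv(_required(config.poses_csv, "poses_csv"))
        measured = pd.read_csv(_required(config.measured_csv, "measured_csv"))
        return receptor, poses, measured

    receptor, poses, measured = _poses()

    # ---- classification + MSM-weighted site scores
    @_stage("classify")
    def _classify():
        per_compound = site_scores_per_compound(
            poses, receptor, regions, pi_hat, cutoff=config.contact_cutoff
        )
        per_compound.to_csv(out / "site_scores.csv")
        weighted = per_compound.mean(axis=0).to_dict()
        hq = filter_high_quality(poses, threshold=config.quality_threshold)
        freq = residue_contact_frequency(hq, receptor, cutoff=config.contact_cutoff) if hq else {}
        pd.DataFrame(
            sorted(freq.items()), columns=["residue_number", "contact_frequency"]
        ).to_csv(out / "contact_frequency.csv", index=False)
        return weighted, len(hq)

    weighted_site_scores, n_high_quality = _classify()
    summary["msm_weighted_site_scores"] = weighted_site_scores
    summary["n_high_quality_poses"] = n_high_quality

    # ---- aggregation + ranking evaluation
    @_stage("evaluate")
    def _evaluate():
        res = evaluate_screen(
            poses,
            measured,
            pi_hat,
            reference_state=config.reference_state,
            temperature=config.temperature,
            seed=config.seed,
        )
        res["macro_table"].to_csv(out / "macro_affinities.csv", index=False)
        return res

    evaluation = _evaluate()
    summary["tau_msm_weighted"] = evaluation["tau_msm_weighted"]
    summary["tau_single_reference"] = evaluation["tau_single_reference"]
    summary["tau_docking"] = evaluation["tau_docking"]
    summary["n_compounds"] = evaluation["n_compounds"]
    summary["potency_type"] = evaluation["potency_type"]
    summary["fit_msm_weighted"] = evaluation["fit_msm_weighted"]

    if config.mode == "synthetic":
        # Ground truth is known: report how well the MSM recovered it.
        center_truth = [int(true_states[f]) for f in cluster_model.center_frame_indices]
        pi_true_mapped = np.zeros(cluster_model.n_states)
        for i, t in enumerate(center_truth):
            pi_true_mapped[i] = pi_target[t]
        # Clusters may split a designed state; compare on the mapped support.
        if len(set(center_truth)) == len(center_truth):
            summary["pi_max_abs_error"] = float(
                np.max(np.abs(pi_hat - pi_true_mapped / pi_true_mapped.sum()))
            )
        summary["n_designed_states"] = config.n_states

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _required(path: str | None, name: str) -> str:
    if path is None:
        raise FileNotFoundError(f"config field {name!r} is required in files mode")
    if not Path(path).exists():
        raise FileNotFoundError(f"{name}: no such file: {path}")
    return path


def _read_frames(config: PipelineConfig):
    return read_ensemble(_required(config.ensemble_pdb, "ensemble_pdb"))
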