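# Methods

This note documents the models, parameter choices, numerical details and
limitations of `msmdock`. It is written for someone who wants to judge
what the package computes and what its passing tests do and do not show.

## The analysis in one paragraph

A target's ground-state structure can lack the pocket its inhibitors use.
The method samples conformations, detects pockets on a grid, clusters the
ensemble into discrete states, builds a Markov state model (MSM) whose
stationary distribution π weighs each state, docks compounds against each
state's representative structure, classifies and quality-filters the
resulting poses, and finally aggregates per-state affinity predictions
into a macroscopic association constant Ka = Σᵢ πᵢ·Kaᵢ. Compound ranking
by the macro pKᵢ is compared against ranking from a single reference
structure and from raw docking scores, using the tie-corrected Kendall
τ_b.

## Pocket detection (ligsite)

A cubic grid (default spacing 1.0 Å) covers the structure with enough
margin that no occupied point touches the boundary; the origin is snapped
to a multiple of the spacing so the digital geometry is reproducible. A
grid point is protein iff it lies within vdW(element) + probe of a protein
heavy atom, with a fixed radius table (C 1.7, N 1.55, O 1.52, S 1.8,
P 1.8, default 1.7 Å) and probe radius 1.4 Å (0.14 nm). For every solvent
point we count protein–solvent–protein (PSP) events along 7 scan
directions (3 axes, 4 cube diagonals): an event requires protein on both
sides of the ray. Points with PSP count ≥ 7 (fully enclosed) are clustered
by face adjacency (6-connectivity); clusters under 3 points are dropped.
Pocket volume is point count × spacing³; the total over pockets is the
adaptive-sampling reward. Ties in pocket ordering break by (volume
descending, smallest flat grid index).

Per-residue pocket scores use score(r) = 1 − exp(−k·n_r) with n_r the
number of pocket points within 4.0 Å of residue r's heavy atoms and
k = 0.05 (27 nearby points ≈ 0.74). This is a generic, bounded stand-in
for an external pocket scorer's per-residue ligand-binding probability;
the scale is ours. The generic pocket filter keeps pockets with score
> 0.2, mirroring a permissive external-scorer threshold.

Numerical caveat: pocket volume at 1 Å spacing is offset-sensitive when
the cavity's solvent span is only a few Å across; the rotation-robustness
property is therefore checked at 0.4 Å spacing, where the measured change
under arbitrary rotation is ~10% (and a 90° axis-aligned turn is exact at
any spacing).

## Clustering and MSM (msm)

Frames sharing a topology are clustered by greedy k-centers under Cα RMSD
minimized over rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`). The first center is
frame 0 (deterministic); each next center is the farthest frame; clustering
stops when the cover radius reaches 2 Å (the published protocol value).
Assignment ties break toward the earlier center.

Transitions are counted sliding-window at lag 1 frame (the protocol does
not state a lag; the value is exposed in config), never across trajectory
boundaries. A uniform pseudocount of 1/n_states is added to every count,
rows are normalized, and π is the left eigenvector of T for the eigenvalue
nearest 1 (power-iteration fallback; both tolerances 1e-8/1e-12). Row
normalization does not enforce detailed balance, so π is computed from the
eigenproblem, not by count symmetrization.

## Adaptive-sampling ranking (fast_ranking)

State score = α·minmax(pocket volume) + minmax(1/(visits+1)), α = 1 by
default; minmax of a constant list is defined as 0.5. Seeds are selected
greedily, multiplying each candidate's score by
Π_{j selected} (1 − exp(−d²ᵢⱼ / 2w²)) with w = 1.5 × cluster radius
(3 Å at the default 2 Å radius), so conformations similar to already
selected seeds are deflated and exact duplicates are annihilated. Ties
break toward the lowest state id. The combining form (normalized sum plus
Gaussian deflation) is stated explicitly because the protocol names the
reward components but not the formula.

## Pose analysis

Contacts are residues with a protein heavy atom within 4 Å of a ligand
heavy atom (inclusive; hydrogens ignored everywhere). Site categories:
contacting both flap and hinge → flap–hinge interface (stated precedence);
otherwise any catalytic-residue contact → active site (co-occurrence with
one flank is logged, since that reading is ambiguous); then flap only,
hinge only, other. Two region variants are supported and never silently
mixed: flap 219–288 / hinge 150–167 (classification protocol) and flap
219–295 / hinge 150–166 (figure analyses); defaults are the former,
selectable in config.

High-quality poses have quality ≥ 0.5 (inclusive). Best pose per
compound/state is by quality, ties by more negative docking score, then
input order (the docking-score tie-break is our addition, for
determinism). MSM-weighted site scores average the best per-state quality
per category under π, with absent categories contributing 0 — a state
whose structure never presented the site simply cannot bind there, and π
is never renormalized. Site preference is read per compound (each
compound's best pose per category and state), then compared across
categories.

The enrichment table compares, per residue, the ensemble maximum pocket
score against the reference conformation's score; the state with the
largest summed positive gain is reported as the most "opened" structure.

## Affinity aggregation and evaluation (ensemble_affinity)

Conversions: Ka = 10^pKi (Ka = 1/Ki), Ka = exp(−ΔG/RT) with
R = 1.98720425864083e−3 kcal/(mol·K) and T = 310 K by default (the
simulation temperature; the Boltzmann-conversion temperature is not stated
in the protocol, so it is configurable). The macro association constant is
Σ πᵢ Kaᵢ over states with a prediction; macro pKᵢ = −log10(1/Ka),
implemented literally and tested as an exact identity. pKᵢ and docking
predictions are never mixed in one aggregation. Measured potencies may be
pKᵢ or pIC50 (−log10 IC50 in M); the potency type is recorded in every
report and never mixed within one τ computation.

τ_b uses the tie-corrected form (scipy, variant "b"); an independent
O(n²) pair-count oracle validates it in tests. The predicted-vs-measured
line gets a percentile 95% bootstrap band over resampled pairs
(seeded; degenerate resamples with zero x-variance are redrawn).

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for all tests.

**Cavity toy.** The open form is a hollow cubic shell of carbon
pseudo-atoms (one residue per atom, 11 per edge, 10 Å side) whose interior
survives vdW+probe inflation as a 27-point pocket at 1 Å spacing; the
closed form is the same shell contracted to a 6 Å side, where inflation
fills the interior — a collapsed cavity, like a ground-state structure
that lacks the pocket. `open_fraction` removes part of one wall of the
open form (atoms nearest the wall center first), reducing enclosure.
Closed and open share one topology so they can serve as conformations of
one Markov ensemble.

**Markov ensembles.** Chains are sampled from a given row-stochastic
matrix starting from its stationary distribution; frames are the mapped
conformations plus isotropic jitter well below the cluster radius. The
pipeline's synthetic ensemble uses per-state fixed deformations (0.5 Å)
with 0.08 Å frame jitter and clusters at a 0.3 Å radius — scaled-down
stand-ins for distinct metastable conformations at the 2 Å production
radius.

**Synthetic screen.** Nine compounds with true pKᵢ evenly spaced 4–8
(a realistic potency span for a small allosteric series), twenty states of
which 25% present the interface pocket (state 0 always closed, serving as
the static reference), and per-state predictions with noise σ = 1.0 pKᵢ
units — a typical error for an affinity predictor on an unseen target.
Compound-specific signal is carried only by open-pocket states: closed
states attenuate the deviation from the screen-mean pKᵢ by 0.5 and
subtract a 1.5-unit loss, modeling a pose-sensitive predictor falling back
toward a ligand-only baseline when the pocket is absent. The attenuation
is what makes the single-reference ranking genuinely worse rather than
merely offset (a constant shift cannot change a ranking); with these
defaults the ensemble route beats the static route in ~96–99 of 100 seeds
and the mean τ values (≈0.81 / 0.44 / 0.0 for ensemble / static / decoy
docking) sit in the regime the method is designed to demonstrate. Docking
scores are pure decoys, N(−7, 1.5²) kcal/mol, uncorrelated with potency.
Pose-quality scores are truncated normals: mean 0.75 for interface poses
in open states, 0.30 everywhere else, σ 0.15, clipped to [0, 1].

What the screen does *not* emulate: real ligand chemistry or geometry,
correlated errors between compounds, predictor bias (regression to the
mean), or the negative docking-potency correlation some screens show —
decoys here are uncorrelated, so the docking τ is centered at 0 rather
than negative. Passing tests therefore show that the aggregation machinery
extracts an open-state-borne signal under noise, not that any particular
real screen would reach a given τ.

**Planted poses.** The screen receptor is a pseudo-atom layout whose
residue numbering matches the real regions: hinge blob at the origin, flap
blob 8 Å away, catalytic blob 20 Å away, with three-atom ligands planted
at four anchors chosen so each pose contacts exactly the intended
region(s) at the 4 Å cutoff.

## Problem sizes

The test suite and the acceptance script use: 600-step chains over 20
designed states for the end-to-end pipeline (~5 s), 50 000-step chains for
MSM parameter recovery (transition-matrix entries recover to <0.01 at
these lengths), 100-seed sweeps for the ranking-ordering statistics, and
grids up to 20³ for exact oracle comparison. These sizes were chosen so
statistical claims have comfortable margins while the whole suite runs in
well under a minute per module.

## Known limitations

* The pocket detector is exact digital geometry, not a solvent-accessible
  surface; volumes at coarse spacing are offset-sensitive (see above).
* k-centers is a covering heuristic: cluster populations (hence π) depend
  on the greedy center order; only the cover radius is guaranteed.
* The MSM assumes the frame interval is a valid lag; no implied-timescale
  analysis is provided.
* File-mode pose tables must reference the supplied ensemble's cluster
  indices (the workflow is: cluster, dock to the exported centers, feed
  poses back); mismatched state ids are rejected rather than guessed.
* Insertion codes are rejected on input; renumber structures first.
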