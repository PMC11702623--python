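# Methods

## Model and pipeline

The package treats the cortical surface as a subdivided icosahedron on the
unit sphere. Subdivision keeps parent vertices as an index prefix and
appends edge midpoints in sorted-edge order, so the standard resolutions
(2 562 / 10 242 / 40 962 vertices at levels 4–6, plus the coarser levels
used for testing) are nested: sampling a lower resolution is taking an
index prefix. Neighbor rings are stored in the cyclic order induced by the
outward-oriented triangle fans, starting at the lowest-index neighbor;
this fixes deterministic semantics for ring rotation (one step = 60° at
hexagonal vertices, 72° at the twelve pentagons) and for translation
directions.

An LGM is computed per scan as: vertex-wise RSFC → Fisher r-to-z →
second-order correlation between connectivity rows → per-row surface
gradient → per-row watershed boundary map → vertex-wise mean of the binary
boundary maps. The per-session map is the AP/PA average where both
acquisitions exist.

### Gradient operator

The gradient magnitude at v is `sqrt(2 · mean_u ((f(u) − f(v)) / ‖x_u −
x_v‖)²)` over the 1-ring. The √2 factor makes the estimator consistent:
for ring directions distributed evenly in the tangent plane the mean
squared directional derivative is half the squared gradient magnitude
(Σ cos²θ = d/2 for a symmetric d-ring). Against the closed form for
f = z on the sphere (|∇f| = √(1−z²)) the level-4 maximum relative error
away from the poles is about 6%. The operator is strictly local and
rotation-agnostic; no pre-smoothing of the RSFC-2nd rows is applied.

### Watershed

Flooding from local minima in increasing (value, vertex index) order. A
vertex is a seed minimum if no neighbor is strictly lower; minima on one
equal-valued plateau (connected through equal-valued edges, union-find)
merge into a single seed, so a constant map yields one basin and an empty
boundary. A vertex flooded while its already-labeled basin neighbors carry
two or more distinct labels becomes a boundary vertex and joins no basin;
a vertex reachable only through boundary vertices is also marked boundary.
The tie rule (vertex index) makes the output bit-reproducible.

### Degenerate inputs

Zero-variance BOLD rows and constant connectivity rows keep their place in
the matrices with correlations set to 0 and are reported in a provenance
record. Constant patches in LCM computation likewise give 0, keeping
center sets aligned across subject pairs. Fisher z clips |r| at 1 − 1e−7.

### Memory

At 40 962 vertices the dense V×V matrices are ~13 GB in float64. Above a
configurable vertex threshold (default 8 192) `compute_lgm` stores only
the standardized z-RSFC in float32 (~6.7 GB at level 6) and generates each
RSFC-2nd row on the fly by a matrix–vector product, never materializing
the second matrix. The float32 path changes boundary decisions only at
numerically knife-edge vertices (observed LGM differences < 0.02 at the
levels where both paths run).

## Fingerprinting

The LCM tensor holds `C_ij(v)` for every target subject i, base subject j
and sampled center v. Vertex-wise identification gives each center one
vote for `argmax_j C_ij(v)`; per-center ties split the vote fractionally;
the predicted identity is the vote argmax with global ties resolved to the
lowest subject index and flagged. Rates are rounded half-up to one
decimal. The deformable variant deforms the **base** patch only: at a
hexagonal center the candidate set is the vanilla pairing, two ring
rotations and six one-hop translations (nine candidates); at a pentagon,
two rotations of the 5-ring and five translations (eight). A translation
candidate whose patch length differs from the center's own (the
hexagon-next-to-pentagon case) is dropped, since Pearson needs
equal-length vectors. The 36-ROI connectome baseline follows the standard
recipe: ROI-mean time series, ROI×ROI correlation, strict upper triangle,
nearest base vector by correlation.

A caution established during development: the max-over-candidates
construction inflates *all* similarities, so under noise with no
systematic misalignment the deformable strategy can *reduce*
discrimination (measured 30% vs 90% vertex-wise on a one-hop displacement
field). Its advantage appears when the base session really is sampled
through a rotated frame — there the rotation candidate restores exact
alignment (measured 90% vs 20% at σ = 0.1). The package therefore treats
deformable matching as an option, not a default.

## Contribution statistics

Uniqueness regresses y(v) = 1 − C_inter(v) on x(v) = 1 − C_intra(v) by
ordinary least squares across centers (closed-form normal equations);
U = y − αx − β. The fit is per dataset; multi-dataset analyses average the
resulting maps. Differential power uses strict inequalities ("equal" never
counts as a violation) and replaces a zero violation count with 0.5,
capping DP_i at −ln(0.5/(2(N−1))) instead of producing infinity at
perfectly separating vertices. DP depends only on the within-center value
ranks, so it is invariant to any strictly increasing transform of the
similarities.

## Prediction

Boundary bands are extracted from a reference parcellation: for every
adjacent region pair, the vertices on either side of the shared edge,
dilated three times (default) to absorb parcellation/gradient
misalignment; bands may overlap and a vertex can belong to several. A
scan's feature for a band is its mean LGM value. Within each training
fold, bands correlating with the score at two-sided p < 0.01 (t transform,
n − 2 df, no multiple-testing correction) are kept and split by sign; the
per-scan sums of the positive and negative sets form a two-dimensional
feature for a regression random forest (20 trees, minimum leaf 5,
bootstrap on, all features eligible per split). A fold selecting nothing
predicts its training-mean score. Predictions are averaged over 10
iterations of shuffled 10-fold cross-validation; accuracy is the Pearson r
between averaged predictions and observed scores. Network contributions
count selected-band vertices per network, normalized by the network's
total band vertex count, with inter-network bands counted for both sides;
leave-one-network-out removes every band touching the held-out network and
re-runs the full procedure.

Two behaviors of this procedure are worth knowing. First, the sum feature
pools every selected band, so correlated co-selected bands dilute a
single-band signal: with scores exactly equal to one band's feature the
cross-validated r is ≈ 0.88, versus ≈ 0.99 when the candidate set is
restricted to that band. Second, cross-validated r is slightly negatively
biased under the null (≈ −0.19 mean over permuted scores here): a fold's
training mean excludes the held-out scores, so null predictions
anti-correlate with them. Leakage would push this bias positive; the audit
log of per-fold train/test indices lets tests verify fold hygiene
directly.

## Synthetic cohorts

The generator emulates exactly the structure the method exploits: each
subject's parcellation is a geodesic (hop-distance) Voronoi tessellation
grown from shared seed vertices jittered per subject within a small hop
radius (individuality); the subject's template LGM is the parcel-border
indicator smoothed by two passes of 1-ring mean filtering and rescaled to
[0, 1]; each session adds Gaussian noise (σ, clipped back to [0, 1])
shared across the session, with an optional second tagged draw emulating
AP/PA phase-encoding noise. Parcel-driven BOLD (shared latent series per
parcel plus vertex noise at 1/snr) exercises the full RSFC pipeline. All
draws derive from one master seed through `SeedSequence` spawning.

Default study conditions (chosen once): 20 subjects, 2 sessions, level-3
mesh (642 vertices), 6 parcels, 2-hop jitter, session σ = 0.1, T = 200,
snr = 5. Prediction experiments use 70 subjects × 2 sessions = 140 scans
and 12 parcels grouped into 4 networks, with both causal boundary pairs
placed in one network and chosen so their dilated bands do not overlap
(`design_prediction_study`); score noise is calibrated from the sample
signal variance to a population R² of 0.36. Effect size 40 on the
[0, 1]-scale band means gives score variation of realistic magnitude for a
composite cognitive score.

What the generator does **not** model: hemodynamics, temporal
autocorrelation, motion or distortion artifacts, spatially graded
(non-parcellated) connectivity, hemispheric asymmetry, registration error
beyond the synthetic rotated-frame construction used in tests, and any
developmental change between sessions. Passing tests therefore demonstrate
the correctness and internal behavior of the algorithms under the stated
generative model, not performance on real infant data; the headline rates
of the motivating application are not reproducible at desk scale and are
not claimed here.

## Problem sizes and determinism

Tests and the acceptance script run at levels 2–3 (162 / 642 vertices)
with full-mesh center sets, where the complete pipeline (including 642
watersheds per LGM) takes seconds per scan; the level-6 mesh is exercised
for construction and connectivity. Every stochastic component takes an
explicit seed, derived seeds stay below 2³¹, and identical seeds reproduce
cohorts, fold assignments and forest predictions bit-for-bit.

## Known limitations

- The gradient operator is a stated substitute for the smoothed-gradient
  constructions used in surface-parcellation pipelines; absolute LGM
  values depend on it, though the boundary geometry is robust.
- Exactly noiseless parcel signals produce ideal gradient plateaus; any
  vertex-level jitter seeds spurious interior minima whose boundaries are
  shared across rows, raising the interior LGM floor. This mirrors the
  real-data situation (LGMs are nowhere near binary) and is why
  border/interior contrast, not absolute level, is the meaningful readout.
- With few, large parcels the dilated boundary bands of a level-3 sphere
  overlap; boundary features are then strongly correlated and
  leave-one-network-out is only interpretable when causal structure is
  confined to spatially separated bands, as `design_prediction_study`
  enforces.
- Hemispheres are handled as independent meshes; no medial-wall masking.
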