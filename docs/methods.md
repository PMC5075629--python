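# Methods

## Model and estimation

Each EEG analysis window `Y` (m channels × d samples, microvolts) is a
linear Gaussian observation of cortical current density `J` (nA·m):
`Y = GJ + ε`, `ε ~ N(0, C)`, `J ~ N(0, R)`.  The source covariance is a
weighted sum of structured components, `R = Σ_i w_i Q_i`, each `Q_i`
derived from one submap of the thresholded fMRI activation map, plus a
sensor-noise component `C`.  Weights are parameterised on the log scale,
`w_i = exp(λ_i)`: covariance weights must be non-negative, and the
shutoff hyperprior (below) only makes sense there.  A linear-weight mode
exists for study (`assemble_R(..., weight_scale="linear")`) but is not
used by the pipeline.

Hyperparameters are estimated per window by maximising the variational
free energy

    F(λ) = −(d/2)[tr(Σ(λ)⁻¹S) + ln|Σ(λ)|] − (dm/2) ln 2π
           + ½ ln|Σ^λ Π| − ½ (λ−η)ᵀ Π (λ−η),

with `Σ(λ) = Σ_i exp(λ_i) K_i`, sensor components
`K_i = {C} ∪ {G Q_i Gᵀ}`, `S = YYᵀ/d`, and
`Σ^λ = (I(λ) + Π)⁻¹` the Laplace posterior covariance from the expected
Fisher information `I_ij = (d/2) tr(Σ⁻¹K̃_i Σ⁻¹K̃_j)`, `K̃ = exp(λ)K`.
Three presentation choices deserve note:

* **Sample scaling.**  The Gaussian data terms are scaled by the number
  of samples d (i.i.d. columns), so F is the actual joint log-likelihood
  bound of the window, not a single-sample surrogate.  Constant offsets
  cancel in model comparison either way.
* **Occam term.**  The hyperparameter-uncertainty term enters as
  `½ln|Σ^λΠ|`, the form in which F is a proper lower bound on the log
  evidence: it is zero for a component the data say nothing about
  (information ≈ 0 ⇒ Σ^λ ≈ Π⁻¹) and penalises well-determined
  components, which is exactly the complexity penalty model comparison
  needs.
* **Evaluation at a point.**  `free_energy(Y, K, λ)` evaluates all terms
  *at* λ (with `Σ^λ` recomputed from the information there), so grid
  scans, the optimizer and the reported model-evidence all refer to one
  and the same function.

Optimisation is Fisher scoring preconditioned by `I(λ) + Π`, with the
gradient of the data and prior terms in closed form and the (small,
slowly varying) gradient of the Occam term by central finite differences
(h = 1e-3).  A proposed step is halved (up to 20 times) until F does not
decrease, so the recorded free-energy trace is non-decreasing on every
run by construction; iteration stops at |ΔF| < 1e-4 or 128 iterations
(`converged=False` plus a warning otherwise).  Initial weights match
component scale to data scale, `λ_i⁰ = ln(tr S / (n·tr K_i))`, clipped
below at η.  Windows with d < m are allowed: S is rank-deficient but F
only needs `Σ(λ)` to be positive definite, which the noise component
guarantees.  If a sensor-space factorisation fails, a diagonal jitter of
`1e-10·tr/m` is added once and logged; persistent failure raises with a
condition estimate.

The window's current density is the L2-norm (minimum-norm) estimate
`J = R Gᵀ (G R Gᵀ + λ^C C)⁻¹ Y`, with `λ^C = exp(μ^λ_C)` the fitted
noise weight — the regulariser is estimated by the same empirical-Bayes
machinery rather than an L-curve.  The L-curve (maximum curvature of the
log residual-norm vs log solution-norm curve over a λ grid) is used only
by the non-Bayesian static baseline, where nothing else sets the scale.

### Hyperprior

`HyperPrior(eta=-32, pi=1/256)`: each λ_i has prior mean −32 (a weight
of exp(−32) ≈ 1e-14, i.e. "off") and prior *variance* 256 (std 16), the
standard loose shutoff prior of empirical-Bayes source imaging.  The
variance matters: a *tight* prior at −32 (e.g. precision 256) would pin
every component at zero weight regardless of the data and make the
hyperparameters non-identifiable — the whole mechanism of data-driven
prior selection depends on the prior being weak.

## From fMRI map to priors

The per-vertex t map (mass-univariate OLS against a boxcar design
convolved with the canonical SPM HRF; drift columns up to order 2;
zero-residual vertices capped at |t| = 1e6) is thresholded at a
two-sided voxel p (default 0.05, t quantile with the GLM's residual
dof), labelled into connected components under shared-edge mesh
adjacency, and components smaller than `min_cluster` (default 4,
inclusive: size ≥ 4 survives) are dropped.  This voxel-p + extent rule
is a deliberate simplification of random-field/permutation FWER cluster
correction.  Surviving clusters become submaps; `mode="labels"`
additionally splits clusters by region labels.  Submaps are disjoint by
construction and enforced.

The default component encoding is the literal indicator outer product
`Q_i = q_i q_iᵀ` (rank one): all sources of a submap rise and fall
together, which matches coherent patch activity and keeps the sensor
component a cheap rank-1 outer product.  It is a strong assumption — a
patch with internally incoherent activity is better served by the
`diagonal` encoding `Q_i = diag(q_i)` (independent equal-variance
sources), provided as an alternative.

## Forward model

The built-in forward solver is the analytic concentric-three-shell
spherical model: per spherical-harmonic order n the radial potential
profile is solved from the 5×5 boundary-condition system (continuity of
potential and radial current at both interfaces, insulating scalp), and
the potential at scalp electrodes from a unit dipole follows from the
Legendre series with radii non-dimensionalised by the scalp radius for
conditioning.  Defaults: radii 87/92/100 mm; conductivities
0.33/0.004125/0.33 S/m (the literature-standard 1 : 1/80 : 1 ratio —
a package choice, configurable); series truncated at n_terms = 140,
which brings the tail below 1e-10 of the maximum gain at the default
source eccentricity 0.78 (a warning reports the tail magnitude when
truncation is too aggressive).  The implementation is validated against
the independent closed-form summation for the homogeneous sphere at
1e-8 relative accuracy.  Dipoles are fixed to the outward surface
normal; electrodes are projected radially onto the scalp shell; `G` is
average-referenced by default and must share its reference with the
data (`average_reference` is provided).  Units are fixed end-to-end:
EEG in µV, moments in nA·m, `G` in µV/(nA·m), coordinates in meters,
vertex indices 0-based.

## Pipeline

Epochs are tiled by non-overlapping windows (default 40 ms); a trailing
partial window is dropped with a warning.  The sensor-noise covariance
is estimated once per recording from the pre-stimulus baseline
(−400..0 ms), shrunk 10% toward a scaled identity, and shared across
windows; with no baseline samples it falls back to the identity.
Fitting is single-trial; `average_epochs` offers post-hoc trial
averaging.  With an empty prior set (no surviving fMRI cluster) the
spatiotemporal fit degrades gracefully to a no-prior minimum-norm model
(one whole-source-space diagonal component).

The time-invariant baseline applies `R = diag(1 on mask, w_off=0.1)` to
the whole epoch (λ^C by L-curve).  For model comparison it is scored per
window — same window grid, same ReML optimizer, a single static
covariance component — so the free-energy difference reflects the
*model* (time-variant vs static prior), not the optimizer.  Whether the
original method refits the static model's weights per window or once per
epoch is genuinely open; per-window scoring is the conservative choice
(it can only help the baseline).  `compare_models` averages converged
per-window F per method and refuses fits whose data/lead-field
provenance hashes differ.

## Synthetic scenes

`default_scene` scripts the paradigm's statistical structure on the
icosphere source space: a 7-vertex "visual" patch bursts at 100–175 ms,
a "premotor" patch at 370–460 ms and a "motor" patch at 550–650 ms
(centred on a 600 ms response time), all Gaussian bursts of equal
1 nA·m amplitude on an epoch of −400..1200 ms sampled at 1 kHz.  The
fMRI map is the static union of all patches at a fixed suprathreshold
t = 10 (dof 100); `mismatch_scene` adds one fMRI-active, EEG-silent
patch.  Sensor noise is spatially white with SNR defined as active-span
signal power over noise power in dB (default 10 dB); everything is
deterministic given the scene seed.  Desk-scale sizes (162 vertices, 32
electrodes, 1 kHz) were chosen so a full windowed fit takes well under a
second while every patch remains separable on the mesh.

What the simulator does **not** emulate: realistic ERP morphology and
latency jitter, spatially correlated (biological) noise by default — a
smooth-covariance option exists for robustness checks — head-geometry
error, BOLD hemodynamic variability, habituation, or artifacts
(EKG/ocular).  Passing tests therefore demonstrate the estimator's
correctness and its advantage under temporal mismatch in a controlled
generative world, not clinical-grade performance on real recordings.

## Evaluation metrics

Per patch: localization error is the distance between the truth's peak
vertex (largest energy within the patch over its active span) and the
estimate's peak vertex (largest energy anywhere over that span);
time-course correlation is Pearson r between patch-mean estimated and
true time courses over the epoch; leaked energy is the estimate's energy
fraction outside the union of true patches.  Window-size stability
correlates a region's reconstruction at each window length against the
shortest-window reference on the samples all runs cover.

## Numerical and design notes

* Cluster survival is inclusive (size ≥ min_cluster).
* Cluster labels are deterministic: decreasing size, ties by lowest
  vertex index.
* `free_energy` raises on a non-positive-definite Σ(λ) rather than
  returning a garbage value; exhaustive-scan callers should map that to
  F = −∞.
* The binary matrix container (JSON header + little-endian float64) is
  the canonical storage dialect because it round-trips bit-exactly; the
  text dialect (%.17g) also round-trips float64 exactly but exists for
  human inspection.  FreeSurfer curv overlays store float32 — exact
  round-trips hold only for float32-representable values.
* BrainVision support covers multiplexed IEEE float32 and int16 with
  resolution scaling; triad consistency is checked before parsing and
  missing members / unsupported format codes are reported by name.
* The lead-field reference is not dictated by the data model; `G` and
  `Y` must simply agree.  The package defaults to average reference and
  provides the projector as a utility.

## Known limitations

Spherical geometry only (no BEM/FEM); fixed-orientation dipoles; static
noise covariance across windows; non-overlapping windows; submaps must
be disjoint; the rank-1 encoding forces full within-submap coherence;
no group-level statistics.
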