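# stfmri-esi — spatiotemporal fMRI-constrained EEG source imaging

EEG source imaging recovers cortical current density from scalp
potentials, an ill-posed inverse problem that is usually regularised
with spatial priors.  fMRI activation maps are an attractive prior —
they are spatially precise — but a BOLD map is *static*: it is the union
of everything that was active at any time during the task.  Imposing it
at every time point biases the reconstruction whenever an fMRI-active
region is electrically silent (or vice versa), the classic EEG–fMRI
temporal mismatch.

This package implements a windowed empirical-Bayes remedy.  The
thresholded fMRI map is split into submaps q_i (connected clusters, or
clusters split by cortical region labels), each contributing a source
covariance component Q_i = q_i q_iᵀ.  For every short EEG analysis
window (default 40 ms) the component weights are re-estimated from that
window's data, so the prior follows the dynamics of the recording
instead of being imposed uniformly.  It is aimed at methods researchers
in multimodal neuroimaging who want a self-contained, testable reference
implementation with a built-in forward model and simulator.

## Model

For one window `Y ∈ ℝ^{m×d}` (m channels, d samples):

    Y = G J + ε,   ε ~ N(0, C),   J ~ N(0, R),   R = Σ_i exp(λ_i) Q_i

with `G` the lead field.  The log-scale weights λ = {λ^C, λ^R} (sensor
noise plus one per submap) carry a Gaussian hyperprior N(η, Π⁻¹) with
η = −32 and prior variance 256 — exp(η) ≈ 0, so components are off until
the data turn them on.  They are estimated by maximising the variational
free energy

    F(λ) = −(d/2)[tr(Σ⁻¹S) + ln|Σ|] − (dm/2)ln2π
           + ½ln|Σ^λΠ| − ½(λ−η)ᵀΠ(λ−η),

where Σ(λ) = Σ_i exp(λ_i) K_i with sensor components K_i = {C, G Q_i Gᵀ}
and S = YYᵀ/d.  F is a lower bound on the log evidence ln p(Y|λ); ReML
(Fisher scoring with step control, monotone by construction) maximises
it, and the converged F doubles as the model-comparison score.  The
window's current density is the L2-norm inverse

    J = R Gᵀ (G R Gᵀ + λ^C C)⁻¹ Y.

The traditional baseline (`fit_time_invariant`) applies one static
R = diag(1 on fMRI-active vertices, 0.1 elsewhere) to the whole epoch
with the regularisation constant chosen by the L-curve, and is scored
per window by the same ReML machinery for a like-for-like evidence
comparison.

The package ships a three-shell spherical-head forward model (analytic
multilayer series, validated against the closed-form single-sphere
solution), fMRI GLM/thresholding utilities, BrainVision and FreeSurfer
I/O, and a synthetic-scene generator with known ground truth.

## Worked example

```python
import stfmri_esi as st

# desk-scale forward model
src = st.make_icosphere_source_space(2)              # 162-vertex cortical stand-in
head = st.SphericalHeadModel()                       # 3-shell sphere, 1:1/80:1
names, pos = st.fibonacci_cap_electrodes(32, radius=head.radii[2])
leadfield = st.compute_lead_field(head, pos, src, channel_names=names)

# synthetic visual -> premotor -> motor scene with a spurious fMRI patch
scene = st.mismatch_scene(src, seed=1, snr_db=10.0)
epochs, fmri_map, J_true = st.simulate_scene(scene, src, leadfield)
priors = st.scene_priors(scene, fmri_map, src)

# windowed empirical-Bayes fit vs the static fMRI-constrained baseline
est_win = st.fit_spatiotemporal(epochs, leadfield, priors)
mask = st.threshold_map(fmri_map, 0.05, 4, src.adjacency)
est_static = st.fit_time_invariant(epochs, leadfield, mask)
report = st.compare_models([est_win, est_static])

metrics = st.evaluate(est_win, J_true, scene, src)
```

Output:

```
4 fMRI submaps of sizes [7, 7, 7, 6]
average window F: spatiotemporal 2033.4, time-invariant 1970.4 (delta +63.1)
localization error (mm): {'visual': 0.0, 'premotor': 0.0, 'motor': 0.0}
time-course correlation: {'visual': 0.996, 'premotor': 0.998, 'motor': 0.997}
energy on the spurious fMRI patch: windowed 1.77e-24, static 1.33e-01
```

Reading: the four submaps are the three true patches plus one spurious
(fMRI-active, electrically silent) patch.  The windowed model explains
the data better (higher average free energy, Δ ≈ +63 nats per window),
localises every burst to the correct vertex, reconstructs the burst
time courses at r ≈ 0.997 — and leaves essentially no current on the
spurious patch, where the static constraint deposits 13% of its energy.

A thin CLI mirrors the library: `stfmri-esi simulate`, `stfmri-esi fit`
and `stfmri-esi compare` (see `stfmri-esi --help`).

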