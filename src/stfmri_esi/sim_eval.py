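"""Synthetic scenes with known ground truth, and evaluation metrics.

The generator emulates the statistical structure of a visual/motor ERP
paradigm: a small "visual" cortical patch bursts early (100–175 ms after
stimulus onset), a "premotor" patch bursts at 370–460 ms and a "motor"
patch around the response time (centered at 600 ms).  The fMRI
activation map is the *static union* of every transiently active patch —
BOLD maps carry no timing — optionally augmented with spurious patches
that are fMRI-active but electrically silent, reproducing the EEG–fMRI
mismatch that motivates time-variant priors.  Sensor noise is spatially
white by default; SNR is defined as active-span signal power over noise
power, in dB.  Everything is deterministic given the scene seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse.csgraph as csgraph

from .bayes_reml import HyperPrior, NoiseModel
from .fmri_priors import ActivationMap, PriorSet, priors_from_map
from .forward_model import LeadField, SourceSpace, mean_edge_length
from .io_formats import EEGEpochs
from .pipeline import SourceEstimate, WindowingScheme, fit_spatiotemporal

__all__ = [
    "SourcePatch",
    "SimScene",
    "EvalReport",
    "geodesic_patch",
    "default_scene",
    "mismatch_scene",
    "simulate_scene",
    "scene_priors",
    "evaluate",
    "window_stability_experiment",
]


@dataclasses.dataclass
class SourcePatch:
    """One transiently active cortical patch."""

    name: str
    vertices: np.ndarray
    onset_ms: float
    offset_ms: float
    amplitude: float = 1.0          # nA·m
    waveform: str = "gaussian-burst"  # | "boxcar"

    def __post_init__(self) -> None:
        self.vertices = np.unique(np.asarray(self.vertices, dtype=int))
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.waveform not in ("gaussian-burst", "boxcar"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    def time_course(self, times_ms: np.ndarray) -> np.ndarray:
        active = (times_ms >= self.onset_ms) & (times_ms <= self.offset_ms)
        if self.waveform == "boxcar":
            return self.amplitude * active.astype(float)
        center = 0.5 * (self.onset_ms + self.offset_ms)
        sigma = (self.offset_ms - self.onset_ms) / 4.0
        w = self.amplitude * np.exp(-0.5 * ((times_ms - center) / sigma) ** 2)
        return np.where(active, w, 0.0)


@dataclasses.dataclass
class SimScene:
    """Scripted source activity plus the static fMRI map description."""

    patches: list[SourcePatch]
    spurious_fmri_patches: list[np.ndarray] = dataclasses.field(default_factory=list)
    snr_db: float = 10.0
    seed: int = 0
    sfreq: float = 1000.0
    epoch_span: tuple[float, float] = (-0.4, 1.2)   # seconds
    t_active: float = 10.0                           # fixed suprathreshold t
    stat_dof: int = 100

    def __post_init__(self) -> None:
        lo, hi = (self.epoch_span[0] * 1e3, self.epoch_span[1] * 1e3)
        for p in self.patches:
            if not (lo <= p.onset_ms and p.offset_ms <= hi):
                raise ValueError(f"patch {p.name!r} active outside the epoch span")

    @property
    def times_ms(self) -> np.ndarray:
        n = int(round((self.epoch_span[1] - self.epoch_span[0]) * self.sfreq))
        return (self.epoch_span[0] + np.arange(n) / self.sfreq) * 1e3


# --------------------------------------------------------------------------
# scene construction
# --------------------------------------------------------------------------

def geodesic_patch(src: SourceSpace, direction: np.ndarray, n_rings: int = 1) -> np.ndarray:
    """Vertex nearest ``direction`` plus its ``n_rings`` mesh neighbourhoods."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    unit = src.vertices / np.linalg.norm(src.vertices, axis=1, keepdims=True)
    seed = int(np.argmax(unit @ d))
    dist = csgraph.shortest_path(src.adjacency, indices=seed, unweighted=True)
    return np.flatnonzero(dist <= n_rings)


def default_scene(src: SourceSpace, seed: int = 0, snr_db: float = 10.0,
                  n_rings: int = 1) -> SimScene:
    """The default visual → premotor → motor timeline (see module docstring)."""
    patches = [
        SourcePatch("visual", geodesic_patch(src, (0.0, -1.0, -0.2), n_rings), 100.0, 175.0),
        SourcePatch("premotor", geodesic_patch(src, (0.45, 0.3, 0.85), n_rings), 370.0, 460.0),
        SourcePatch("motor", geodesic_patch(src, (-0.8, 0.15, 0.55), n_rings), 550.0, 650.0),
    ]
    return SimScene(patches=patches, snr_db=snr_db, seed=seed)


def mismatch_scene(src: SourceSpace, seed: int = 0, snr_db: float = 10.0,
                   n_rings: int = 1) -> SimScene:
    """Default scene plus one fMRI-active but electrically silent patch."""
    scene = default_scene(src, seed=seed, snr_db=snr_db, n_rings=n_rings)
    scene.spurious_fmri_patches = [geodesic_patch(src, (0.9, -0.45, -0.1), n_rings)]
    return scene


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_scene(
    scene: SimScene, src: SourceSpace, G
) -> tuple[EEGEpochs, ActivationMap, np.ndarray]:
    """Generate (EEG epoch, static fMRI map, ground-truth J).

    J_true carries each patch's waveform on its vertices; sensor data are
    G·J_true plus white noise scaled so that the signal/noise power ratio
    over the union of active spans equals ``scene.snr_db``.  The fMRI map
    assigns the fixed suprathreshold statistic ``t_active`` to the union
    of all patches and spurious patches, zero elsewhere.
    """
    Gm = np.asarray(getattr(G, "G", G), dtype=float)
    s = src.n_vertices
    if Gm.shape[1] != s:
        raise ValueError("lead field and source space disagree on vertex count")
    for p in scene.patches:
        if p.vertices.max(initial=-1) >= s:
            raise ValueError(f"patch {p.name!r} has vertices outside the source space")
    for q in scene.spurious_fmri_patches:
        if np.asarray(q).max(initial=-1) >= s:
            raise ValueError("spurious fMRI patch has vertices outside the source space")

    t_ms = scene.times_ms
    d = t_ms.size
    J = np.zeros((s, d))
    active = np.zeros(d, dtype=bool)
    for p in scene.patches:
        tc = p.time_course(t_ms)
        J[p.vertices] += tc[np.newaxis, :]
        active |= tc != 0

    signal = Gm @ J
    rng = np.random.default_rng(scene.seed)
    m = Gm.shape[0]
    if np.isinf(scene.snr_db):
        noise = np.zeros_like(signal)
    else:
        p_sig = float(np.mean(signal[:, active] ** 2)) if active.any() else 0.0
        sigma = np.sqrt(p_sig / 10.0 ** (scene.snr_db / 10.0)) if p_sig > 0 else 1.0
        noise = sigma * rng.standard_normal(signal.shape)
    Y = signal + noise

    stat = np.zeros(s)
    for p in scene.patches:
        stat[p.vertices] = scene.t_active
    for q in scene.spurious_fmri_patches:
        stat[np.asarray(q, dtype=int)] = scene.t_active
    amap = ActivationMap(stat=stat, dof=scene.stat_dof)

    epochs = EEGEpochs(
        data=Y[np.newaxis],
        sfreq=scene.sfreq,
        t0=scene.epoch_span[0],
        channel_names=[f"E{i + 1:02d}" for i in range(m)],
        condition=["sim"],
    )
    return epochs, amap, J


def scene_priors(scene: SimScene, amap: ActivationMap, src: SourceSpace,
                 **kwargs) -> PriorSet:
    """Threshold/partition the simulated map into the pipeline's PriorSet."""
    return priors_from_map(amap, src, dof=scene.stat_dof, **kwargs)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclasses.dataclass
class EvalReport:
    """Per-patch recovery metrics against the known truth."""

    localization_error: dict[str, float]     # meters
    timecourse_corr: dict[str, float]        # Pearson r
    energy_outside_truth: float              # fraction in [0, 1]
    window_stability_corr: dict | None = None

    def __post_init__(self) -> None:
        for r in self.timecourse_corr.values():
            if not (-1.0 - 1e-9 <= r <= 1.0 + 1e-9):
                raise ValueError("correlations must lie in [-1, 1]")
        for e in self.localization_error.values():
            if e < 0:
                raise ValueError("localization error must be non-negative")
        if not (0.0 <= self.energy_outside_truth <= 1.0 + 1e-12):
            raise ValueError("energy fraction must lie in [0, 1]")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def evaluate(
    est: SourceEstimate, truth: np.ndarray, scene: SimScene, src: SourceSpace
) -> EvalReport:
    """Localization error, time-course correlation and leaked energy.

    Per patch: the true peak vertex (largest truth energy within the
    patch over its active span) is compared with the estimated peak
    vertex (largest estimate energy anywhere over the same span); their
    Euclidean distance is the localization error.  The time-course
    correlation is the Pearson r between the patch-mean estimated and
    true time courses over the whole epoch.
    """
    truth = np.asarray(truth, dtype=float)
    d_used = est.J.shape[1]
    if truth.shape[0] != est.J.shape[0]:
        raise ValueError("estimate and truth have different source counts")
    t_ms = scene.times_ms[:d_used]
    loc: dict[str, float] = {}
    corr: dict[str, float] = {}
    for p in scene.patches:
        span = (t_ms >= p.onset_ms) & (t_ms <= p.offset_ms)
        if not span.any():
            continue
        e_true = (truth[:, :d_used][:, span] ** 2).sum(axis=1)
        true_peak = p.vertices[int(np.argmax(e_true[p.vertices]))]
        e_est = (est.J[:, span] ** 2).sum(axis=1)
        est_peak = int(np.argmax(e_est))
        loc[p.name] = float(
            np.linalg.norm(src.vertices[true_peak] - src.vertices[est_peak])
        )
        corr[p.name] = _pearson(
            est.J[p.vertices].mean(axis=0), truth[p.vertices, :d_used].mean(axis=0)
        )
    support = np.zeros(truth.shape[0], dtype=bool)
    for p in scene.patches:
        support[p.vertices] = True
    total = float((est.J**2).sum())
    outside = 0.0 if total == 0 else float((est.J[~support] ** 2).sum() / total)
    return EvalReport(
        localization_error=loc,
        timecourse_corr=corr,
        energy_outside_truth=outside,
    )


def window_stability_experiment(
    scene: SimScene,
    src: SourceSpace,
    G,
    window_sizes_ms: list[float],
    region: str = "premotor",
    hyper: HyperPrior | None = None,
    noise: NoiseModel | None = None,
) -> dict[float, float]:
    """Reconstruction stability across analysis window sizes.

    Runs the spatiotemporal fit at each window size and correlates the
    designated region's mean time course (restricted to the samples all
    runs cover) against the smallest-window reference.  Returns
    {window_ms: Pearson r}; the reference maps to r = 1.
    """
    if len(window_sizes_ms) < 2:
        raise ValueError("need at least two window sizes")
    epochs, amap, _ = simulate_scene(scene, src, G)
    priors = scene_priors(scene, amap, src)
    idx = {p.name: p.vertices for p in scene.patches}
    if region not in idx:
        raise ValueError(f"unknown region {region!r}; patches: {sorted(idx)}")
    sizes = sorted(set(float(w) for w in window_sizes_ms))
    courses: dict[float, np.ndarray] = {}
    for w in sizes:
        est = fit_spatiotemporal(
            epochs, G, priors, noise=noise, hyper=hyper,
            scheme=WindowingScheme(window_ms=w),
        )
        courses[w] = est.J[idx[region]].mean(axis=0)
    d_min = min(tc.size for tc in courses.values())
    ref = courses[sizes[0]][:d_min]
    return {w: _pearson(courses[w][:d_min], ref) for w in sizes}
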