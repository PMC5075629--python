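"""fMRI-derived spatial priors for EEG source imaging.

A per-vertex BOLD statistic map is thresholded (voxel-level p plus a
cluster-extent rule), partitioned into submaps q_i — connected clusters,
optionally split further by cortical region labels — and each submap is
turned into a source-covariance component Q_i.  The assembled source
prior is the weighted sum R = Σ_i w_i Q_i, with the weights estimated per
EEG time window by ReML (see :mod:`stfmri_esi.bayes_reml`).

Two component encodings are provided:

``indicator-rank1``
    Q_i = q_i q_iᵀ with q_i the 0/1 indicator vector of the submap — the
    literal covariance-component definition.  Rank one: sources within a
    submap are perfectly correlated a priori.
``diagonal``
    Q_i = diag(q_i) — independent sources of equal prior variance within
    the submap, the common empirical-Bayes patch prior.  Off by default.

Note the full random-field / permutation FWER cluster correction used in
volumetric fMRI analysis is deliberately approximated here by voxel-p
thresholding plus a cluster-extent minimum (default 4 vertices); this is
a declared simplification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .forward_model import SourceSpace

__all__ = [
    "ActivationMap",
    "CovarianceComponent",
    "PriorSet",
    "GLMDesign",
    "boxcar_design",
    "glm_tmap",
    "threshold_map",
    "partition_submaps",
    "build_components",
    "priors_from_map",
]

#: documented cap applied to t statistics in zero-residual (perfect-fit) vertices
T_CAP = 1e6


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ActivationMap:
    """Per-vertex fMRI statistic with threshold state and cluster labels.

    ``cluster_labels`` is None while unthresholded; after thresholding it
    holds one integer per vertex, 0 for inactive and 1..K for surviving
    connected clusters (labelled in decreasing size order).
    """

    stat: np.ndarray
    dof: int | None = None
    threshold_p: float | None = None
    min_cluster: int | None = None
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stat = np.asarray(self.stat, dtype=float).ravel()
        if not np.all(np.isfinite(self.stat)):
            raise ValueError("activation map contains non-finite statistics")

    @property
    def n_vertices(self) -> int:
        return self.stat.shape[0]

    @property
    def is_thresholded(self) -> bool:
        return self.cluster_labels is not None

    @property
    def n_clusters(self) -> int:
        if self.cluster_labels is None:
            return 0
        return int(self.cluster_labels.max(initial=0))

    def active_mask(self) -> np.ndarray:
        if self.cluster_labels is None:
            raise ValueError("map is unthresholded; call threshold_map first")
        return self.cluster_labels > 0


@dataclasses.dataclass
class CovarianceComponent:
    """One structured source-covariance block Q_i, stored by its support."""

    indices: np.ndarray
    encoding: str  # "indicator-rank1" | "diagonal"

    def __post_init__(self) -> None:
        self.indices = np.unique(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError("covariance component has empty support")
        if self.encoding not in ("indicator-rank1", "diagonal"):
            raise ValueError(f"unknown encoding {self.encoding!r}")

    def dense(self, s: int) -> np.ndarray:
        Q = np.zeros((s, s))
        if self.encoding == "indicator-rank1":
            q = np.zeros(s)
            q[self.indices] = 1.0
            Q = np.outer(q, q)
        else:
            Q[self.indices, self.indices] = 1.0
        return Q

    def sensor_component(self, G: np.ndarray) -> np.ndarray:
        """G Q Gᵀ without forming the dense s×s block."""
        Gi = G[:, self.indices]
        if self.encoding == "indicator-rank1":
            g = Gi.sum(axis=1)
            return np.outer(g, g)
        return Gi @ Gi.T


@dataclasses.dataclass
class PriorSet:
    """The submaps {q_i} and covariance components {Q_i} of the prior."""

    submaps: list[np.ndarray]
    components: list[CovarianceComponent]
    source_count: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for q in self.submaps:
            q = np.asarray(q, dtype=int)
            if q.size == 0:
                raise ValueError("submaps must be non-empty")
            if q.min() < 0 or q.max() >= self.source_count:
                raise ValueError("submap index outside source space")
            overlap = seen.intersection(q.tolist())
            if overlap:
                raise ValueError(f"submaps overlap on vertices {sorted(overlap)}")
            seen.update(q.tolist())

    @property
    def n_components(self) -> int:
        return len(self.components)

    def support(self) -> np.ndarray:
        mask = np.zeros(self.source_count, dtype=bool)
        for q in self.submaps:
            mask[q] = True
        return mask


@dataclasses.dataclass
class GLMDesign:
    """Design matrix (condition regressors convolved with the HRF, plus
    nuisance/drift columns) and the contrast vector of interest."""

    regressors: np.ndarray
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        self.contrast = np.asarray(self.contrast, dtype=float).ravel()
        T, k = self.regressors.shape
        if T <= k:
            raise ValueError(f"need more scans than regressors (T={T}, k={k})")
        if self.contrast.shape[0] != k:
            raise ValueError("contrast length must equal number of regressors")

    @property
    def dof(self) -> int:
        return self.regressors.shape[0] - self.regressors.shape[1]


def boxcar_design(
    n_scans: int,
    tr: float,
    onsets: list[float],
    durations: list[float] | float,
    drift_order: int = 2,
) -> GLMDesign:
    """Canonical single-condition block design.

    The condition boxcar is convolved with the 0th-derivative canonical
    SPM hemodynamic response function; Legendre-style polynomial drift
    columns up to ``drift_order`` model slow nuisance trends.  The
    contrast selects the condition regressor.
    """
    from nilearn.glm.first_level.hemodynamic_models import spm_hrf

    if np.isscalar(durations):
        durations = [float(durations)] * len(onsets)
    box = np.zeros(n_scans)
    for on, dur in zip(onsets, durations):
        i0 = int(np.floor(on / tr))
        i1 = int(np.ceil((on + dur) / tr))
        box[max(i0, 0): min(i1, n_scans)] = 1.0
    hrf = spm_hrf(tr, oversampling=1)
    reg = np.convolve(box, hrf)[:n_scans]
    t = np.linspace(-1.0, 1.0, n_scans)
    drifts = np.vander(t, drift_order + 1, increasing=True)  # 1, t, t², ...
    X = np.column_stack([reg, drifts])
    contrast = np.zeros(X.shape[1])
    contrast[0] = 1.0
    return GLMDesign(regressors=X, contrast=contrast)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def glm_tmap(bold: np.ndarray, design: GLMDesign) -> np.ndarray:
    """Mass-univariate OLS t map, t = cᵀβ̂ / sqrt(σ̂² cᵀ(XᵀX)⁻¹c).

    ``bold`` is (T scans × s vertices).  σ̂² is the residual variance with
    T − k degrees of freedom.  Vertices with an exactly zero residual
    (data in the column space of the design) receive a capped statistic
    of ±``T_CAP``.
    """
    bold = np.asarray(bold, dtype=float)
    X = design.regressors
    T, k = X.shape
    if bold.shape[0] != T:
        raise ValueError(f"bold has {bold.shape[0]} scans, design has {T}")
    if not np.all(np.isfinite(bold)):
        raise ValueError("bold series contains non-finite values")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, Rq = np.linalg.qr(X)
        collinear = np.flatnonzero(np.abs(np.diag(Rq)) < 1e-10 * np.abs(np.diag(Rq)).max())
        raise ValueError(f"design matrix rank deficient; collinear columns: {collinear.tolist()}")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ bold)                      # (k, s)
    resid = bold - X @ beta
    sigma2 = np.einsum("ts,ts->s", resid, resid) / (T - k)
    c = design.contrast
    num = c @ beta
    denom2 = sigma2 * float(c @ XtX_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(denom2)
    zero_res = denom2 <= 0
    t[zero_res] = np.sign(num[zero_res]) * T_CAP
    t[zero_res & (num == 0)] = 0.0
    return np.clip(t, -T_CAP, T_CAP)


def threshold_map(
    amap: ActivationMap,
    p: float,
    min_cluster: int,
    adjacency: sp.spmatrix,
    dof: int | None = None,
) -> ActivationMap:
    """Voxel-p threshold followed by a cluster-extent rule.

    Vertices whose two-sided p value (t distribution, ``dof`` degrees of
    freedom) fails ``p`` are removed; survivors are labelled by connected
    components under the mesh adjacency and components with fewer than
    ``min_cluster`` vertices are removed (survival rule is inclusive:
    size >= min_cluster).  Returns a new thresholded map; labels are
    assigned in decreasing cluster-size order (ties broken by the lowest
    vertex index).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    dof = dof if dof is not None else amap.dof
    if dof is None:
        raise ValueError("degrees of freedom required to convert p to a t threshold")
    t_crit = stats.t.isf(p / 2.0, dof)
    supra = np.abs(amap.stat) >= t_crit

    labels = np.zeros(amap.n_vertices, dtype=int)
    idx = np.flatnonzero(supra)
    if idx.size:
        sub = sp.csr_matrix(adjacency)[idx][:, idx]
        n_comp, comp = connected_components(sub, directed=False)
        keep = []
        for ci in range(n_comp):
            members = idx[comp == ci]
            if members.size >= min_cluster:
                keep.append(members)
        keep.sort(key=lambda mem: (-mem.size, mem.min()))
        for lab, members in enumerate(keep, start=1):
            labels[members] = lab
    return ActivationMap(
        stat=amap.stat.copy(),
        dof=dof,
        threshold_p=p,
        min_cluster=min_cluster,
        cluster_labels=labels,
    )


def partition_submaps(amap: ActivationMap, mode: str = "clusters",
                      src: SourceSpace | None = None) -> list[np.ndarray]:
    """Split the thresholded map into submaps q_i.

    ``mode="clusters"`` gives one submap per surviving connected cluster;
    ``mode="labels"`` additionally splits each cluster by the region
    labels of the source space (requires ``src.region_labels``).
    """
    if not amap.is_thresholded:
        raise ValueError("map must be thresholded before partitioning")
    if mode not in ("clusters", "labels"):
        raise ValueError(f"unknown partition mode {mode!r}")
    labels = amap.cluster_labels
    submaps: list[np.ndarray] = []
    for lab in range(1, amap.n_clusters + 1):
        members = np.flatnonzero(labels == lab)
        if mode == "clusters":
            submaps.append(members)
        else:
            if src is None or src.region_labels is None:
                raise ValueError("mode='labels' requires a source space with region_labels")
            regions = src.region_labels[members]
            for reg in sorted(set(regions.tolist())):
                submaps.append(members[regions == reg])
    return submaps


def build_components(
    submaps: list[np.ndarray], s: int, encoding: str = "indicator-rank1"
) -> PriorSet:
    """Wrap submaps into covariance components Q_i (see module docstring)."""
    comps = [CovarianceComponent(indices=q, encoding=encoding) for q in submaps]
    return PriorSet(
        submaps=[c.indices for c in comps], components=comps, source_count=s
    )


def priors_from_map(
    amap: ActivationMap,
    src: SourceSpace,
    p: float = 0.05,
    min_cluster: int = 4,
    mode: str = "clusters",
    encoding: str = "indicator-rank1",
    dof: int | None = None,
) -> PriorSet:
    """Convenience chain: threshold → partition → components.

    Accepts an unthresholded or already-thresholded map; thresholding is
    (re)applied when ``p``/``min_cluster`` are given and the map is raw.
    """
    if not amap.is_thresholded:
        amap = threshold_map(amap, p, min_cluster, src.adjacency, dof=dof)
    submaps = partition_submaps(amap, mode=mode, src=src)
    if not submaps:
        return PriorSet(submaps=[], components=[], source_count=src.n_vertices)
    return build_components(submaps, src.n_vertices, encoding=encoding)
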