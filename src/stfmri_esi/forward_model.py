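"""Source space and lead field for the EEG forward problem.

The forward model maps dipole moments on a cortical source space to scalp
electrode potentials through the lead-field matrix ``G`` (units
µV/(nA·m)), so that sensor data follow ``Y = G J + ε``.  The built-in
forward solver is the analytic series solution for a dipole inside a set
of concentric spherical shells (brain / skull / scalp) with an insulating
exterior.  A user-supplied gain matrix can be wrapped in
:class:`LeadField` directly; the spherical model exists so that the whole
inverse pipeline is testable without a boundary-element solver.

Conventions
-----------
* All coordinates are in meters; vertex indices are 0-based.
* Dipoles are oriented along the outward surface normal of their vertex
  ("fixed orientation"); one column of ``G`` is the scalp topography of a
  unit (1 nA·m) dipole.
* By default ``G`` is average-referenced (each channel minus the mean
  over channels).  ``G`` and the EEG data must share a reference; use
  :func:`average_reference` to bring data to the same convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = [
    "SourceSpace",
    "LeadField",
    "SphericalHeadModel",
    "make_icosphere_source_space",
    "compute_lead_field",
    "average_reference",
    "adjacency_from_faces",
    "assign_octant_labels",
    "fibonacci_cap_electrodes",
    "mean_edge_length",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SourceSpace:
    """Candidate dipole locations with fixed normal orientations.

    Parameters
    ----------
    vertices : (s, 3) float array
        Vertex positions in meters.
    normals : (s, 3) float array
        Outward unit normals (dipole orientations).
    adjacency : scipy.sparse matrix of bool, shape (s, s)
        Symmetric, irreflexive vertex-neighbour relation (shared-edge
        neighbours of the triangulation).
    faces : (f, 3) int array, optional
        Triangles; kept for geometry I/O and plotting.
    region_labels : (s,) array of str, optional
        Anatomical/functional label per vertex.
    """

    vertices: np.ndarray
    normals: np.ndarray
    adjacency: sp.spmatrix
    faces: np.ndarray | None = None
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (s, 3), got {self.vertices.shape}")
        s = self.vertices.shape[0]
        if s < 1:
            raise ValueError("source space needs at least one vertex")
        if self.normals.shape != (s, 3):
            raise ValueError("normals shape must match vertices")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("normals must be unit length (|1 - ||n||| <= 1e-9)")
        adj = sp.csr_matrix(self.adjacency).astype(bool)
        if adj.shape != (s, s):
            raise ValueError("adjacency shape must be (s, s)")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive (no self-edges)")
        self.adjacency = adj
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels)
            if self.region_labels.shape[0] != s:
                raise ValueError("region_labels length must equal vertex count")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def identifier(self) -> str:
        """Content hash used to link lead fields back to their source space."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.normals).tobytes())
        return h.hexdigest()[:12]


@dataclasses.dataclass
class LeadField:
    """Gain matrix ``G`` (m channels × s sources), units µV/(nA·m)."""

    G: np.ndarray
    channel_names: list[str]
    source_space_id: str = ""

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D matrix")
        m, s = self.G.shape
        if len(self.channel_names) != m:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {m} rows of G"
            )
        if not np.all(np.isfinite(self.G)):
            raise ValueError("lead field contains non-finite values")
        dead_rows = np.flatnonzero(~self.G.any(axis=1))
        dead_cols = np.flatnonzero(~self.G.any(axis=0))
        if dead_rows.size:
            warnings.warn(f"lead field has all-zero rows (dead channels): {dead_rows.tolist()}")
        if dead_cols.size:
            warnings.warn(f"lead field has all-zero columns (invisible sources): {dead_cols.tolist()}")

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G.shape[1]


@dataclasses.dataclass
class SphericalHeadModel:
    """Concentric three-shell head geometry.

    ``radii`` are the outer radii of brain, skull and scalp shells
    (strictly increasing, meters); ``conductivities`` the corresponding
    shell conductivities in S/m.  The defaults use the literature-standard
    1 : 1/80 : 1 brain:skull:scalp conductivity ratio with brain
    conductivity 0.33 S/m; they are a package choice, configurable.
    """

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.33, 0.33 / 80.0, 0.33)
    n_terms: int = 140

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if r.shape != (3,) or c.shape != (3,):
            raise ValueError("expect exactly three radii and conductivities")
        if not np.all(np.diff(r) > 0) or not np.all(r > 0):
            raise ValueError("radii must be positive and strictly increasing")
        if not np.all(c > 0):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


# --------------------------------------------------------------------------
# source-space construction and helpers
# --------------------------------------------------------------------------

def adjacency_from_faces(n_vertices: int, faces: np.ndarray) -> sp.csr_matrix:
    """Shared-edge neighbour relation of a triangle mesh as a sparse bool matrix."""
    faces = np.asarray(faces, dtype=int)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(i.size, dtype=bool)
    adj = sp.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices)).tocsr()
    adj = (adj + adj.T).astype(bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    return adj


def make_icosphere_source_space(subdivisions: int, radius: float = 0.078) -> SourceSpace:
    """Geodesic-sphere source space (desk-scale stand-in for a cortical mesh).

    Vertex count follows the icosahedral formula ``10·4**subdivisions + 2``.
    Normals point radially outward.
    """
    if not (0 <= int(subdivisions) <= 6):
        raise ValueError("subdivisions must be in 0..6")
    mesh = trimesh.creation.icosphere(subdivisions=int(subdivisions), radius=float(radius))
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    normals = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
    adj = adjacency_from_faces(vertices.shape[0], faces)
    return SourceSpace(vertices=vertices, normals=normals, adjacency=adj, faces=faces)


def assign_octant_labels(src: SourceSpace) -> SourceSpace:
    """Attach coarse region labels by coordinate octant (testing utility)."""
    signs = np.where(src.vertices >= 0, "+", "-")
    labels = np.array([f"{s[0]}x{s[1]}y{s[2]}z" for s in signs])
    src.region_labels = labels
    return src


def mean_edge_length(src: SourceSpace) -> float:
    """Mean Euclidean length of mesh edges (localization-error yardstick)."""
    adj = sp.triu(src.adjacency.tocoo())
    d = np.linalg.norm(src.vertices[adj.row] - src.vertices[adj.col], axis=1)
    return float(d.mean())


def fibonacci_cap_electrodes(
    n: int = 32, radius: float = 0.100, max_polar_deg: float = 100.0
) -> tuple[list[str], np.ndarray]:
    """Quasi-uniform electrode layout on a spherical cap (golden-angle spiral).

    Covers polar angles 0..``max_polar_deg`` (an EEG cap reaching slightly
    below the equator).  Returns labels ``E01..`` and (n, 3) positions.
    """
    k = np.arange(n)
    zmin = np.cos(np.deg2rad(max_polar_deg))
    z = 1.0 - (1.0 - zmin) * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    names = [f"E{i + 1:02d}" for i in range(n)]
    return names, pos


def average_reference(x: np.ndarray) -> np.ndarray:
    """Apply the average-reference projector ``I - 11ᵀ/m`` to rows=channels."""
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


# --------------------------------------------------------------------------
# multilayer-sphere series solution
# --------------------------------------------------------------------------

def _layer_gains(head: SphericalHeadModel, n_max: int) -> np.ndarray:
    """Per-order surface gain c_n of the layered sphere.

    For each harmonic order n the radial part of the potential in shell l
    is ``A_l ρ^n + B_l ρ^-(n+1)`` (innermost shell additionally carries the
    source term ``ρ^-(n+1)`` with unit coefficient).  Solving the
    continuity/flux conditions at the interfaces and the insulating outer
    boundary yields the surface value c_n = u_outer(1) with radii
    non-dimensionalised by the scalp radius.  For a homogeneous sphere
    c_n = (2n+1)/n exactly.
    """
    r = np.asarray(head.radii, dtype=float)
    sig = np.asarray(head.conductivities, dtype=float)
    a1, a2 = r[0] / r[2], r[1] / r[2]
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # continuity at a1
        M[0] = [a1**n, -(a1**n), -(a1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -(a1 ** -(n + 1))
        # flux continuity at a1
        M[1] = [
            sig[0] * n * a1 ** (n - 1),
            -sig[1] * n * a1 ** (n - 1),
            sig[1] * (n + 1) * a1 ** -(n + 2),
            0.0,
            0.0,
        ]
        rhs[1] = sig[0] * (n + 1) * a1 ** -(n + 2)
        # continuity at a2
        M[2] = [0.0, a2**n, a2 ** -(n + 1), -(a2**n), -(a2 ** -(n + 1))]
        # flux continuity at a2
        M[3] = [
            0.0,
            sig[1] * n * a2 ** (n - 1),
            -sig[1] * (n + 1) * a2 ** -(n + 2),
            -sig[2] * n * a2 ** (n - 1),
            sig[2] * (n + 1) * a2 ** -(n + 2),
        ]
        # insulating outer boundary at 1
        M[4] = [0.0, 0.0, 0.0, float(n), -float(n + 1)]
        x = np.linalg.solve(M, rhs)
        out[n - 1] = x[3] + x[4]  # A3 + B3 at ρ = 1
    return out


def compute_lead_field(
    head: SphericalHeadModel,
    electrodes: np.ndarray,
    src: SourceSpace,
    channel_names: list[str] | None = None,
    reference: str = "average",
    tail_warn: float = 1e-10,
) -> LeadField:
    """Lead field of normal-oriented unit dipoles in a layered sphere.

    ``G[j, k]`` is the potential (µV) at electrode j produced by a
    1 nA·m dipole at source vertex k oriented along its normal, from the
    multilayer-sphere spherical-harmonic series truncated at
    ``head.n_terms``.  Electrodes must lie on or outside the scalp shell
    (they are projected radially onto it); sources must lie strictly
    inside the innermost shell.

    ``reference`` is ``"average"`` (default; columns sum to zero) or
    ``"none"`` (potentials against infinity).  A warning is issued when
    the last series term still contributes more than ``tail_warn`` of the
    maximum gain magnitude.
    """
    electrodes = np.asarray(electrodes, dtype=float)
    if electrodes.ndim != 2 or electrodes.shape[1] != 3:
        raise ValueError("electrodes must be (m, 3)")
    if reference not in ("average", "none"):
        raise ValueError(f"unknown reference {reference!r}")
    R = head.radii[2]
    e_norm = np.linalg.norm(electrodes, axis=1)
    inside = np.flatnonzero(e_norm < R * (1.0 - 1e-9))
    if inside.size:
        raise ValueError(
            f"electrodes must lie on/outside the outer shell; offending indices: {inside.tolist()}"
        )
    v_norm = np.linalg.norm(src.vertices, axis=1)
    bad = np.flatnonzero(v_norm >= head.radii[0])
    if bad.size:
        raise ValueError(
            f"source vertices not strictly inside the innermost shell: {bad.tolist()}"
        )

    m, s = electrodes.shape[0], src.n_vertices
    r_e = electrodes / e_norm[:, None]          # unit electrode directions
    # a vertex at the exact center has no radial direction; r_s = 0 there
    # makes the n = 1 term reduce to the correct central-dipole potential
    safe = np.where(v_norm > 0, v_norm, 1.0)
    r_s = src.vertices / safe[:, None]
    f = v_norm / R                               # source eccentricities

    # decompose each dipole into radial and tangential parts
    p_r = np.einsum("sj,sj->s", src.normals, r_s)           # radial moment
    p_tan = src.normals - p_r[:, None] * r_s                # tangential vector

    cosg = r_e @ r_s.T                                       # (m, s)
    # tangential geometric factor (r̂_e - cosγ r̂_s)·p_tan; r̂_s·p_tan = 0 by
    # construction so the subtraction only removes rounding residue
    tang = r_e @ p_tan.T - cosg * np.einsum("sj,sj->s", r_s, p_tan)[np.newaxis, :]

    c_n = _layer_gains(head, head.n_terms)

    # Legendre recurrences, accumulated over orders
    P_prev = np.ones_like(cosg)        # P_0
    P_cur = cosg.copy()                # P_1
    dP_prev = np.zeros_like(cosg)      # P_0'
    dP_cur = np.ones_like(cosg)        # P_1'
    fpow = np.ones(s)                  # f^(n-1)
    V = np.zeros((m, s))
    last_term = np.zeros((m, s))
    for n in range(1, head.n_terms + 1):
        term = c_n[n - 1] * fpow[np.newaxis, :] * (
            n * p_r[np.newaxis, :] * P_cur + dP_cur * tang
        )
        V += term
        last_term = term
        # advance recurrences to order n+1
        P_next = ((2 * n + 1) * cosg * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next
        fpow = fpow * f

    # SI prefactor for a 1 A·m dipole, then volts→µV and A·m→nA·m
    V *= 1.0 / (4.0 * np.pi * head.conductivities[0] * R**2)
    V *= 1e-3  # (1e-9 A·m per nA·m) * (1e6 µV per V)

    vmax = np.abs(V).max()
    tmax = np.abs(last_term).max() / (4.0 * np.pi * head.conductivities[0] * R**2) * 1e-3
    if vmax > 0 and tmax > tail_warn * vmax:
        warnings.warn(
            f"spherical-harmonic series not converged at n_terms={head.n_terms}: "
            f"last-term magnitude {tmax:.3e} vs max gain {vmax:.3e}"
        )

    if reference == "average":
        V = average_reference(V)
    if channel_names is None:
        channel_names = [f"E{i + 1:02d}" for i in range(m)]
    return LeadField(G=V, channel_names=list(channel_names), source_space_id=src.identifier)
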