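"""Empirical-Bayes covariance-component estimation (ReML) and the L2 inverse.

Model
-----
One EEG analysis window ``Y`` (m channels × d samples) is modelled as

    Y = G J + ε,   ε ~ N(0, C),   J ~ N(0, R),
    R = Σ_i w_i Q_i,

with source-covariance components Q_i built from fMRI submaps and an
additional sensor-noise component C.  The component weights are
parameterised on the log scale, w_i = exp(λ_i), with a Gaussian
hyperprior p(λ_i) = N(η, 1/π) (defaults η = −32, prior variance 256;
exp(η) ≈ 0, so the prior switches components off until the data demand
them).

The weights are estimated by maximising the variational free energy

    F(λ) = −(d/2)[tr(Σ⁻¹S) + ln|Σ|] − (dm/2) ln 2π
           + ½ ln|Σ^λ Π| − ½ (λ−η)ᵀ Π (λ−η),

where Σ(λ) = Σ_i exp(λ_i) K_i is the sensor covariance implied by the
components K_i = {C, G Q_i Gᵀ}, S = YYᵀ/d is the sample covariance, and
Σ^λ = (I(λ) + Π)⁻¹ is the Laplace posterior covariance of the
hyperparameters computed from the expected Fisher information

    I_ij(λ) = (d/2) tr(Σ⁻¹K_i Σ⁻¹K_j) exp(λ_i + λ_j).

F is a lower bound on the log evidence ln p(Y|λ) and doubles as the
model-comparison score.  Maximisation uses Fisher scoring with step
halving, which guarantees a non-decreasing free-energy trace.

The current density for a window is the L2-norm (minimum-norm) solution

    J = R Gᵀ (G R Gᵀ + λ^C C)⁻¹ Y,

where in the empirical-Bayes pipeline λ^C = exp(μ^λ_C) is simply the
fitted weight of the sensor-noise component.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import linalg

from .fmri_priors import PriorSet

__all__ = [
    "HyperPrior",
    "NoiseModel",
    "ReMLFit",
    "sensor_covariance_components",
    "free_energy",
    "reml_estimate",
    "assemble_R",
    "inverse_solution",
]

LOG2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass
class HyperPrior:
    """Gaussian prior N(eta, 1/pi) on each log-scale hyperparameter.

    Defaults are the standard empirical-Bayes shutoff prior: mean
    η = −32 (exp(η) ≈ 0 switches a component off) with prior *variance*
    256 (precision pi = 1/256, prior std 16), loose enough that the data
    decide which components switch on.  A tight precision of 256 would
    pin every weight at exp(−32) and make the hyperparameters
    non-identifiable, so the loose convention is the package default.
    """

    eta: float = -32.0
    pi: float = 1.0 / 256.0

    def __post_init__(self) -> None:
        if self.pi <= 0:
            raise ValueError("prior precision pi must be positive")

    @property
    def variance(self) -> float:
        return 1.0 / self.pi


@dataclasses.dataclass
class NoiseModel:
    """Sensor-noise covariance C and how it was obtained."""

    C: np.ndarray
    source: str = "identity"  # "identity" | "baseline-estimated"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        m = self.C.shape[0]
        if self.C.shape != (m, m) or not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("noise covariance must be square symmetric")
        w = np.linalg.eigvalsh(self.C)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            raise ValueError("noise covariance must be positive semidefinite")


@dataclasses.dataclass
class ReMLFit:
    """Hyperparameter posterior and free energy for one window."""

    mu_lambda: np.ndarray
    sigma_lambda: np.ndarray
    F_trace: np.ndarray
    R: np.ndarray | None
    converged: bool
    n_iter: int

    @property
    def F(self) -> float:
        return float(self.F_trace[-1])

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.mu_lambda)


# --------------------------------------------------------------------------
# components and free energy
# --------------------------------------------------------------------------

def _as_gain(G) -> np.ndarray:
    return np.asarray(getattr(G, "G", G), dtype=float)


def sensor_covariance_components(G, priors: PriorSet, noise: NoiseModel) -> list[np.ndarray]:
    """Sensor-space components {C} ∪ {G Q_i Gᵀ}; the noise term is first."""
    Gm = _as_gain(G)
    m = Gm.shape[0]
    if noise.C.shape[0] != m:
        raise ValueError(f"noise covariance is {noise.C.shape}, lead field has {m} channels")
    if priors.source_count != Gm.shape[1]:
        raise ValueError(
            f"priors built for {priors.source_count} sources, lead field has {Gm.shape[1]}"
        )
    comps = [np.asarray(noise.C, dtype=float)]
    for q in priors.components:
        comps.append(q.sensor_component(Gm))
    return comps


def _chol(sigma: np.ndarray):
    try:
        return linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "sensor covariance Sigma(lambda) is not positive definite"
        ) from err


def _data_terms(S: np.ndarray, cf, d: int, m: int) -> float:
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    tr = float(np.trace(linalg.cho_solve(cf, S)))
    return -0.5 * d * (tr + logdet + m * LOG2PI)


def _fisher_info(cf, K: list[np.ndarray], lam: np.ndarray, d: int) -> np.ndarray:
    """Expected information I_ij = (d/2) tr(Σ⁻¹K̃_i Σ⁻¹K̃_j), K̃ = e^λ K."""
    W = [linalg.cho_solve(cf, np.exp(li) * Ki) for li, Ki in zip(lam, K)]
    n = len(K)
    info = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            info[i, j] = info[j, i] = 0.5 * d * float(np.einsum("ij,ji->", W[i], W[j]))
    return info


def free_energy(
    Y: np.ndarray,
    components: list[np.ndarray],
    lam: np.ndarray,
    hyper: HyperPrior | None = None,
    return_parts: bool = False,
):
    """Evaluate the free energy F(λ) (see module docstring).

    With ``return_parts=True`` also returns a dict with the ``data``
    (Gaussian log-likelihood), ``laplace`` (½ ln|Σ^λΠ|) and ``prior``
    (−½(λ−η)ᵀΠ(λ−η)) terms.
    """
    hyper = hyper or HyperPrior()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    lam = np.asarray(lam, dtype=float).ravel()
    K = [np.asarray(k, dtype=float) for k in components]
    if len(K) != lam.size:
        raise ValueError("one hyperparameter per component required")
    m, d = Y.shape
    S = Y @ Y.T / d
    sigma = np.zeros((m, m))
    for li, Ki in zip(lam, K):
        sigma += np.exp(li) * Ki
    cf = _chol(sigma)
    data = _data_terms(S, cf, d, m)
    info = _fisher_info(cf, K, lam, d)
    n = lam.size
    Pi = hyper.pi * np.eye(n)
    sign, logdet_post = np.linalg.slogdet(info + Pi)
    if sign <= 0:
        raise np.linalg.LinAlgError("hyperparameter posterior precision not PD")
    laplace = 0.5 * (n * np.log(hyper.pi) - logdet_post)
    dev = lam - hyper.eta
    prior = -0.5 * hyper.pi * float(dev @ dev)
    F = data + laplace + prior
    if return_parts:
        return F, {"data": data, "laplace": laplace, "prior": prior}
    return F


# --------------------------------------------------------------------------
# ReML (Fisher scoring with step control)
# --------------------------------------------------------------------------

def reml_estimate(
    Y: np.ndarray,
    components: list[np.ndarray],
    hyper: HyperPrior | None = None,
    *,
    tol: float = 1e-4,
    max_iter: int = 128,
    priors: PriorSet | None = None,
    weight_scale: str = "log",
    init: np.ndarray | None = None,
    max_halvings: int = 20,
) -> ReMLFit:
    """Maximise F over the log-scale component weights for one window.

    Fisher-scoring ascent with step halving whenever a proposed step
    would decrease F, so the recorded ``F_trace`` is non-decreasing by
    construction.  Convergence at |ΔF| < ``tol``; otherwise the fit is
    returned with ``converged=False`` and a warning.

    ``components[0]`` is the sensor-noise term by convention; when
    ``priors`` is supplied the source covariance R = Σ exp(μ^λ_i) Q_i is
    assembled from the remaining weights.
    """
    if weight_scale != "log":
        raise NotImplementedError("reml_estimate operates on log-scale weights")
    hyper = hyper or HyperPrior()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, d = Y.shape
    if d < 1:
        raise ValueError("window must contain at least one sample")
    K = [np.asarray(k, dtype=float) for k in components]
    if not K:
        raise ValueError("at least one covariance component required")
    trK = np.array([np.trace(k) for k in K])
    if np.all(np.abs(trK) < 1e-300) or all(not k.any() for k in K):
        raise ValueError("all covariance components are numerically zero")
    S = Y @ Y.T / d
    n = len(K)

    if init is not None:
        lam = np.asarray(init, dtype=float).ravel().copy()
        if lam.size != n:
            raise ValueError("init length must equal component count")
    else:
        trS = float(np.trace(S))
        if trS <= 0:
            lam = np.full(n, hyper.eta)
        else:
            with np.errstate(divide="ignore"):
                lam = np.log(trS / (n * np.maximum(trK, 1e-300)))
            lam = np.clip(lam, hyper.eta, 32.0)

    F_cur = free_energy(Y, K, lam, hyper)
    trace = [F_cur]
    converged = False
    n_iter = 0
    Pi = hyper.pi * np.eye(n)

    def _laplace_at(lam_v: np.ndarray) -> float:
        sig = np.zeros((m, m))
        for li, Ki in zip(lam_v, K):
            sig += np.exp(li) * Ki
        cfv = _chol(sig)
        _, ld = np.linalg.slogdet(_fisher_info(cfv, K, lam_v, d) + Pi)
        return 0.5 * (n * np.log(hyper.pi) - ld)

    fd_h = 1e-3
    for n_iter in range(1, max_iter + 1):
        sigma = np.zeros((m, m))
        for li, Ki in zip(lam, K):
            sigma += np.exp(li) * Ki
        cf = _chol(sigma)
        SinvS = linalg.cho_solve(cf, S)
        grad = np.empty(n)
        for i, Ki in enumerate(K):
            Wi = linalg.cho_solve(cf, np.exp(lam[i]) * Ki)
            grad[i] = -0.5 * d * (np.trace(Wi) - float(np.einsum("ij,ji->", Wi, SinvS)))
        grad -= hyper.pi * (lam - hyper.eta)
        # the Laplace/Occam term ½ln|Σ^λΠ| depends on λ through the expected
        # information; its gradient has no convenient closed form, so central
        # finite differences keep the ascent aimed at the full F
        for i in range(n):
            e = np.zeros(n)
            e[i] = fd_h
            try:
                grad[i] += (_laplace_at(lam + e) - _laplace_at(lam - e)) / (2 * fd_h)
            except np.linalg.LinAlgError:
                pass
        info = _fisher_info(cf, K, lam, d)
        step = np.linalg.solve(info + Pi, grad)

        t = 1.0
        accepted = False
        for _ in range(max_halvings):
            cand = lam + t * step
            try:
                F_new = free_energy(Y, K, cand, hyper)
            except np.linalg.LinAlgError:
                F_new = -np.inf
            if np.isfinite(F_new) and F_new >= F_cur:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True  # no ascent direction improves F any further
            break
        lam = cand
        dF = F_new - F_cur
        F_cur = F_new
        trace.append(F_cur)
        if abs(dF) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"ReML did not converge within {max_iter} iterations")

    sigma = np.zeros((m, m))
    for li, Ki in zip(lam, K):
        sigma += np.exp(li) * Ki
    cf = _chol(sigma)
    info = _fisher_info(cf, K, lam, d)
    sigma_lambda = np.linalg.inv(info + Pi)
    sigma_lambda = 0.5 * (sigma_lambda + sigma_lambda.T)
    R = None
    if priors is not None:
        if priors.n_components != n - 1:
            raise ValueError("priors component count must equal len(components) - 1")
        R = assemble_R(priors, lam[1:])
    return ReMLFit(
        mu_lambda=lam,
        sigma_lambda=sigma_lambda,
        F_trace=np.asarray(trace),
        R=R,
        converged=converged,
        n_iter=n_iter,
    )


def assemble_R(priors: PriorSet, mu_lambda: np.ndarray, weight_scale: str = "log") -> np.ndarray:
    """Source covariance R = Σ w_i Q_i with w_i = exp(μ^λ_i) (log scale).

    In linear-weight mode the weights are used as given and must be
    non-negative.
    """
    mu_lambda = np.asarray(mu_lambda, dtype=float).ravel()
    if mu_lambda.size != priors.n_components:
        raise ValueError(
            f"{mu_lambda.size} weights for {priors.n_components} components"
        )
    if weight_scale == "log":
        w = np.exp(mu_lambda)
    elif weight_scale == "linear":
        if np.any(mu_lambda < 0):
            raise ValueError("linear-weight mode requires non-negative weights")
        w = mu_lambda
    else:
        raise ValueError(f"unknown weight_scale {weight_scale!r}")
    s = priors.source_count
    R = np.zeros((s, s))
    for wi, comp in zip(w, priors.components):
        if comp.encoding == "indicator-rank1":
            q = np.zeros(s)
            q[comp.indices] = 1.0
            R += wi * np.outer(q, q)
        else:
            R[comp.indices, comp.indices] += wi
    return R


# --------------------------------------------------------------------------
# L2-norm inverse
# --------------------------------------------------------------------------

def inverse_solution(
    Y: np.ndarray,
    G,
    R: np.ndarray,
    C: np.ndarray,
    lambda_C: float,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Minimum-norm current density J = R Gᵀ (G R Gᵀ + λ^C C)⁻¹ Y.

    If the sensor-space system fails to factorise, a diagonal jitter of
    ``jitter · trace/m`` is added once (and logged); a persistent failure
    raises with a condition-number estimate.
    """
    Gm = _as_gain(G)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    m = Gm.shape[0]
    A = Gm @ R @ Gm.T + lambda_C * C
    if not np.all(np.isfinite(A)) or np.abs(A).max() == 0.0:
        raise np.linalg.LinAlgError(
            f"sensor system singular after jitter (cond ~ {np.inf:.3e})"
        )
    try:
        cf = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:
        bump = jitter * max(np.trace(A), 1e-300) / m
        warnings.warn(f"sensor system not PD; adding diagonal jitter {bump:.3e}")
        A = A + bump * np.eye(m)
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"sensor system singular after jitter (cond ~ {np.linalg.cond(A):.3e})"
            ) from err
    return R @ Gm.T @ linalg.cho_solve(cf, Y)
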