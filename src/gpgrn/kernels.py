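"""Gaussian process primitives: SE-ARD kernel, affine mean, Gram matrices, GP regression.

The drift of each gene is modelled as a Gaussian process over the joint
expression state (plus any external-input coordinates).  The squared
exponential kernel with automatic relevance determination (ARD) carries one
inverse length scale per candidate regulator:

    k_i(x, z) = gamma_i * exp(-sum_j beta_{i,j} (x_j - z_j)^2)

A zero inverse length scale beta_{i,j} = 0 makes the drift of gene i constant
along coordinate j, i.e. removes the regulatory link j -> i.  The mean
function m_i(x) = b_i - a_i * x_i encodes basal transcription (b_i) and
first-order mRNA degradation (a_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Relative jitter added to Gram diagonals before factorization.  SE kernels
#: evaluated on dense trajectories are severely ill-conditioned.
JITTER = 1e-8


@dataclass
class KernelParams:
    """SE-ARD kernel hyperparameters for one target gene.

    Parameters
    ----------
    gamma : float
        Signal variance (squared expression units), strictly positive.
    beta : ndarray
        Inverse length scales (per squared expression unit), one per
        candidate regulator coordinate (genes first, then external inputs).
        All entries must be non-negative.
    """

    gamma: float
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 1:
            raise ValueError("beta must be a 1-D vector of inverse length scales")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if np.any(self.beta < 0):
            raise ValueError("inverse length scales must be non-negative")


@dataclass
class MeanParams:
    """Affine drift mean m(x) = b - a*x: degradation rate a, basal rate b."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError("degradation and basal rates must be non-negative")


@dataclass
class GPTrainingSet:
    """Noisy drift observations (inputs xi_j, targets eta_j) with noise variance r."""

    inputs: np.ndarray
    targets: np.ndarray
    noise_var: float = 0.0

    def __post_init__(self) -> None:
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal length")
        if self.noise_var < 0:
            raise ValueError("noise variance must be non-negative")


def se_ard_kernel(x: np.ndarray, z: np.ndarray, kp: KernelParams) -> float:
    """Evaluate the SE-ARD covariance between two points.

    Symmetric in ``(x, z)`` and bounded by ``kp.gamma``.
    """
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape or x.shape != kp.beta.shape:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, z {z.shape}, beta {kp.beta.shape}"
        )
    return float(kp.gamma * np.exp(-np.dot(kp.beta, (x - z) ** 2)))


def mean_fn(x_i: float, mp: MeanParams) -> float:
    """Drift mean b - a*x_i (may be negative above the basal steady level b/a)."""
    return mp.b - mp.a * x_i


def sq_dist_stack(points: np.ndarray) -> np.ndarray:
    """Per-coordinate squared distance tensor D[j, k, l] = (p_kj - p_lj)^2.

    Precomputed once per point set so Gram matrices for many beta vectors can
    be built by a single tensor contraction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points[:, None, :] - points[None, :, :]
    return np.ascontiguousarray(np.moveaxis(diff**2, -1, 0))


def gram_from_sqdist(sqd: np.ndarray, gamma: float, beta: np.ndarray) -> np.ndarray:
    """Gram matrix from a precomputed squared-distance stack."""
    return gamma * np.exp(-np.tensordot(beta, sqd, axes=1))


def gram_matrix(points: np.ndarray, kp: KernelParams) -> np.ndarray:
    """Dense N x N SE-ARD Gram matrix over the rows of ``points``.

    Symmetric with diagonal ``kp.gamma``; positive semi-definite up to
    floating-point roundoff (add ``JITTER * gamma`` before factorizing).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != kp.beta.shape[0]:
        raise ValueError("point dimension does not match beta length")
    return gram_from_sqdist(sq_dist_stack(points), kp.gamma, kp.beta)


def cross_gram(a: np.ndarray, b: np.ndarray, kp: KernelParams) -> np.ndarray:
    """Rectangular Gram matrix k(a_k, b_l) between two point sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    diff = a[:, None, :] - b[None, :, :]
    return kp.gamma * np.exp(-np.tensordot(diff**2, kp.beta, axes=(-1, 0)))


def gp_posterior_mean(
    query: np.ndarray,
    train: GPTrainingSet,
    kp: KernelParams,
    mp: MeanParams,
    target_index: int = 0,
) -> float:
    """Posterior mean of the drift GP at ``query`` given noisy observations.

    Computes m(xi) + K(xi, Xbar)(K(Xbar, Xbar) + r I)^{-1}(eta - m(Xbar))
    with a Cholesky solve.  ``target_index`` selects which coordinate of the
    input feeds the affine mean (the gene's own expression level).
    """
    query = np.asarray(query, dtype=float).ravel()
    if train.inputs.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    K = gram_matrix(train.inputs, kp)
    K[np.diag_indices_from(K)] += train.noise_var + JITTER * kp.gamma
    kstar = cross_gram(query[None, :], train.inputs, kp).ravel()
    resid = train.targets - (mp.b - mp.a * train.inputs[:, target_index])
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "conditioning matrix is singular; add observation noise or jitter"
        ) from exc
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, resid))
    return float(mean_fn(query[target_index], mp) + kstar @ alpha)
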