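"""Time grids, Euler discretization, and the marginal trajectory distribution.

Gene expression x(t) follows the SDE dx = f(x) dt + dw with a GP-distributed
drift f and Brownian process noise w of intensity diag(q).  On a refined
partition tau_0 < ... < tau_M the Euler scheme gives

    X_{tau_k} = X_{tau_{k-1}} + dtau_k f(u_{tau_{k-1}}, X_{tau_{k-1}}) + eps_k,
    eps_k ~ N(0, dtau_k diag(q)).

Integrating the GP drift out analytically, the increments d_i = Xbar_i -
Xunder_i of gene i are jointly Gaussian,

    d_i ~ N( Dtau m_i(Xunder),  Dtau K_i(Xunder) Dtau + q_i Dtau ),

with Dtau = diag(dtau_k), K_i the SE-ARD Gram matrix over previous-step
states (augmented with external-input coordinates), and m_i(x) = b_i - a_i
x_i.  Multiple series are independent initial-value problems sharing one
drift, so their increments are stacked into one joint Gaussian per gene.
Steady-state measurements enter as extra observations that the drift
vanishes there; a pseudo-input (FITC-style) low-rank approximation of K_i
cuts the cubic cost on dense grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2

from .kernels import JITTER, gram_from_sqdist, sq_dist_stack

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class Partition:
    """Refined time grid for one series, with the measurement-time -> index map."""

    grid_times: np.ndarray
    meas_index: np.ndarray  # grid index of each measurement time, in order

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.meas_index = np.asarray(self.meas_index, dtype=int)
        self._dtau = np.diff(self.grid_times)
        if np.any(self._dtau <= 0):
            raise ValueError("grid times must be strictly increasing")

    @property
    def dtau(self) -> np.ndarray:
        return self._dtau

    @property
    def n_steps(self) -> int:
        return self.grid_times.shape[0] - 1


@dataclass
class Trajectory:
    """Latent expression on the grid: (M+1) x n matrix, row k = state at tau_k."""

    values: np.ndarray
    partition: Partition

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.partition.grid_times.shape[0]:
            raise ValueError("trajectory must have one row per grid time")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")

    @classmethod
    def _wrap(cls, values: np.ndarray, partition: Partition) -> "Trajectory":
        """Unchecked constructor for hot loops building known-good states."""
        obj = object.__new__(cls)
        obj.values = values
        obj.partition = partition
        return obj


@dataclass
class NoiseParams:
    """Process-noise intensities q_i (per gene) and measurement variances r_i."""

    q: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.r = np.asarray(self.r, dtype=float).ravel()
        if np.any(self.q <= 0) or np.any(self.r <= 0):
            raise ValueError("noise intensities must be strictly positive")


@dataclass
class PseudoInputSet:
    """Representative points approximating the GP Gram matrix at low rank."""

    points: np.ndarray
    active: bool = True

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.active and self.points.shape[0] < 1:
            raise ValueError("need at least one pseudo-input when active")


def build_grid(meas_times: np.ndarray, refine: int = 1) -> Partition:
    """Refine measurement times into a latent grid.

    Inserts ``refine - 1`` equally spaced latent points inside every
    measurement interval, so non-constant sampling frequency yields
    non-constant grid steps.  All measurement times are grid points.
    """
    t = np.asarray(meas_times, dtype=float).ravel()
    if t.size < 1:
        raise ValueError("need at least one measurement time")
    if np.any(np.diff(t) <= 0):
        raise ValueError("measurement times must be strictly increasing")
    if refine < 1:
        raise ValueError("refine must be a positive integer")
    pieces = [np.array([t[0]])]
    for a, b in zip(t[:-1], t[1:]):
        pieces.append(np.linspace(a, b, refine + 1)[1:])
    grid = np.concatenate(pieces)
    meas_index = np.arange(0, grid.size, refine)
    return Partition(grid_times=grid, meas_index=meas_index)


def euler_simulate(
    drift,
    x0: np.ndarray,
    partition: Partition,
    q: np.ndarray,
    rng: np.random.Generator | int,
    inputs: np.ndarray | None = None,
) -> Trajectory:
    """Euler–Maruyama simulation of the SDE on the partition.

    ``drift`` maps a state vector (and, when ``inputs`` is given, the input
    row at the current grid time) to the drift vector.  ``q = 0`` gives a
    deterministic Euler integration.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x0 = np.asarray(x0, dtype=float).ravel()
    q = np.broadcast_to(np.asarray(q, dtype=float), x0.shape)
    if np.any(q < 0):
        raise ValueError("process-noise intensities must be non-negative")
    dtau = partition.dtau
    X = np.empty((dtau.size + 1, x0.size))
    X[0] = x0
    for k in range(dtau.size):
        if inputs is None:
            f = np.asarray(drift(X[k]), dtype=float)
        else:
            f = np.asarray(drift(X[k], inputs[k]), dtype=float)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"drift returned non-finite values at grid index {k}")
        X[k + 1] = X[k] + dtau[k] * f + rng.normal(size=x0.size) * np.sqrt(dtau[k] * q)
    return Trajectory(values=X, partition=partition)


def select_pseudo_inputs(
    X: Trajectory | np.ndarray, n_pseudo: int, seed: int | np.random.Generator
) -> PseudoInputSet:
    """Choose pseudo-inputs as k-means centroids of the previous-step rows.

    Deterministic given the seed; with ``n_pseudo`` equal to the number of
    rows the exact points are returned, making the low-rank approximation
    exact.
    """
    rows = X.values[:-1] if isinstance(X, Trajectory) else np.atleast_2d(X)
    if not 1 <= n_pseudo <= rows.shape[0]:
        raise ValueError("n_pseudo must be between 1 and the number of rows")
    if n_pseudo == rows.shape[0]:
        return PseudoInputSet(points=rows.copy())
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centroids, _ = kmeans2(rows, n_pseudo, minit="++", seed=rng)
    return PseudoInputSet(points=centroids)


# ---------------------------------------------------------------------------
# Gaussian log-density helpers


def _dense_gaussian_logpdf(resid: np.ndarray, cov: np.ndarray) -> float:
    L = np.linalg.cholesky(cov)
    alpha = np.linalg.solve(L, resid)
    return float(
        -0.5 * resid.size * LOG2PI
        - np.sum(np.log(np.diag(L)))
        - 0.5 * np.dot(alpha, alpha)
    )


def _fitc_parts(sqd_nm, sqd_mm, gamma, beta):
    """Whitened pieces of the FITC approximation K ~ Knm Kmm^-1 Kmn + diag(D).

    Returns (V, d_corr) with V = Lm^{-1} Knm^T the whitened cross block,
    so the low-rank term is V^T V and the diagonal correction is
    d_corr = gamma - diag(V^T V), clipped at zero.
    """
    Kmm = gram_from_sqdist(sqd_mm, gamma, beta)
    Kmm[np.diag_indices_from(Kmm)] += JITTER * gamma
    Knm = gamma * np.exp(-np.tensordot(beta, sqd_nm, axes=1))
    Lm = np.linalg.cholesky(Kmm)
    V = np.linalg.solve(Lm, Knm.T)  # (m, N)
    d_corr = np.maximum(gamma - np.einsum("ij,ij->j", V, V), 0.0)
    return V, d_corr


def _lowrank_gaussian_logpdf(resid, a_diag, dt, V):
    """log N(resid; 0, diag(a_diag) + (dt o V^T)(dt o V^T)^T).

    Uses the Woodbury identity with the normalized capacitance
    I + Ga Ga^T (Ga = V diag(dt/sqrt(a))): identity plus a Gram matrix,
    whose Cholesky factorization is stable regardless of how
    ill-conditioned the raw covariance is.
    """
    sa = np.sqrt(a_diag)
    Ga = V * (dt / sa)[None, :]
    C = Ga @ Ga.T
    C[np.diag_indices_from(C)] += 1.0
    LC = np.linalg.cholesky(C)
    ra = resid / sa
    w = np.linalg.solve(LC, Ga @ ra)
    quad = np.dot(ra, ra) - np.dot(w, w)
    logdet = np.sum(np.log(a_diag)) + 2.0 * np.sum(np.log(np.diag(LC)))
    return float(-0.5 * (resid.size * LOG2PI + logdet + quad))


# ---------------------------------------------------------------------------
# Marginal trajectory log-density


def stack_series(
    trajs: list[Trajectory], grid_inputs: list[np.ndarray] | None = None
):
    """Stack previous-step states, increments, and grid steps across series.

    Returns (Z, d, dt): Z the kernel-input rows (states plus input
    coordinates), d the per-gene increment matrix, dt the grid steps.  No
    increment crosses a series junction.
    """
    zs, ds, dts = [], [], []
    for s, tr in enumerate(trajs):
        prev = tr.values[:-1]
        if grid_inputs is not None:
            prev = np.hstack([prev, np.atleast_2d(grid_inputs[s])[:-1]])
        zs.append(prev)
        ds.append(np.diff(tr.values, axis=0))
        dts.append(tr.partition.dtau)
    return np.vstack(zs), np.vstack(ds), np.concatenate(dts)


def gene_increment_logpdf(
    d_i: np.ndarray,
    dt: np.ndarray,
    x_prev_i: np.ndarray,
    sqd: np.ndarray,
    gamma: float,
    beta: np.ndarray,
    q_i: float,
    a_i: float,
    b_i: float,
    pseudo: PseudoInputSet | None = None,
    Z: np.ndarray | None = None,
) -> float:
    """Log-density of one gene's stacked increments under the marginal model.

    ``sqd`` is the per-coordinate squared-distance stack over the kernel
    input rows Z (precomputed once per trajectory state and shared across
    genes).  Steady-state conditioning is handled by
    :func:`log_trajectory_prior`, not here.
    """
    resid = d_i - dt * (b_i - a_i * x_prev_i)

    if pseudo is not None and pseudo.active:
        # FITC low-rank path: cov = diag(q dt + dt^2 (D + jitter)) + U Kmm^-1 U^T
        diff_nm = Z[:, None, :] - pseudo.points[None, :, :]
        sqd_nm = np.ascontiguousarray(np.moveaxis(diff_nm**2, -1, 0))
        V, d_corr = _fitc_parts(sqd_nm, sq_dist_stack(pseudo.points), gamma, beta)
        a_diag = q_i * dt + dt**2 * (d_corr + JITTER * gamma)
        return _lowrank_gaussian_logpdf(resid, a_diag, dt, V)

    K = gram_from_sqdist(sqd, gamma, beta)
    K = K + np.eye(K.shape[0]) * (JITTER * gamma)
    cov = dt[:, None] * K * dt[None, :]
    cov[np.diag_indices_from(cov)] += q_i * dt
    return _dense_gaussian_logpdf(resid, cov)


def _gene_logpdf_with_ss(
    resid, dt, sqd, gamma, beta, q_i, a_i, b_i, Z, steady_points, ss_noise_scale,
    gene_index,
):
    """Dense log-density conditioning the increments on zero drift at steady states."""
    K = gram_from_sqdist(sqd, gamma, beta)
    K = K + np.eye(K.shape[0]) * (JITTER * gamma)
    cov = dt[:, None] * K * dt[None, :]
    cov[np.diag_indices_from(cov)] += q_i * dt
    diff = Z[:, None, :] - steady_points[None, :, :]
    K_zs = gamma * np.exp(-np.tensordot(diff**2, beta, axes=(-1, 0)))
    diff_ss = steady_points[:, None, :] - steady_points[None, :, :]
    K_ss = gamma * np.exp(-np.tensordot(diff_ss**2, beta, axes=(-1, 0)))
    K_ss[np.diag_indices_from(K_ss)] += ss_noise_scale * gamma + JITTER * gamma
    cross = dt[:, None] * K_zs
    m_ss = b_i - a_i * steady_points[:, gene_index]
    L_ss = np.linalg.cholesky(K_ss)
    # conditional of the increments given the zero-drift observations
    W = np.linalg.solve(L_ss, cross.T)  # (n_ss, N)
    obs_resid = np.linalg.solve(L_ss, 0.0 - m_ss)
    cond_mean_shift = W.T @ obs_resid
    cov_cond = cov - W.T @ W
    return _dense_gaussian_logpdf(resid - cond_mean_shift, cov_cond)


def log_trajectory_prior(
    trajs: Trajectory | list[Trajectory],
    hyper,
    grid_inputs: list[np.ndarray] | None = None,
    steady_points: np.ndarray | None = None,
    ss_noise_scale: float = 1e-4,
    pseudo: PseudoInputSet | None = None,
    per_gene: bool = False,
):
    """Marginal log-density of the discretised trajectory given hyperparameters.

    The density factorizes over genes; each factor is a Gaussian over that
    gene's stacked increments with covariance Dtau K_i Dtau + q_i Dtau.  The
    initial state of every series carries a flat (constant) factor, dropped
    here, so values are comparable only across states sharing the grids.
    ``hyper`` is any object exposing ``beta`` (n x (n+p)), ``gamma``, ``q``,
    ``a``, ``b`` vectors (see :class:`gpgrn.state.HyperState`).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    Z, d, dt = stack_series(trajs, grid_inputs)
    sqd = sq_dist_stack(Z)
    beta = np.atleast_2d(hyper.beta)
    n = beta.shape[0]
    n_ss = 0 if steady_points is None or steady_points.shape[0] == 0 else steady_points.shape[0]
    out = np.empty(n)
    for i in range(n):
        resid = d[:, i] - dt * (hyper.b[i] - hyper.a[i] * Z[:, i])
        if n_ss:
            out[i] = _gene_logpdf_with_ss(
                resid, dt, sqd, hyper.gamma[i], beta[i], hyper.q[i], hyper.a[i],
                hyper.b[i], Z, steady_points, ss_noise_scale, i,
            )
        else:
            out[i] = gene_increment_logpdf(
                d[:, i], dt, Z[:, i], sqd, hyper.gamma[i], beta[i], hyper.q[i],
                hyper.a[i], hyper.b[i], pseudo=pseudo, Z=Z,
            )
    return out if per_gene else float(np.sum(out))


def log_measurement_likelihood(
    ds, trajs: Trajectory | list[Trajectory], r: np.ndarray
) -> float:
    """Gaussian measurement log-likelihood y_{j,i} ~ N(X[t_j, i], r_i).

    Missing entries contribute nothing.  ``ds`` is a
    :class:`gpgrn.data.TimeSeriesDataset`; trajectories must be on grids
    whose ``meas_index`` maps every measurement time.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    r = np.asarray(r, dtype=float).ravel()
    if np.any(r <= 0):
        raise ValueError("measurement noise variances must be strictly positive")
    total = 0.0
    for s, tr in zip(ds.series, trajs):
        Xm = tr.values[tr.partition.meas_index]
        mask = s.mask
        resid = np.where(mask, s.values - Xm, 0.0)
        per_entry = -0.5 * (LOG2PI + np.log(r)[None, :]) - 0.5 * resid**2 / r[None, :]
        total += float(np.sum(per_entry[mask]))
    return total
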