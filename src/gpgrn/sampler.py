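"""MCMC engine: pCN trajectory updates, MH-within-Gibbs hyperparameter moves,
indicator (topology) flips, priors, chain pooling and the confidence matrix.

The posterior over (trajectory X, hyperparameters theta) factorizes as

    p(X, theta | Y)  ∝  p(Y | X, r) * p(X | theta) * p(theta),

where p(X|theta) is the marginal trajectory density (drift integrated out;
see :mod:`gpgrn.trajectory`) and p(theta) combines noninformative
inverse-Gamma priors on q, r, gamma, exponential priors on the slab
magnitudes H and the kinetic rates a, b, and the sparsity prior
p(S) ∝ eta^{|S|_0} on the binary topology.

Trajectories are updated with a preconditioned Crank–Nicolson (pCN)
proposal whose Gaussian reference is the law of the drift-free increments
N(0, q_i dtau_k); the proposal is reversible with respect to that
reference, so the acceptance ratio only involves the posterior divided by
the reference density and stays well behaved as the grid is refined.
Hyperparameters move by random walks (log-scale for positive scale
parameters, reflected at zero for a and b); one indicator entry per target
gene is flipped per sweep, with the slab magnitude persisting across
removals (pseudo-prior convention: every H_{i,j} carries the same
exponential factor whether or not the link is active, so the factor cancels
in flip ratios, the dimension-change Hastings factor is one, and the
marginal prior frequency of S_{i,j} = 1 is exactly eta/(eta+1)).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import get_lapack_funcs, solve_triangular
from scipy.special import gammaln

_potrf, _trtrs, _trtri = get_lapack_funcs(
    ("potrf", "trtrs", "trtri"), (np.empty((1, 1)),)
)

from .data import ModelAssembly, TimeSeriesDataset, concatenate
from .kernels import JITTER, gram_from_sqdist, sq_dist_stack
from .state import ConfidenceMatrix, HyperState, PriorSpec, SamplerConfig, default_eta
from .trajectory import (
    LOG2PI,
    PseudoInputSet,
    Trajectory,
    gene_increment_logpdf,
    _gene_logpdf_with_ss,
    select_pseudo_inputs,
)

# ---------------------------------------------------------------------------
# Priors


def _invgamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return shape * math.log(scale) - gammaln(shape) - (shape + 1) * math.log(x) - scale / x


def _expon_logpdf(x: float, rate: float) -> float:
    if x < 0:
        return -np.inf
    return math.log(rate) - rate * x


def log_prior(hyper: HyperState, spec: PriorSpec) -> float:
    """Joint log-prior of a hyperparameter state.

    Inverse-Gamma for every q_i, r_i, gamma_i; exponential for every slab
    magnitude H_{i,j} (inactive entries carry the same factor as a
    pseudo-prior, so link flips see only the eta term) and for a_i, b_i;
    plus |S|_0 * log(eta).  Out-of-support values yield -inf rather than
    raising.
    """
    total = 0.0
    for vec in (hyper.q, hyper.r, hyper.gamma):
        for x in vec:
            total += _invgamma_logpdf(float(x), spec.ig_shape, spec.ig_scale)
    for x in hyper.a:
        total += _expon_logpdf(float(x), spec.exp_rate_a)
    for x in hyper.b:
        total += _expon_logpdf(float(x), spec.exp_rate_b)
    for h in hyper.H.ravel():
        total += _expon_logpdf(float(h), spec.exp_rate_h)
    n_links = int(np.sum(hyper.S))
    if hyper.eta == 0:
        total += 0.0 if n_links == 0 else -np.inf
    else:
        total += n_links * math.log(hyper.eta)
    return float(total)


def prior_link_probability(eta: float) -> float:
    """Prior probability eta/(eta+1) that any given link exists."""
    if eta < 0:
        raise ValueError("eta must be non-negative")
    return eta / (eta + 1.0)


# ---------------------------------------------------------------------------
# Elementary MH pieces


def mh_step(
    current_logpost: float,
    proposal_logpost: float,
    log_hastings: float,
    rng: np.random.Generator,
) -> bool:
    """Metropolis–Hastings accept/reject for a single proposed move."""
    if not np.isfinite(current_logpost):
        raise ValueError("current log-posterior must be finite")
    if np.isnan(proposal_logpost) or np.isnan(log_hastings):
        warnings.warn("NaN log-posterior in proposal; rejecting")
        return False
    log_ratio = proposal_logpost - current_logpost + log_hastings
    if log_ratio >= 0:
        return True
    return bool(math.log(rng.random()) < log_ratio)


def propose_indicator_flip(
    S: np.ndarray, target_gene: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Toggle one uniformly chosen entry of row ``target_gene`` of S."""
    row = np.array(S[target_gene], dtype=int)
    col = int(rng.integers(row.size))
    row[col] = 1 - row[col]
    return row, col


def cn_propose_trajectory(
    trajs: list[Trajectory],
    q: np.ndarray,
    s: float,
    rng: np.random.Generator,
    frozen_cols: list[frozenset[int]] | None = None,
) -> list[Trajectory]:
    """Preconditioned Crank–Nicolson proposal for the latent trajectories.

    Keeps each series' initial state fixed and mixes the current increments
    with a fresh draw from the reference N(0, q_i dtau_k):
    ``eps_hat = sqrt(1 - s^2) eps + s zeta``.  ``s = 1`` is an independent
    redraw of the increments; ``s = 0`` returns the current state
    (degenerate, allowed for tests).  ``frozen_cols`` lists per-series gene
    columns to leave untouched (clamped knockouts).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("pCN step size must lie in [0, 1]")
    keep = math.sqrt(1.0 - s * s)
    out = []
    for si, tr in enumerate(trajs):
        d = tr.values[1:] - tr.values[:-1]
        dt = tr.partition.dtau
        zeta = rng.normal(size=d.shape) * np.sqrt(dt[:, None] * q[None, :])
        d_new = keep * d + s * zeta
        if frozen_cols:
            for g in frozen_cols[si]:
                d_new[:, g] = d[:, g]
        X = np.empty_like(tr.values)
        X[0] = tr.values[0]
        X[1:] = tr.values[0] + np.cumsum(d_new, axis=0)
        out.append(Trajectory._wrap(X, tr.partition))
    return out


def confidence_matrix(S_samples: np.ndarray, gene_names=None, input_names=None) -> ConfidenceMatrix:
    """Element-wise mean of the indicator samples (posterior link probabilities)."""
    S_samples = np.asarray(S_samples)
    if S_samples.ndim != 3 or S_samples.shape[0] < 1:
        raise ValueError("need a stack of at least one indicator sample")
    return ConfidenceMatrix(
        probs=S_samples.mean(axis=0),
        n_samples=S_samples.shape[0],
        gene_names=gene_names,
        input_names=input_names,
    )


# ---------------------------------------------------------------------------
# Posterior evaluation with per-gene caching


class Posterior:
    """Evaluates per-gene posterior factors against a cached trajectory state.

    The trajectory density factorizes over target genes: gene i's factor
    depends on the full previous-step state (through the kernel) but only on
    gene i's hyperparameters, so hyperparameter blocks are cheap to update.
    ``likelihood_off`` zeroes the measurement term; ``prior_only``
    additionally zeroes the trajectory term (used to validate that the
    topology-flip kernel preserves the sparsity prior).
    """

    def __init__(
        self,
        assembly: ModelAssembly,
        config: SamplerConfig,
        likelihood_off: bool = False,
        prior_only: bool = False,
    ) -> None:
        self.assembly = assembly
        self.config = config
        self.likelihood_off = likelihood_off
        self.prior_only = prior_only
        self.n = assembly.n_genes
        self.p = assembly.n_inputs
        ds = assembly.dataset
        self.clamped = ds.clamped or [frozenset()] * len(ds.series)
        self.has_clamping = any(self.clamped)
        self.has_ss = assembly.steady_points.shape[0] > 0
        self.pseudo: PseudoInputSet | None = None
        # per-gene inclusion mask over stacked increment rows (clamped series
        # contribute kernel-input rows but no dynamics factor for that gene)
        masks = []
        row_counts = [p.n_steps for p in assembly.partitions]
        for i in range(self.n):
            m = np.concatenate(
                [
                    np.full(c, i not in cl, dtype=bool)
                    for c, cl in zip(row_counts, self.clamped)
                ]
            )
            masks.append(m)
        self.gene_masks = masks
        # dt and everything derived from it is fixed by the partitions
        self.dt = np.concatenate([p.dtau for p in assembly.partitions])
        self.dtouter = self.dt[:, None] * self.dt[None, :]
        self._dtouter_flat = self.dtouter.reshape(-1)
        self._dt2jit = JITTER * self.dt**2
        self._idx = np.arange(self.dt.size)
        self._invdt = 1.0 / self.dt
        self._logdt_sum = float(np.log(self.dt).sum())
        self._row_slices = []
        start = 0
        for c in row_counts:
            self._row_slices.append(slice(start, start + c))
            start += c
        # external-input kernel coordinates are fixed signals, so their
        # columns of Z and slabs of the squared-distance tensor never change
        gi = assembly.grid_inputs
        if self.p and gi is not None:
            N = self.dt.size
            U = np.empty((N, self.p))
            for s, sl in enumerate(self._row_slices):
                U[sl] = np.atleast_2d(gi[s])[:-1]
            self._u_cols = U
            self._input_sqd = np.empty((self.p, N, N))
            for j in range(self.p):
                diff = U[:, j, None] - U[None, :, j]
                np.multiply(diff, diff, out=self._input_sqd[j])
        else:
            self._u_cols = None
            self._input_sqd = None
        self.Z = self.d = self.sqd = self.sqd2 = None
        self._sqd_nm2 = None
        self._sqd_mm2 = None
        self._lr_split = None
        self._buffers = None
        self._buffer_mode = None
        # static measurement pieces: observation masks and zero-filled values
        self._meas_cache = []
        for s in assembly.dataset.series:
            obs = ~np.isnan(s.values)
            self._meas_cache.append(
                (obs, np.where(obs, s.values, 0.0), obs.sum(axis=0))
            )

    @property
    def fast(self) -> bool:
        """Whether the cached dense fast path applies (no special features)."""
        return not (self.has_ss or self.has_clamping or self.pseudo is not None
                    or self.prior_only)

    @property
    def fast_lowrank(self) -> bool:
        """Whether the cached pseudo-input (low-rank) fast path applies."""
        return self.pseudo is not None and not (
            self.has_ss or self.has_clamping or self.prior_only
        )

    # -- trajectory-dependent cache

    def set_trajs(self, trajs: list[Trajectory]) -> None:
        # Two buffer sets, used alternately: pCN keeps references to the
        # previous arrays so a rejected proposal is undone by restoring the
        # old pointers, and only the current and previous states are ever
        # live at once.  Writing into the set not currently referenced by
        # ``self.sqd`` is therefore safe and avoids reallocating ~0.5 MB
        # per proposal.
        n = self.n
        N = self.dt.size
        dim = n + self.p
        lowrank = self.fast_lowrank
        mode = "lowrank" if lowrank else "dense"
        if self._buffers is None or self._buffer_mode != mode:
            self._buffers = []
            self._buffer_mode = mode
            for _ in range(2):
                Zb = np.empty((N, dim))
                if self._u_cols is not None:
                    Zb[:, n:] = self._u_cols
                if lowrank:
                    # input coordinates and pseudo-points are fixed, so
                    # their distance slabs are filled once per allocation
                    P = self.pseudo.points
                    m_ps = P.shape[0]
                    split = N * m_ps
                    third = np.empty((dim, split + m_ps * m_ps))
                    nm = third[:, :split].reshape(dim, N, m_ps)
                    for j in range(n, dim):
                        np.subtract(Zb[:, j, None], P[None, :, j], out=nm[j])
                        np.multiply(nm[j], nm[j], out=nm[j])
                    third[:, split:] = self._sqd_mm2
                else:
                    third = np.empty((dim, N, N))
                    if self._input_sqd is not None:
                        third[n:] = self._input_sqd
                self._buffers.append((Zb, np.empty((N, n)), third))
        buf = self._buffers[0]
        if buf[0] is self.Z:
            buf = self._buffers[1]
        Z, d, third = buf
        for s, tr in enumerate(trajs):
            sl = self._row_slices[s]
            Z[sl, :n] = tr.values[:-1]
            np.subtract(tr.values[1:], tr.values[:-1], out=d[sl])
        self.Z = Z
        self.d = d
        if lowrank:
            # one flat squared-distance block per coordinate: rows-to-pseudo
            # distances (N*m) followed by pseudo-to-pseudo distances (m*m),
            # so every kernel evaluation is a single matmul + exp
            P = self.pseudo.points
            m_ps = P.shape[0]
            split = N * m_ps
            nm = third[:, :split].reshape(dim, N, m_ps)
            for j in range(n):
                np.subtract(Z[:, j, None], P[None, :, j], out=nm[j])
                np.multiply(nm[j], nm[j], out=nm[j])
            self._sqd_nm2 = third
            self._lr_split = split
            self.sqd = self.sqd2 = None
        else:
            for j in range(n):
                np.subtract(Z[:, j, None], Z[None, :, j], out=third[j])
                np.multiply(third[j], third[j], out=third[j])
            self.sqd = third
            self.sqd2 = third.reshape(dim, N * N)
            self._sqd_nm2 = None

    def refresh_pseudo(self, rng: np.random.Generator) -> None:
        """Re-pick the pseudo-inputs from the current kernel-input rows.

        ``"auto"`` keeps the exact density on small grids and uses a few
        dozen inducing points on larger ones; the drift surfaces live in a
        low-dimensional regulator space and are smooth under the
        squared-exponential kernel, so tens of centroids resolve them.
        """
        n_pseudo = self.config.n_pseudo
        N = self.dt.size
        if n_pseudo == "auto":
            n_pseudo = "exact" if N <= 64 else min(64, max(32, N // 4))
        if n_pseudo == "exact" or n_pseudo is None:
            self.pseudo = None
            return
        m = min(int(n_pseudo), self.Z.shape[0])
        self.pseudo = select_pseudo_inputs(self.Z, m, rng)
        P = self.pseudo.points
        self._sqd_mm2 = sq_dist_stack(P).reshape(P.shape[1], -1)
        # the buffers' static slabs encode the previous pseudo-points;
        # force a reallocation so the next set_trajs refills them
        self._buffers = None

    # -- trajectory prior factors

    def gene_factor(self, i: int, hyper: HyperState) -> float:
        """Trajectory-prior factor of gene i at the cached trajectory state."""
        if self.prior_only:
            return 0.0
        beta = hyper.S[i] * hyper.H[i]
        m = self.gene_masks[i]
        if self.has_ss:
            sub = np.ix_(np.arange(self.sqd.shape[0]), np.where(m)[0], np.where(m)[0])
            resid = self.d[m, i] - self.dt[m] * (hyper.b[i] - hyper.a[i] * self.Z[m, i])
            return _gene_logpdf_with_ss(
                resid, self.dt[m], self.sqd[sub], hyper.gamma[i], beta,
                hyper.q[i], hyper.a[i], hyper.b[i], self.Z[m],
                self.assembly.steady_points, self.config.ss_noise_scale, i,
            )
        if not m.all():
            sub = np.ix_(np.arange(self.sqd.shape[0]), np.where(m)[0], np.where(m)[0])
            return gene_increment_logpdf(
                self.d[m, i], self.dt[m], self.Z[m, i], self.sqd[sub],
                hyper.gamma[i], beta, hyper.q[i], hyper.a[i], hyper.b[i],
                pseudo=self.pseudo, Z=self.Z[m],
            )
        return gene_increment_logpdf(
            self.d[:, i], self.dt, self.Z[:, i], self.sqd,
            hyper.gamma[i], beta, hyper.q[i], hyper.a[i], hyper.b[i],
            pseudo=self.pseudo, Z=self.Z,
        )

    def all_gene_factors(self, hyper: HyperState) -> np.ndarray:
        """All genes' trajectory factors; batched when no special features."""
        if self.prior_only:
            return np.zeros(self.n)
        if self.fast:
            return _batched_factors(self, hyper)[0]
        if self.fast_lowrank:
            return _lr_batched_factors(self, hyper)[0]
        return np.array([self.gene_factor(i, hyper) for i in range(self.n)])

    # -- measurement likelihood factors

    def meas_factor(self, i: int, trajs: list[Trajectory], r_i: float) -> float:
        if self.likelihood_off or self.prior_only:
            return 0.0
        total = 0.0
        for (obs, vals0, counts), tr in zip(self._meas_cache, trajs):
            xm = tr.values[tr.partition.meas_index, i]
            resid = (vals0[:, i] - xm) * obs[:, i]
            total += float(
                -0.5 * counts[i] * (LOG2PI + math.log(r_i))
                - 0.5 * (resid @ resid) / r_i
            )
        return total

    def all_meas_factors(self, trajs: list[Trajectory], r: np.ndarray) -> np.ndarray:
        if self.likelihood_off or self.prior_only:
            return np.zeros(self.n)
        total = np.zeros(self.n)
        for (obs, vals0, counts), tr in zip(self._meas_cache, trajs):
            xm = tr.values[tr.partition.meas_index]
            resid = (vals0 - xm) * obs
            total += (
                -0.5 * counts * (LOG2PI + np.log(r))
                - 0.5 * np.einsum("ki,ki->i", resid, resid) / r
            )
        return total

    # -- pCN reference density of the increments

    def reference_logpdf(self, q: np.ndarray) -> float:
        if self.prior_only:
            return 0.0
        d = self.d
        if not self.has_clamping:
            N = self.dt.size
            quad = (d * d).T @ self._invdt  # per-gene sum of d_k^2 / dt_k
            return float(
                -0.5 * (N * (self.n * LOG2PI + np.log(q).sum())
                        + self.n * self._logdt_sum)
                - 0.5 * (quad / q).sum()
            )
        total = 0.0
        for i in range(self.n):
            m = self.gene_masks[i]
            var = q[i] * self.dt[m]
            total += float(
                -0.5 * np.sum(np.log(2.0 * np.pi * var))
                - 0.5 * np.sum(d[m, i] ** 2 / var)
            )
        return total


def _batched_factors(post: Posterior, hyper: HyperState, reuse=None):
    """All per-gene trajectory factors with cached covariance cores.

    Returns (factors, caches): one :class:`_GeneCache` per gene, reused by
    the hyperparameter blocks so that only the pieces a proposal touches are
    recomputed.

    ``reuse`` may carry the caches of the current state evaluated at the
    *same* hyperparameters (as in a pCN trajectory proposal).  A gene whose
    active regulators are all external inputs (or none) then has a
    covariance that does not depend on the sampled trajectories, so its
    Cholesky factor is reused and only the residual solve is redone.
    """
    beta = hyper.S * hyper.H  # (n, n+p)
    n = beta.shape[0]
    dt = post.dt
    N = dt.size
    idx = post._idx
    factors = np.empty(n)
    caches = []
    for i in range(n):
        resid = post.d[:, i] - dt * (hyper.b[i] - hyper.a[i] * post.Z[:, i])
        if reuse is not None and reuse[i].L is not None and not beta[i, :n].any():
            c = reuse[i]
            alpha, _ = _trtrs(c.L, resid, lower=1)
            factors[i] = -0.5 * N * LOG2PI - c.logdet - 0.5 * float(alpha @ alpha)
            caches.append(_GeneCache(B=c.B, L=c.L, logdet=c.logdet, resid=resid))
            continue
        # B = E .* dt dt^T + jitter * dt^2 I  (gamma-free covariance core)
        if beta[i].any():
            A = beta[i] @ post.sqd2
            np.negative(A, out=A)
            np.exp(A, out=A)
            A *= post._dtouter_flat
            B = A.reshape(N, N)
        else:
            B = post.dtouter.copy()  # constant kernel: E is all ones
        B[idx, idx] += post._dt2jit
        cov = hyper.gamma[i] * B
        cov[idx, idx] += hyper.q[i] * dt
        f, L, logdet = _factor_from_cov(cov, resid)
        factors[i] = f
        caches.append(_GeneCache(B=B, L=L, logdet=logdet, resid=resid))
    return factors, caches


@dataclass
class _GeneCache:
    """Cached pieces of one gene's trajectory factor at the current state.

    ``B`` is the gamma-free covariance core E .* (dt dt^T) + jitter dt^2 I;
    the full covariance is gamma * B + diag(q dt).  ``L`` is its Cholesky
    factor, ``resid`` the increments minus the mean term.
    """

    B: np.ndarray
    L: np.ndarray
    logdet: float
    resid: np.ndarray


def _factor_from_cov(cov: np.ndarray, resid: np.ndarray):
    """Gaussian log-density pieces via direct LAPACK calls.

    Returns (logpdf, L, logdet) where only the lower triangle of ``L`` is
    meaningful.  A non-positive-definite covariance yields -inf so the
    enclosing MH step simply rejects instead of aborting the chain.

    ``cov`` must be a freshly built symmetric matrix; it is factored in
    place (its transpose is an F-contiguous view with identical values, so
    LAPACK needs no copy) and must not be reused by the caller.
    """
    L, info = _potrf(cov.T, lower=1, clean=0, overwrite_a=1)
    if info != 0:
        return -np.inf, None, float("nan")
    alpha, _ = _trtrs(L, resid, lower=1)
    logdet = float(np.log(L.diagonal()).sum())
    return (
        -0.5 * resid.size * LOG2PI - logdet - 0.5 * float(alpha @ alpha),
        L,
        logdet,
    )


@dataclass
class _LRCache:
    """Cached pieces of one gene's low-rank (pseudo-input) factor.

    ``Enm``/``Emm`` are the gamma-free kernel shapes exp(-beta . sqd)
    between kernel-input rows and pseudo-inputs (N x m) and among
    pseudo-inputs (m x m).  ``Li`` is the inverse Cholesky factor of the
    (jittered) pseudo-point Gram matrix, ``V = Li Knm^T`` the whitened
    cross block, so the covariance is diag(a) + (dt o V^T)(dt o V^T)^T
    with a = q dt + dt^2 (d_corr + jitter gamma).  ``Ga = V diag(dt/sa)``
    (sa = sqrt(a)) and ``LC``, the Cholesky factor of the normalized
    capacitance I + Ga Ga^T, finish the Woodbury evaluation.  Every
    kernel piece scales exactly with gamma (stored alongside), so gamma
    and q proposals reuse them without refactorizing the kernel.
    """

    Enm: np.ndarray
    Emm: np.ndarray
    gamma: float
    Li: np.ndarray | None
    V: np.ndarray | None
    d_corr: np.ndarray | None
    sa: np.ndarray | None
    Ga: np.ndarray | None
    LC: np.ndarray | None
    logdet: float
    resid: np.ndarray


def _lr_fail(Enm, Emm, gamma, resid):
    nan = float("nan")
    return -np.inf, _LRCache(
        Enm, Emm, gamma, None, None, None, None, None, None, nan, resid
    )


def _lr_tail(dt, Enm, Emm, gamma, Li, V, d_corr, q, resid):
    """Finish a low-rank factor from its whitened kernel pieces.

    The capacitance is formed as I + Ga Ga^T — identity plus a Gram
    matrix — whose Cholesky pivots are bounded below by one, so the
    factorization stays stable even when gamma/q make the raw Woodbury
    matrix extremely ill-conditioned.
    """
    a = q * dt + (dt * dt) * (d_corr + JITTER * gamma)
    sa = np.sqrt(a)
    Ga = V * (dt / sa)[None, :]
    C = Ga @ Ga.T
    m = C.shape[0]
    C.flat[:: m + 1] += 1.0
    LC, info = _potrf(C.T, lower=1, clean=0, overwrite_a=1)
    if info != 0:
        return _lr_fail(Enm, Emm, gamma, resid)
    ra = resid / sa
    w, _ = _trtrs(LC, Ga @ ra, lower=1)
    quad = float(ra @ ra) - float(w @ w)
    logdet = float(np.log(a).sum()) + 2.0 * float(np.log(LC.diagonal()).sum())
    return (
        -0.5 * (dt.size * LOG2PI + logdet + quad),
        _LRCache(Enm, Emm, gamma, Li, V, d_corr, sa, Ga, LC, logdet, resid),
    )


def _lr_factor(dt: np.ndarray, Enm, Emm, gamma: float, q: float, resid):
    """One gene's Gaussian log-density under the pseudo-input approximation.

    cov = diag(q dt + dt^2 (d_corr + jitter gamma)) + (dt o Knm) Kmm^{-1} (dt o Knm)^T
    with the diagonal correction d_corr = gamma - diag(Knm Kmm^{-1} Kmn),
    evaluated with the Woodbury identity and the matrix determinant lemma.
    Returns (logpdf, cache); a non-positive-definite pseudo-point Gram
    matrix yields -inf so the enclosing MH step rejects.
    """
    m = Emm.shape[0]
    Kmm = gamma * Emm
    Kmm.flat[:: m + 1] += JITTER * gamma
    # clean=1 zeroes the unused triangle so the inverse factor can be used
    # in a plain matrix product below
    Lm, info = _potrf(Kmm.T, lower=1, clean=1, overwrite_a=1)
    if info != 0:
        return _lr_fail(Enm, Emm, gamma, resid)
    # inverting the small triangular factor once lets the N-column solve
    # run as a matrix product, which is much faster than a triangular solve
    Li, info = _trtri(Lm, lower=1)
    if info != 0:
        return _lr_fail(Enm, Emm, gamma, resid)
    V = Li @ (gamma * Enm).T
    d_corr = gamma - np.einsum("ij,ij->j", V, V)
    np.maximum(d_corr, 0.0, out=d_corr)
    return _lr_tail(dt, Enm, Emm, gamma, Li, V, d_corr, q, resid)


def _lr_traj_factor(dt, Enm, cache: _LRCache, gamma: float, q: float, resid):
    """Low-rank factor after a trajectory change, reusing kernel factors.

    The pseudo-inputs are fixed, so a trajectory move changes only the
    cross block Enm; the pseudo-point Gram factor carries over from the
    cached state unchanged.
    """
    V = cache.Li @ (gamma * Enm).T
    d_corr = gamma - np.einsum("ij,ij->j", V, V)
    np.maximum(d_corr, 0.0, out=d_corr)
    return _lr_tail(dt, Enm, cache.Emm, gamma, cache.Li, V, d_corr, q, resid)


def _lr_scaled_factor(dt, cache: _LRCache, gamma: float, q: float):
    """Low-rank factor after a gamma and/or q change, reusing kernel pieces.

    Every kernel block is proportional to gamma (the whitened cross block
    V scales with sqrt(gamma), its inverse Cholesky factor with
    1/sqrt(gamma), the diagonal correction with gamma), so a rescale is
    exact -- only the capacitance must be refactorized because the
    diagonal enters it nonlinearly.
    """
    if cache.LC is None:
        return _lr_factor(dt, cache.Enm, cache.Emm, gamma, q, cache.resid)
    rho = gamma / cache.gamma
    if rho == 1.0:
        Li, V, d_corr = cache.Li, cache.V, cache.d_corr
    else:
        s = math.sqrt(rho)
        Li = cache.Li / s
        V = s * cache.V
        d_corr = rho * cache.d_corr
    return _lr_tail(dt, cache.Enm, cache.Emm, gamma, Li, V, d_corr, q,
                    cache.resid)


def _lr_resid_factor(cache: _LRCache, resid: np.ndarray) -> float:
    """Re-evaluate a cached low-rank factor for a new residual only."""
    ra = resid / cache.sa
    w, _ = _trtrs(cache.LC, cache.Ga @ ra, lower=1)
    quad = float(ra @ ra) - float(w @ w)
    return -0.5 * (resid.size * LOG2PI + cache.logdet + quad)


def _lr_kernel_shapes(post: Posterior, beta: np.ndarray):
    """Gamma-free kernel shapes of one gene against the pseudo-inputs."""
    m = post.pseudo.points.shape[0]
    A = beta @ post._sqd_nm2
    np.negative(A, out=A)
    np.exp(A, out=A)
    split = post._lr_split
    return A[:split].reshape(-1, m), A[split:].reshape(m, m)


def _lr_batched_factors(post: Posterior, hyper: HyperState, reuse=None):
    """All per-gene low-rank trajectory factors at the cached state.

    The kernel shapes for all genes come from one matmul + exp over the
    concatenated squared-distance block; the remaining per-gene work is a
    handful of small (m x m) factorizations.  ``reuse`` may hold per-gene
    caches valid for the current hyperparameters (a trajectory move leaves
    the pseudo-point Gram factors unchanged), in which case only the cross
    block is rebuilt.
    """
    beta = hyper.S * hyper.H  # (n, n+p)
    n = beta.shape[0]
    dt = post.dt
    N = dt.size
    m = post.pseudo.points.shape[0]
    split = post._lr_split
    A = beta @ post._sqd_nm2[:, :split]
    np.negative(A, out=A)
    np.exp(A, out=A)
    resid = (
        post.d - dt[:, None] * (hyper.b[None, :] - hyper.a[None, :] * post.Z[:, :n])
    ).T.copy()
    factors = np.empty(n)
    caches = []
    for i in range(n):
        Enm = A[i].reshape(N, m)
        c = reuse[i] if reuse is not None else None
        if c is not None and c.LC is not None:
            f, c_new = _lr_traj_factor(
                dt, Enm, c, hyper.gamma[i], hyper.q[i], resid[i]
            )
        else:
            Emm = np.exp(-(beta[i] @ post._sqd_mm2)).reshape(m, m)
            f, c_new = _lr_factor(
                dt, Enm, Emm, hyper.gamma[i], hyper.q[i], resid[i]
            )
        factors[i] = f
        caches.append(c_new)
    return factors, caches


# ---------------------------------------------------------------------------
# The chain


@dataclass
class SweepCounts:
    """Per-block proposal/acceptance tallies for one or more sweeps."""

    proposed: dict[str, int] = field(default_factory=dict)
    accepted: dict[str, int] = field(default_factory=dict)

    def tally(self, block: str, accepted: bool) -> None:
        self.proposed[block] = self.proposed.get(block, 0) + 1
        if accepted:
            self.accepted[block] = self.accepted.get(block, 0) + 1

    def rate(self, block: str) -> float:
        p = self.proposed.get(block, 0)
        return self.accepted.get(block, 0) / p if p else float("nan")


class MCMCChain:
    """One MH-within-Gibbs chain over (trajectories, hyperparameters)."""

    def __init__(
        self,
        assembly: ModelAssembly,
        config: SamplerConfig,
        rng: np.random.Generator,
        hyper: HyperState | None = None,
        trajs: list[Trajectory] | None = None,
        likelihood_off: bool = False,
        prior_only: bool = False,
        update_trajectory: bool = True,
    ) -> None:
        self.assembly = assembly
        self.config = config
        self.rng = rng
        self.post = Posterior(assembly, config, likelihood_off, prior_only)
        self.update_trajectory = update_trajectory and not prior_only
        self.cn_step = config.cn_step
        self.spec = config.prior_spec
        n, p = assembly.n_genes, assembly.n_inputs
        eta = config.eta if config.eta is not None else default_eta(n)
        self.hyper = hyper if hyper is not None else HyperState.initial(n, p, eta)
        self.trajs = trajs if trajs is not None else initial_trajectories(assembly)
        self.counts = SweepCounts()
        base = config.rw_scales
        blocks = ("H", "gamma", "q", "r", "a", "b")
        if isinstance(base, dict):
            self.rw = {k: float(base.get(k, 0.1)) for k in blocks}
        else:
            self.rw = {k: float(base) for k in blocks}
        self._sweeps_done = 0
        self._sync()
        self.post.refresh_pseudo(self.rng)
        self._sync()

    # cached per-gene factors
    def _sync(self) -> None:
        self.post.set_trajs(self.trajs)
        if self.post.fast:
            self.prior_f, self.caches = _batched_factors(self.post, self.hyper)
        elif self.post.fast_lowrank:
            self.prior_f, self.caches = _lr_batched_factors(self.post, self.hyper)
        else:
            self.prior_f = self.post.all_gene_factors(self.hyper)
            self.caches = None
        self.meas_f = self.post.all_meas_factors(self.trajs, self.hyper.r)

    @property
    def log_posterior(self) -> float:
        return float(
            np.sum(self.prior_f) + np.sum(self.meas_f)
            + log_prior(self.hyper, self.spec)
        )

    # -- trajectory block -------------------------------------------------

    def _pcn_substep(self) -> None:
        prop = cn_propose_trajectory(
            self.trajs, self.hyper.q, self.cn_step, self.rng,
            frozen_cols=self.post.clamped if self.post.has_clamping else None,
        )
        ref_cur = self.post.reference_logpdf(self.hyper.q)
        cur = float(np.sum(self.prior_f) + np.sum(self.meas_f)) - ref_cur
        saved = (
            self.post.Z, self.post.d, self.post.sqd, self.post.sqd2,
            self.post._sqd_nm2,
        )
        self.post.set_trajs(prop)
        if self.post.fast:
            # hyperparameters are fixed within the trajectory block, so
            # factors of genes without active gene-coordinate regulators
            # can reuse the current Cholesky factors
            prior_new, caches_new = _batched_factors(
                self.post, self.hyper, reuse=self.caches
            )
        elif self.post.fast_lowrank:
            prior_new, caches_new = _lr_batched_factors(
                self.post, self.hyper, reuse=self.caches
            )
        else:
            prior_new = self.post.all_gene_factors(self.hyper)
            caches_new = None
        meas_new = self.post.all_meas_factors(prop, self.hyper.r)
        new = (
            float(np.sum(prior_new) + np.sum(meas_new))
            - self.post.reference_logpdf(self.hyper.q)
        )
        if mh_step(cur, new, 0.0, self.rng):
            self.trajs = prop
            self.prior_f, self.meas_f, self.caches = prior_new, meas_new, caches_new
            self.counts.tally("trajectory", True)
        else:
            (self.post.Z, self.post.d, self.post.sqd, self.post.sqd2,
             self.post._sqd_nm2) = saved
            self.counts.tally("trajectory", False)

    # -- hyperparameter blocks (gene i) -----------------------------------
    # Each block mutates self.hyper in place, evaluates only the factors it
    # touches (reusing the per-gene cache), and restores the value on reject.

    def _decide(self, block: str, log_ratio: float) -> bool:
        if np.isnan(log_ratio):
            warnings.warn(f"NaN log-ratio in block {block}; rejecting")
            self.counts.tally(block, False)
            return False
        ok = log_ratio >= 0 or math.log(self.rng.random()) < log_ratio
        self.counts.tally(block, ok)
        return ok

    def _beta_factor(self, i: int):
        """Gene i's factor after a beta (S or H) change; returns (f, cache)."""
        if self.caches is None:
            return self.post.gene_factor(i, self.hyper), None
        c = self.caches[i]
        post = self.post
        beta = self.hyper.S[i] * self.hyper.H[i]
        if post.fast_lowrank:
            Enm, Emm = _lr_kernel_shapes(post, beta)
            return _lr_factor(
                post.dt, Enm, Emm, self.hyper.gamma[i], self.hyper.q[i], c.resid
            )
        N = post.dt.size
        idx = post._idx
        if beta.any():
            A = beta @ post.sqd2
            np.negative(A, out=A)
            np.exp(A, out=A)
            A *= post._dtouter_flat
            B = A.reshape(N, N)
        else:
            B = post.dtouter.copy()  # constant kernel: E is all ones
        B[idx, idx] += post._dt2jit
        cov = self.hyper.gamma[i] * B
        cov[idx, idx] += self.hyper.q[i] * post.dt
        f, L, logdet = _factor_from_cov(cov, c.resid)
        return f, _GeneCache(B=B, L=L, logdet=logdet, resid=c.resid)

    def _scale_factor(self, i: int):
        """Gene i's factor after a gamma or q change (kernel shape unchanged)."""
        if self.caches is None:
            return self.post.gene_factor(i, self.hyper), None
        c = self.caches[i]
        if self.post.fast_lowrank:
            return _lr_scaled_factor(
                self.post.dt, c, self.hyper.gamma[i], self.hyper.q[i]
            )
        cov = self.hyper.gamma[i] * c.B
        cov[self.post._idx, self.post._idx] += self.hyper.q[i] * self.post.dt
        f, L, logdet = _factor_from_cov(cov, c.resid)
        return f, _GeneCache(B=c.B, L=L, logdet=logdet, resid=c.resid)

    def _mean_factor(self, i: int):
        """Gene i's factor after an a or b change (covariance unchanged)."""
        if self.caches is None:
            return self.post.gene_factor(i, self.hyper), None
        c = self.caches[i]
        resid = self.post.d[:, i] - self.post.dt * (
            self.hyper.b[i] - self.hyper.a[i] * self.post.Z[:, i]
        )
        if self.post.fast_lowrank:
            if c.LC is None:  # current state was non-PD; rebuild fully
                return _lr_factor(
                    self.post.dt, c.Enm, c.Emm,
                    self.hyper.gamma[i], self.hyper.q[i], resid,
                )
            f = _lr_resid_factor(c, resid)
            return f, _LRCache(
                c.Enm, c.Emm, c.gamma, c.Li, c.V, c.d_corr,
                c.sa, c.Ga, c.LC, c.logdet, resid,
            )
        alpha, _ = _trtrs(c.L, resid, lower=1)
        f = -0.5 * resid.size * LOG2PI - c.logdet - 0.5 * float(alpha @ alpha)
        return f, _GeneCache(B=c.B, L=c.L, logdet=c.logdet, resid=resid)

    def _commit(self, i: int, f: float, cache) -> None:
        self.prior_f[i] = f
        if self.caches is not None:
            self.caches[i] = cache

    def _update_indicator(self, i: int) -> None:
        row, col = propose_indicator_flip(self.hyper.S, i, self.rng)
        old = self.hyper.S[i, col]
        self.hyper.S[i, col] = row[col]
        # the persistent slab's exponential factor is carried on both sides
        # of the flip, so only the sparsity term remains in the prior ratio
        log_eta = math.log(self.hyper.eta) if self.hyper.eta > 0 else -np.inf
        delta = log_eta if row[col] == 1 else -log_eta
        f, cache = self._beta_factor(i)
        if self._decide("indicator", (f - self.prior_f[i]) + delta):
            self._commit(i, f, cache)
        else:
            self.hyper.S[i, col] = old

    def _update_h(self, i: int, j: int) -> None:
        h = self.hyper.H[i, j]
        h_new = h * math.exp(self.rw["H"] * self.rng.normal())
        self.hyper.H[i, j] = h_new
        delta = (
            _expon_logpdf(h_new, self.spec.exp_rate_h)
            - _expon_logpdf(h, self.spec.exp_rate_h)
            + math.log(h_new / h)  # Jacobian of the log-scale walk
        )
        f, cache = self._beta_factor(i)
        if self._decide("H", (f - self.prior_f[i]) + delta):
            self._commit(i, f, cache)
        else:
            self.hyper.H[i, j] = h

    def _update_scale(self, i: int, name: str) -> None:
        vec = getattr(self.hyper, name)
        x = vec[i]
        x_new = x * math.exp(self.rw[name] * self.rng.normal())
        vec[i] = x_new
        delta = (
            _invgamma_logpdf(x_new, self.spec.ig_shape, self.spec.ig_scale)
            - _invgamma_logpdf(x, self.spec.ig_shape, self.spec.ig_scale)
            + math.log(x_new / x)
        )
        f, cache = self._scale_factor(i)
        if self._decide(name, (f - self.prior_f[i]) + delta):
            self._commit(i, f, cache)
        else:
            vec[i] = x

    def _update_r(self, i: int) -> None:
        r = self.hyper.r[i]
        r_new = r * math.exp(self.rw["r"] * self.rng.normal())
        new_f = self.post.meas_factor(i, self.trajs, r_new)
        delta = (
            (new_f - self.meas_f[i])
            + _invgamma_logpdf(r_new, self.spec.ig_shape, self.spec.ig_scale)
            - _invgamma_logpdf(r, self.spec.ig_shape, self.spec.ig_scale)
            + math.log(r_new / r)
        )
        if self._decide("r", delta):
            self.hyper.r[i] = r_new
            self.meas_f[i] = new_f

    def _update_rate(self, i: int, name: str, rate: float) -> None:
        vec = getattr(self.hyper, name)
        x = vec[i]
        x_new = abs(x + self.rw[name] * self.rng.normal())  # reflect at 0
        vec[i] = x_new
        delta = _expon_logpdf(x_new, rate) - _expon_logpdf(x, rate)
        f, cache = self._mean_factor(i)
        if self._decide(name, (f - self.prior_f[i]) + delta):
            self._commit(i, f, cache)
        else:
            vec[i] = x

    # -- one full sweep ----------------------------------------------------

    def sweep(self) -> None:
        """One Gibbs sweep: trajectory sub-steps, then per-gene hyper blocks."""
        if self.update_trajectory:
            for _ in range(self.config.cn_substeps):
                self._pcn_substep()
        for i in range(self.post.n):
            self._update_indicator(i)
            for j in np.flatnonzero(self.hyper.S[i]):
                self._update_h(i, int(j))
            if not self.post.prior_only:
                self._update_scale(i, "gamma")
                self._update_scale(i, "q")
                self._update_r(i)
                self._update_rate(i, "a", self.spec.exp_rate_a)
                self._update_rate(i, "b", self.spec.exp_rate_b)
        self._sweeps_done += 1
        # the low-rank factor caches are updated incrementally; rebuilding
        # them from scratch periodically keeps accumulated roundoff from
        # drifting over long runs (the rebuild is exact in exact arithmetic,
        # so this does not change the target density)
        if self.post.fast_lowrank and self._sweeps_done % 100 == 0:
            self._sync()

    def adapt(self) -> None:
        """Nudge proposal scales toward healthy acceptance (burn-in only).

        The pCN step targets 20-30% acceptance; random-walk scales target
        roughly 30%.  Adaptation is frozen after burn-in to keep the
        post-burn-in kernel fixed (and hence ergodic).
        """
        rate = self.counts.rate("trajectory")
        if not np.isnan(rate):
            self.cn_step = float(
                np.clip(self.cn_step * math.exp(0.3 * (rate - 0.25)), 1e-4, 1.0)
            )
        for block in self.rw:
            br = self.counts.rate(block)
            if not np.isnan(br):
                self.rw[block] = float(
                    np.clip(self.rw[block] * math.exp(0.3 * (br - 0.3)), 1e-3, 10.0)
                )
        self.counts = SweepCounts()
        # pseudo-inputs track the trajectories the chain actually visits;
        # like the step sizes they are frozen after burn-in so the
        # post-burn-in kernel targets a fixed density
        if self.post.pseudo is not None:
            self.post.refresh_pseudo(self.rng)
            self._sync()


def gibbs_sweep(chain: MCMCChain) -> SweepCounts:
    """Run one full sweep on the chain and return its running tallies."""
    chain.sweep()
    return chain.counts


def initial_trajectories(assembly: ModelAssembly) -> list[Trajectory]:
    """Linear interpolation of per-gene mean-imputed measurements onto each grid."""
    out = []
    for s, part in zip(assembly.dataset.series, assembly.partitions):
        vals = np.array(s.values, dtype=float)
        for i in range(vals.shape[1]):
            col = vals[:, i]
            obs = ~np.isnan(col)
            if obs.all():
                continue
            fill = float(np.nanmean(col)) if obs.any() else 0.0
            if obs.any():
                vals[~obs, i] = np.interp(
                    s.times[~obs], s.times[obs], col[obs]
                )
            else:
                vals[:, i] = fill
        X = np.empty((part.grid_times.size, vals.shape[1]))
        for i in range(vals.shape[1]):
            X[:, i] = np.interp(part.grid_times, s.times, vals[:, i])
        out.append(Trajectory(values=X, partition=part))
    return out


# ---------------------------------------------------------------------------
# Full runs and pooling


@dataclass
class SampleStore:
    """Pooled MCMC output: indicator samples, hyper traces, diagnostics."""

    S_samples: np.ndarray  # (n_samples, n, n+p) int8
    hyper_traces: dict[str, np.ndarray]  # name -> (n_samples, n)
    chain_ids: np.ndarray
    acceptance: dict[str, float]
    config: SamplerConfig
    seeds: list[int]
    gene_names: list[str] | None = None
    input_names: list[str] | None = None
    trajectory_snapshots: list[np.ndarray] = field(default_factory=list)

    def confidence(self) -> ConfidenceMatrix:
        return confidence_matrix(self.S_samples, self.gene_names, self.input_names)

    def save(self, directory: str) -> None:
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        np.savez_compressed(
            os.path.join(directory, "indicator_samples.npz"),
            S=self.S_samples.astype(np.int8),
            chain=self.chain_ids,
        )
        for name, arr in self.hyper_traces.items():
            pd.DataFrame(arr).to_csv(
                os.path.join(directory, f"trace_{name}.csv"), index=False
            )
        meta = {
            "seeds": list(map(int, self.seeds)),
            "acceptance": self.acceptance,
            "n_samples": int(self.S_samples.shape[0]),
            "gene_names": self.gene_names,
            "input_names": self.input_names,
            "config": {
                k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                for k, v in vars(self.config).items()
            },
        }
        with open(os.path.join(directory, "run_manifest.json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def run_mcmc(
    data: TimeSeriesDataset | ModelAssembly,
    config: SamplerConfig,
    likelihood_off: bool = False,
) -> SampleStore:
    """Run ``config.n_chains`` independent chains and pool their samples.

    Chains use seeds spawned from ``config.seed``; burn-in samples are
    discarded, the remainder thinned by ``config.thin``.  The pCN step is
    adapted during burn-in only, so the post-burn-in kernel is fixed.
    """
    assembly = data if isinstance(data, ModelAssembly) else concatenate(data, config.refine)
    n, p = assembly.n_genes, assembly.n_inputs
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(max(1, config.n_chains))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    all_S, all_chain, traces = [], [], {k: [] for k in ("gamma", "q", "r", "a", "b")}
    acc_pool: dict[str, list[float]] = {}
    snapshots = []
    for ci, child in enumerate(children):
        rng = np.random.default_rng(child)
        chain = MCMCChain(assembly, config, rng, likelihood_off=likelihood_off)
        for it in range(config.n_iter):
            chain.sweep()
            if config.adapt_cn and it < config.burn_in and (it + 1) % 50 == 0:
                chain.adapt()
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                all_S.append(chain.hyper.S.copy())
                all_chain.append(ci)
                for k in traces:
                    traces[k].append(getattr(chain.hyper, k).copy())
        snapshots.append(np.vstack([t.values for t in chain.trajs]))
        for block in chain.counts.proposed:
            acc_pool.setdefault(block, []).append(chain.counts.rate(block))

    ds = assembly.dataset
    return SampleStore(
        S_samples=np.asarray(all_S, dtype=np.int8).reshape(-1, n, n + p),
        hyper_traces={k: np.asarray(v) for k, v in traces.items()},
        chain_ids=np.asarray(all_chain),
        acceptance={k: float(np.mean(v)) for k, v in acc_pool.items()},
        config=config,
        seeds=seeds,
        gene_names=list(ds.gene_names),
        input_names=list(ds.input_names),
        trajectory_snapshots=snapshots,
    )
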