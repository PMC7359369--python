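"""Shared oracles and instance builders for the test suite.

The oracles here are deliberately naive, loop-based implementations built
only from textbook formulas (dense multivariate-normal log-pdfs, brute-force
pair counting, exhaustive threshold enumeration) so they are independent of
the library's vectorized code paths.
"""

import numpy as np
from scipy.stats import multivariate_normal

from gpgrn import HyperState, KernelParams, Trajectory, build_grid, se_ard_kernel


def dense_trajectory_oracle(
    trajs,
    hyper,
    steady_points=None,
    ss_noise_scale=1e-4,
    jitter=1e-8,
):
    """Brute-force dense MVN evaluation of the marginal trajectory density.

    Builds, per gene, the full covariance Dtau K Dtau + q Dtau with explicit
    loops over the kernel, optionally conditions on zero-drift steady-state
    observations by block-Gaussian algebra, and calls scipy's generic
    multivariate-normal log-pdf.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    n = hyper.S.shape[0]
    Zs, ds, dts = [], [], []
    for tr in trajs:
        Zs.append(tr.values[:-1])
        ds.append(np.diff(tr.values, axis=0))
        dts.append(tr.partition.dtau)
    Z = np.vstack(Zs)
    d = np.vstack(ds)
    dt = np.concatenate(dts)
    N = dt.size
    total = 0.0
    for i in range(n):
        kp = KernelParams(gamma=hyper.gamma[i], beta=hyper.S[i] * hyper.H[i])
        K = np.array(
            [[se_ard_kernel(Z[p], Z[q], kp) for q in range(N)] for p in range(N)]
        )
        K = K + np.eye(N) * jitter * hyper.gamma[i]
        cov = np.diag(dt) @ K @ np.diag(dt) + np.diag(hyper.q[i] * dt)
        mean = dt * (hyper.b[i] - hyper.a[i] * Z[:, i])
        if steady_points is not None and np.size(steady_points):
            S = np.atleast_2d(steady_points)
            m_ss = hyper.b[i] - hyper.a[i] * S[:, i]
            Kzs = np.array(
                [[se_ard_kernel(Z[p], S[q], kp) for q in range(S.shape[0])] for p in range(N)]
            )
            Kss = np.array(
                [
                    [se_ard_kernel(S[p], S[q], kp) for q in range(S.shape[0])]
                    for p in range(S.shape[0])
                ]
            )
            Kss = Kss + np.eye(S.shape[0]) * (
                ss_noise_scale * hyper.gamma[i] + jitter * hyper.gamma[i]
            )
            cross = np.diag(dt) @ Kzs
            mean = mean + cross @ np.linalg.solve(Kss, -m_ss)
            cov = cov - cross @ np.linalg.solve(Kss, cross.T)
        total += multivariate_normal.logpdf(d[:, i], mean=mean, cov=cov, allow_singular=True)
    return float(total)


def random_instance(rng, n=None, M=None, refine=1):
    """A random (trajectory, hyperstate) pair with n <= 3 genes, M <= 10 steps."""
    n = int(rng.integers(1, 4)) if n is None else n
    M = int(rng.integers(2, 11)) if M is None else M
    times = np.cumsum(rng.uniform(0.2, 1.0, size=M + 1))
    times -= times[0]
    part = build_grid(times, refine)
    X = rng.normal(size=(part.grid_times.size, n))
    tr = Trajectory(values=X, partition=part)
    shape = (n, n)
    hyper = HyperState(
        S=rng.integers(0, 2, size=shape),
        H=rng.uniform(0.1, 2.0, size=shape),
        gamma=rng.uniform(0.3, 2.0, size=n),
        q=rng.uniform(0.05, 1.0, size=n),
        r=np.ones(n),
        a=rng.uniform(0.0, 1.0, size=n),
        b=rng.uniform(0.0, 1.0, size=n),
    )
    return tr, hyper


def auroc_oracle(scores, labels):
    """Brute-force Mann-Whitney pair counting with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (pos.size * neg.size)


def aupr_oracle(scores, labels):
    """Exhaustive threshold enumeration of the step precision-recall curve.

    Tied scores enter as one threshold block; the area is the sum of
    precision times recall increment over descending distinct thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_true = int(labels.sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        sel = scores >= t
        tp = int(labels[sel].sum())
        precision = tp / int(sel.sum())
        recall = tp / n_true
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area
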