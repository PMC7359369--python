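"""Sampler state containers: hyperparameters, configuration, confidence matrix."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


@dataclass
class HyperState:
    """All sampled hyperparameters of the model for one MCMC state.

    The inverse length scales decompose as beta_{i,j} = S_{i,j} * H_{i,j}:
    S is the binary adjacency (the quantity of interest), H the persistent
    slab magnitude retained across link removals.  Columns cover the n genes
    followed by any external inputs; rows are target genes.  The sparsity
    parameter eta is fixed, not sampled: a priori each link exists with
    probability eta / (eta + 1).
    """

    S: np.ndarray
    H: np.ndarray
    gamma: np.ndarray
    q: np.ndarray
    r: np.ndarray
    a: np.ndarray
    b: np.ndarray
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        self.H = np.asarray(self.H, dtype=float)
        for name in ("gamma", "q", "r", "a", "b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.S.shape != self.H.shape:
            raise ValueError("S and H must have identical shape")
        if not np.all((self.S == 0) | (self.S == 1)):
            raise ValueError("S entries must be binary")
        if np.any(self.H < 0):
            raise ValueError("slab magnitudes must be non-negative")
        if np.any(self.gamma <= 0) or np.any(self.q <= 0) or np.any(self.r <= 0):
            raise ValueError("gamma, q, r must be strictly positive")
        if np.any(self.a < 0) or np.any(self.b < 0) or self.eta < 0:
            raise ValueError("a, b, eta must be non-negative")

    @property
    def beta(self) -> np.ndarray:
        """Effective inverse length scales S * H."""
        return self.S * self.H

    @property
    def n_genes(self) -> int:
        return self.S.shape[0]

    def copy(self) -> "HyperState":
        return copy.deepcopy(self)

    @classmethod
    def initial(cls, n: int, n_inputs: int = 0, eta: float | None = None) -> "HyperState":
        """Default initialization on normalized data: empty topology, unit slabs."""
        if eta is None:
            eta = default_eta(n)
        shape = (n, n + n_inputs)
        return cls(
            S=np.zeros(shape, dtype=int),
            H=np.ones(shape),
            gamma=np.ones(n),
            q=np.full(n, 0.01),
            r=np.full(n, 0.01),
            a=np.ones(n),
            b=np.ones(n),
            eta=eta,
        )


def default_eta(n: int) -> float:
    """Sparsity parameter giving prior expected in-degree 2, clipped to (0, 1].

    Solving eta/(eta+1) * n = 2 gives eta = 2/(n-2); for n <= 4 this is
    clipped to 1 (a uniform prior over topologies).
    """
    if n <= 4:
        return 1.0
    return min(1.0, 2.0 / (n - 2))


@dataclass
class PriorSpec:
    """Hyperprior constants.

    Noninformative inverse-Gamma(shape, scale) for q, r, gamma; exponential
    (rate) priors for active slab magnitudes H and for the degradation and
    basal rates a, b — all on normalized data, where expression ranges are
    order one.
    """

    ig_shape: float = 0.01
    ig_scale: float = 0.01
    exp_rate_h: float = 1.0
    exp_rate_a: float = 1.0
    exp_rate_b: float = 1.0


@dataclass
class SamplerConfig:
    """Run-length, proposal-scale and parallel-chain settings.

    ``n_pseudo`` controls the pseudo-input (inducing point) acceleration of
    the trajectory density: an integer uses that many points, ``"exact"``
    disables the approximation, and ``"auto"`` (the default) keeps the
    exact density on small grids (up to 64 increments) and switches to a
    few dozen inducing points on larger ones, where the dense evaluation
    dominates the runtime.
    """

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    cn_step: float = 0.1
    cn_substeps: int = 5
    adapt_cn: bool = True
    rw_scales: float | dict = 0.1
    seed: int = 0
    n_chains: int = 1
    n_pseudo: int | str = "auto"
    refine: int | None = None
    eta: float | None = None
    ss_noise_scale: float = 1e-4
    prior_spec: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if not 0.0 < self.cn_step <= 1.0:
            raise ValueError("cn_step must lie in (0, 1]")


@dataclass
class ConfidenceMatrix:
    """Posterior link probabilities: the running mean of indicator samples.

    Entry (i, j) is the posterior probability that regulator j (gene or
    external input) acts on target gene i.  The diagonal (self-regulation)
    is reported but is excluded from standard benchmark scoring.
    """

    probs: np.ndarray
    n_samples: int
    gene_names: list[str] | None = None
    input_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("confidence entries must lie in [0, 1]")
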