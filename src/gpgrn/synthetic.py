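"""Synthetic gene-circuit simulator with known ground truth.

Small nonlinear networks with Hill-type transcription kinetics, integrated
as a chemical-Langevin-style SDE (Euler–Maruyama on a fine internal grid):

    dx_i = ( v_i * prod_act h(x_j) * prod_rep (1 - h(x_k)) - deg_i x_i ) dt
           + sqrt(q) dW_i,        h(x) = x^m / (x^m + K^m).

Protocols cover free-running recordings (transient discarded, then sampled
at a fixed interval) and perturbation–relaxation designs where a
transcription-rate multiplier is applied to a random gene subset for the
first half of the recording.  Measurement noise is additive Gaussian on the
sampled values.  Every simulation carries its binary ground-truth adjacency
for scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Series, TimeSeriesDataset


@dataclass
class SyntheticNetwork:
    """Signed regulatory structure plus per-gene/per-edge kinetic constants."""

    adjacency: np.ndarray  # n x n signed: +1 activation, -1 repression, 0 none
    max_rate: np.ndarray  # v_i, per-gene maximal transcription rate
    degradation: np.ndarray  # deg_i
    hill_coef: np.ndarray  # m, per edge (n x n)
    hill_thresh: np.ndarray  # K, per edge (n x n)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        for name in ("max_rate", "degradation"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            setattr(self, name, v)

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def ground_truth(self) -> np.ndarray:
        """Binary adjacency: entry (i, j) = 1 iff gene j regulates gene i."""
        return (self.adjacency != 0).astype(int)


@dataclass
class Protocol:
    """Experimental design for one simulated recording."""

    duration: float = 48.0
    transient_discard: float = 20.0
    sample_interval: float = 1.0
    process_noise: float = 0.01  # q, expression^2 per time unit
    meas_noise_sd: float = 0.05
    n_replicates: int = 1
    seed: int = 0
    perturb_genes: tuple[int, ...] = ()
    perturb_multiplier: float = 1.0
    perturb_first_half_only: bool = True

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.duration < self.sample_interval:
            raise ValueError("duration must cover at least one sampling interval")


def random_network(
    n: int,
    expected_in_degree: float,
    seed: int | np.random.Generator,
    n_edges: int | None = None,
) -> SyntheticNetwork:
    """Random directed network with Bernoulli edges, self-loops excluded.

    Each off-diagonal entry is a link with probability
    ``expected_in_degree / (n - 1)``; signs are activation or repression
    with equal probability.  ``n_edges`` forces an exact edge count instead
    (uniformly placed), useful for fixing the link density of a fixture.
    """
    if n < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    adj = np.zeros((n, n), dtype=int)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    if n_edges is not None:
        chosen = rng.choice(len(off), size=n_edges, replace=False)
        for c in chosen:
            i, j = off[c]
            adj[i, j] = 1
    else:
        p = expected_in_degree / (n - 1)
        for i, j in off:
            if rng.random() < p:
                adj[i, j] = 1
    signs = rng.choice([-1, 1], size=(n, n))
    adj *= signs
    return SyntheticNetwork(
        adjacency=adj,
        max_rate=np.full(n, 1.0),
        degradation=np.full(n, 1.0),
        hill_coef=np.full((n, n), 2.0),
        hill_thresh=np.full((n, n), 0.5),
    )


def hill(x: np.ndarray, m: float, K: float) -> np.ndarray:
    """Activating Hill function x^m / (x^m + K^m)."""
    xm = np.maximum(x, 0.0) ** m
    return xm / (xm + K**m)


def production(net: SyntheticNetwork, x: np.ndarray, rate_mult: np.ndarray | None = None) -> np.ndarray:
    """Per-gene transcription rate: v_i times the product of Hill terms."""
    n = net.n_genes
    prod = np.array(net.max_rate, dtype=float)
    if rate_mult is not None:
        prod = prod * rate_mult
    for i in range(n):
        for j in range(n):
            sign = net.adjacency[i, j]
            if sign == 0:
                continue
            h = hill(x[j], net.hill_coef[i, j], net.hill_thresh[i, j])
            prod[i] *= h if sign > 0 else (1.0 - h)
    return prod


def drift(net: SyntheticNetwork, x: np.ndarray, rate_mult: np.ndarray | None = None) -> np.ndarray:
    return production(net, x, rate_mult) - net.degradation * x


def _integrate(
    net: SyntheticNetwork,
    x0: np.ndarray,
    t_grid: np.ndarray,
    q: float,
    rng: np.random.Generator,
    rate_mult_fn=None,
) -> np.ndarray:
    X = np.empty((t_grid.size, net.n_genes))
    X[0] = x0
    for k in range(1, t_grid.size):
        dt = t_grid[k] - t_grid[k - 1]
        mult = rate_mult_fn(t_grid[k - 1]) if rate_mult_fn else None
        f = drift(net, X[k - 1], mult)
        X[k] = X[k - 1] + dt * f + rng.normal(size=net.n_genes) * np.sqrt(dt * q)
        X[k] = np.maximum(X[k], 0.0)  # expression cannot go negative
        if np.any(np.abs(X[k]) > 1e6):
            raise FloatingPointError(
                f"trajectory diverged at t={t_grid[k]:.3g} "
                f"(q={q}, rates={net.max_rate})"
            )
    return X


def simulate_expression(
    net: SyntheticNetwork, proto: Protocol
) -> tuple[list[np.ndarray], TimeSeriesDataset]:
    """Simulate the circuit and sample it per the protocol.

    Integrates on a fine internal grid (step <= sample_interval / 50),
    discards ``transient_discard`` time units, records ``duration`` and
    samples every ``sample_interval`` inclusive of both endpoints — a
    recording of duration D at interval h yields D/h + 1 points.  Gaussian
    measurement noise is added to the sampled values only.  Returns the
    dense post-transient trajectories and the sampled dataset.
    """
    rng = np.random.default_rng(proto.seed)
    n = net.n_genes
    step = proto.sample_interval / 50.0
    n_samp = int(round(proto.duration / proto.sample_interval)) + 1
    sample_times = np.arange(n_samp) * proto.sample_interval

    def mult_fn(t: float):
        if not proto.perturb_genes or proto.perturb_multiplier == 1.0:
            return None
        active = (not proto.perturb_first_half_only) or (t < proto.duration / 2.0)
        m = np.ones(n)
        if active:
            for g in proto.perturb_genes:
                m[g] = proto.perturb_multiplier
        return m

    dense_trajs, series = [], []
    for _ in range(proto.n_replicates):
        x0 = rng.uniform(0.1, 1.0, size=n)
        if proto.transient_discard > 0:
            n_burn = max(2, int(np.ceil(proto.transient_discard / step)) + 1)
            burn_grid = np.linspace(0.0, proto.transient_discard, n_burn)
            x0 = _integrate(net, x0, burn_grid, proto.process_noise, rng)[-1]
        # fine grid containing every sample time exactly
        per = max(1, int(np.ceil(proto.sample_interval / step)))
        fine = np.concatenate(
            [
                np.linspace(sample_times[k], sample_times[k + 1], per + 1)[:-1]
                for k in range(n_samp - 1)
            ]
            + [sample_times[-1:]]
        )
        X = _integrate(net, x0, fine, proto.process_noise, rng, mult_fn)
        dense_trajs.append(X)
        sample_idx = np.searchsorted(fine, sample_times)
        Y = X[sample_idx] + rng.normal(size=(n_samp, n)) * proto.meas_noise_sd
        series.append(Series(times=sample_times, values=Y))
    ds = TimeSeriesDataset(series=series, gene_names=[f"G{i+1}" for i in range(n)])
    return dense_trajs, ds


def steady_state(net: SyntheticNetwork, x0=None, t_max: float = 200.0) -> np.ndarray:
    """Deterministic steady state found by integrating the noise-free system."""
    n = net.n_genes
    x0 = np.full(n, 0.5) if x0 is None else np.asarray(x0, dtype=float)
    grid = np.linspace(0.0, t_max, int(t_max * 50) + 1)
    X = _integrate(net, x0, grid, 0.0, np.random.default_rng(0))
    return X[-1]


def dream_style_protocol(
    net: SyntheticNetwork,
    seed: int,
    n_series: int = 3,
    n_points: int = 21,
    duration: float = 20.0,
    process_noise: float = 0.01,
    meas_noise_sd: float = 0.05,
    multiplier: float = 3.0,
    with_inputs: bool = False,
) -> TimeSeriesDataset:
    """Perturbation–relaxation design: rate multiplier on a random gene subset
    for the first half of each recording, removed for the second half.

    Each series starts at the unperturbed steady state, has ``n_points``
    samples, and the dataset also carries that steady state as a
    steady-state measurement.

    With ``with_inputs=True`` the known experimental design is exposed to
    inference as external-input indicator courses: one 0/1 column per
    distinct perturbed gene, equal to 1 while that gene's transcription rate
    is multiplied in a given series.  The perturbation changes the dynamics,
    so an autonomous drift cannot explain the recording; the indicator gives
    the drift a coordinate that accounts for the regime switch, mirroring
    how known treatments are handled on real data.
    """
    rng = np.random.default_rng(seed)
    n = net.n_genes
    ss = steady_state(net)
    interval = duration / (n_points - 1)
    all_series = []
    perturbed_sets = []
    for s in range(n_series):
        k = max(1, n // 3)
        genes = tuple(int(g) for g in rng.choice(n, size=k, replace=False))
        perturbed_sets.append(genes)
        proto = Protocol(
            duration=duration,
            transient_discard=0.0,
            sample_interval=interval,
            process_noise=process_noise,
            meas_noise_sd=meas_noise_sd,
            n_replicates=1,
            seed=int(rng.integers(2**31)),
            perturb_genes=genes,
            perturb_multiplier=multiplier,
            perturb_first_half_only=True,
        )
        rng_rep = np.random.default_rng(proto.seed)

        def mult_fn(t: float, genes=genes):
            m = np.ones(n)
            if multiplier != 1.0 and t < duration / 2.0:
                for g in genes:
                    m[g] = multiplier
            return m if multiplier != 1.0 else None

        step = interval / 50.0
        per = max(1, int(np.ceil(interval / step)))
        sample_times = np.arange(n_points) * interval
        fine = np.concatenate(
            [
                np.linspace(sample_times[j], sample_times[j + 1], per + 1)[:-1]
                for j in range(n_points - 1)
            ]
            + [sample_times[-1:]]
        )
        X = _integrate(net, ss.copy(), fine, process_noise, rng_rep, mult_fn)
        idx = np.searchsorted(fine, sample_times)
        Y = X[idx] + rng_rep.normal(size=(n_points, n)) * meas_noise_sd
        all_series.append(Series(times=sample_times, values=Y))
    inputs = None
    input_names: list[str] = []
    if with_inputs:
        from .data import InputCourse

        distinct = sorted({g for genes in perturbed_sets for g in genes})
        input_names = [f"u_G{g+1}" for g in distinct]
        times = np.array([0.0, duration / 2.0])
        inputs = [
            InputCourse(
                times=times,
                values=np.array(
                    [[1.0 if g in genes else 0.0 for g in distinct],
                     [0.0] * len(distinct)]
                ),
            )
            for genes in perturbed_sets
        ]
    ds = TimeSeriesDataset(
        series=all_series,
        gene_names=[f"G{i+1}" for i in range(n)],
        inputs=inputs,
        input_names=input_names,
        steady_states=[ss],
    )
    return ds


def write_dataset_dir(ds: TimeSeriesDataset, net: SyntheticNetwork, directory: str) -> None:
    """Write series tables, the ground-truth edge list, and a manifest."""
    import json
    import os

    os.makedirs(directory, exist_ok=True)
    import pandas as pd

    for k, s in enumerate(ds.series):
        df = pd.DataFrame(s.values, columns=ds.gene_names)
        df.insert(0, "time", s.times)
        df.to_csv(os.path.join(directory, f"series_{k+1}.csv"), index=False)
    gt = net.ground_truth
    with open(os.path.join(directory, "ground_truth.tsv"), "w") as fh:
        for i in range(net.n_genes):
            for j in range(net.n_genes):
                if i != j and gt[i, j]:
                    fh.write(f"{ds.gene_names[j]}\t{ds.gene_names[i]}\t1\n")
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(
            {
                "n_genes": net.n_genes,
                "n_series": len(ds.series),
                "gene_names": ds.gene_names,
                "n_steady_states": len(ds.steady_states),
            },
            fh,
            indent=2,
        )
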