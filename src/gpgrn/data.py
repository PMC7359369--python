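"""Reading, validating, normalizing and assembling expression time-series data.

A dataset holds one or more bulk time series (rows = time points, columns =
genes), optional known external-input time courses (e.g. a drug on/off
indicator), optional steady-state expression vectors, and optional per-series
knockout annotations.  ``concatenate`` turns a validated dataset into the
model-ready assembly used by the likelihood: one refined time grid per
series, step-interpolated input courses on each grid, and the steady states
augmented with input coordinates.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory import Partition, build_grid

logger = logging.getLogger(__name__)


@dataclass
class Series:
    """One measured time series: times t_j and values Y (NaN = missing)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values must have one row per time point")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("measurement times must be strictly increasing")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) entries."""
        return ~np.isnan(self.values)


@dataclass
class InputCourse:
    """Known external-input signal sampled at given times (one series).

    Values between the given times are taken as previous-value (step)
    interpolation, matching step-like treatment indicators.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("input values must have one row per time point")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Step-interpolated input values at times ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("input course undefined before its first time point")
        return self.values[idx]


@dataclass
class TimeSeriesDataset:
    """Measured series with gene labels, optional inputs and steady states."""

    series: list[Series]
    gene_names: list[str]
    inputs: list[InputCourse] | None = None
    input_names: list[str] = field(default_factory=list)
    steady_states: list[np.ndarray] = field(default_factory=list)
    normalization: dict[str, tuple[float, float]] | None = None
    clamped: list[frozenset[int]] | None = None  # knocked-out gene indices per series

    def __post_init__(self) -> None:
        n = len(self.gene_names)
        for s in self.series:
            if s.values.shape[1] != n:
                raise ValueError("all series must share the gene set")
        if self.inputs is not None and len(self.inputs) != len(self.series):
            raise ValueError("one input course per series required")
        for ss in self.steady_states:
            if np.asarray(ss).ravel().shape[0] != n:
                raise ValueError(
                    f"steady-state vector length {len(np.asarray(ss).ravel())} "
                    f"does not match gene count {n}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_inputs(self) -> int:
        return len(self.input_names)


@dataclass
class ModelAssembly:
    """Model-ready view of a dataset: grids, grid inputs, augmented steady states.

    The trajectory prior treats series as independent initial-value problems
    (no dynamics increment across series junctions) while all series share one
    GP drift: the kernel conditioning set spans the previous-step rows of
    every series, plus one drift-is-zero observation per steady state.
    """

    dataset: TimeSeriesDataset
    partitions: list[Partition]
    grid_inputs: list[np.ndarray] | None  # (M_s+1, p) per series
    steady_points: np.ndarray  # (n_ss, n + p), input coords appended
    refine: int

    @property
    def n_genes(self) -> int:
        return self.dataset.n_genes

    @property
    def n_inputs(self) -> int:
        return self.dataset.n_inputs


def _parse_table(text: str, sep: str | None) -> pd.DataFrame:
    return pd.read_csv(
        io.StringIO(text), sep=sep, engine="python", na_values=["NA", "na", "NaN", ""]
    )


def _frames_from_file(path: str) -> list[pd.DataFrame]:
    """Parse a delimited file into one frame per blank-line-separated block."""
    with open(path) as fh:
        text = fh.read()
    blocks = [b for b in text.split("\n\n") if b.strip()]
    sep = None  # sniffed by the python engine
    return [_parse_table(b, sep) for b in blocks]


def read_dataset(paths: str | list[str]) -> TimeSeriesDataset:
    """Read time-series tables into a validated dataset.

    Each file holds one or more blank-line-separated blocks.  The first
    column is time, the header names the genes; missing values are empty
    cells or ``NA``.  Gene columns are aligned by name across blocks, so
    files with permuted columns are accepted.
    """
    if isinstance(paths, str):
        paths = [paths]
    frames: list[pd.DataFrame] = []
    for p in paths:
        frames.extend(_frames_from_file(p))
    if not frames:
        raise ValueError("no data blocks found")
    gene_names = list(frames[0].columns[1:])
    series = []
    for i, df in enumerate(frames):
        genes_here = set(df.columns[1:])
        if genes_here != set(gene_names):
            missing = set(gene_names) ^ genes_here
            raise ValueError(
                f"series {i} gene set differs from series 0; symmetric "
                f"difference: {sorted(missing)}"
            )
        times = df.iloc[:, 0].to_numpy(dtype=float)
        values = df[gene_names].to_numpy(dtype=float)
        series.append(Series(times, values))
    return TimeSeriesDataset(series=series, gene_names=gene_names)


def normalize(ds: TimeSeriesDataset) -> TimeSeriesDataset:
    """Scale each gene's observed dynamical range (max - min over all series) to one.

    No centering: constant shifts barely affect the model, as the trajectory
    density depends on expression differences between time points only.
    Genes with fewer than two distinct observed values are left unscaled with
    a warning — such genes should normally be excluded upstream.
    """
    n = ds.n_genes
    all_vals = np.vstack([s.values for s in ds.series])
    scales = np.ones(n)
    record: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(ds.gene_names):
        col = all_vals[:, i]
        obs = col[~np.isnan(col)]
        lo, hi = (np.min(obs), np.max(obs)) if obs.size else (np.nan, np.nan)
        if obs.size < 2 or hi == lo:
            warnings.warn(
                f"gene {name!r} has <2 distinct observed values; left unscaled"
            )
            record[name] = (float(lo), float(lo))
        else:
            scales[i] = hi - lo
            record[name] = (float(lo), float(hi))
    new_series = [Series(s.times, s.values / scales) for s in ds.series]
    new_ss = [np.asarray(ss, dtype=float) / scales for ss in ds.steady_states]
    return replace(ds, series=new_series, steady_states=new_ss, normalization=record)


def default_refine(ds: TimeSeriesDataset) -> int:
    """Smallest refinement so the largest grid step is <= median interval / 4."""
    intervals = np.concatenate([np.diff(s.times) for s in ds.series])
    med = float(np.median(intervals))
    return max(1, int(np.ceil(4.0 * float(np.max(intervals)) / med)))


def concatenate(ds: TimeSeriesDataset, refine: int | None = None) -> ModelAssembly:
    """Assemble a multi-series dataset for the model.

    Each series gets its own refined grid (an independent initial-value
    problem: no increment couples the end of one series to the start of the
    next) while the GP drift conditioning set spans all series.  Warns when
    per-series dynamical ranges differ by more than a factor of two, since
    concatenated series should have comparable properties.
    """
    if refine is None:
        refine = default_refine(ds)
    ranges = []
    for s in ds.series:
        obs = s.values[s.mask]
        ranges.append(np.ptp(obs) if obs.size else 0.0)
    finite = [r for r in ranges if r > 0]
    if finite and max(finite) > 2.0 * min(finite):
        warnings.warn(
            "per-series dynamical ranges differ by more than 2x; concatenated "
            "series should have similar properties"
        )
    partitions = [build_grid(s.times, refine) for s in ds.series]
    grid_inputs = None
    p = ds.n_inputs
    if ds.inputs is not None and p > 0:
        grid_inputs = [
            course.at(part.grid_times)
            for course, part in zip(ds.inputs, partitions)
        ]
    if ds.steady_states:
        # steady states carry no external input by convention (baseline state)
        ss = np.vstack([np.asarray(v, dtype=float).ravel() for v in ds.steady_states])
        steady_points = np.hstack([ss, np.zeros((ss.shape[0], p))]) if p else ss
    else:
        steady_points = np.empty((0, ds.n_genes + p))
    return ModelAssembly(
        dataset=ds,
        partitions=partitions,
        grid_inputs=grid_inputs,
        steady_points=steady_points,
        refine=refine,
    )


def add_steady_states(ds: TimeSeriesDataset, vectors: np.ndarray) -> TimeSeriesDataset:
    """Append steady-state expression vectors (rows) to the dataset.

    Each steady state contributes, for every gene, one observation that the
    drift vanishes there (f_i(x_ss) = 0) with a small noise variance; no
    latent trajectory is attached to steady states.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != ds.n_genes:
        raise ValueError(
            f"steady-state vectors have {vectors.shape[1]} entries, "
            f"expected {ds.n_genes}"
        )
    return replace(ds, steady_states=list(ds.steady_states) + [v for v in vectors])


def attach_inputs(
    ds: TimeSeriesDataset, courses: list[InputCourse], names: list[str]
) -> TimeSeriesDataset:
    """Attach known external-input time courses (one per series).

    Inputs become extra kernel coordinates with their own indicator/slab
    columns: links *from* inputs are inferred, links *to* inputs do not
    exist, and input trajectories are never sampled.
    """
    if len(courses) != len(ds.series):
        raise ValueError("one input course per series required")
    widths = {c.values.shape[1] for c in courses}
    if widths != {len(names)}:
        raise ValueError("input course width must match the number of input names")
    return replace(ds, inputs=courses, input_names=list(names))


def write_results(cm, path_matrix: str, path_edges: str, gene_names=None) -> None:
    """Write a confidence matrix and the DREAM-style ranked edge list.

    The matrix goes out as a delimited table with gene-name headers; the edge
    list has one ``regulator<TAB>target<TAB>score`` row per candidate link,
    sorted by descending score (ties broken by regulator then target name),
    self-loops excluded.
    """
    probs = np.asarray(getattr(cm, "probs", cm), dtype=float)
    n = probs.shape[0]
    if gene_names is None:
        gene_names = getattr(cm, "gene_names", None) or [f"G{i+1}" for i in range(n)]
    col_names = list(gene_names) + list(getattr(cm, "input_names", []) or [])
    col_names = col_names[: probs.shape[1]]
    df = pd.DataFrame(probs, index=gene_names, columns=col_names)
    df.to_csv(path_matrix)
    rows = []
    for i, target in enumerate(gene_names):
        for j, reg in enumerate(col_names):
            if j < n and reg == target:
                continue  # self-loop
            rows.append((reg, target, probs[i, j]))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path_edges, "w") as fh:
        for reg, target, score in rows:
            fh.write(f"{reg}\t{target}\t{score:.10g}\n")


def read_confidence_matrix(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Round-trip reader for matrices written by :func:`write_results`."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.index), list(df.columns)
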