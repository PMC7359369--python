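"""Dataset reading, validation, normalization, and model assembly."""

import warnings

import numpy as np
import pytest

from gpgrn import (
    ConfidenceMatrix,
    HyperState,
    InputCourse,
    Series,
    TimeSeriesDataset,
    Trajectory,
    add_steady_states,
    attach_inputs,
    concatenate,
    log_measurement_likelihood,
    log_trajectory_prior,
    normalize,
    read_confidence_matrix,
    read_dataset,
    write_results,
)
from conftest import dense_trajectory_oracle, random_instance


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadDataset:
    def test_single_table(self, tmp_path):
        path = _write(tmp_path, "s1.csv", "time,g1,g2\n0,0.1,0.5\n1,0.2,0.6\n2,0.3,0.7\n")
        ds = read_dataset([path])
        assert len(ds.series) == 1
        assert ds.gene_names == ["g1", "g2"]
        assert np.allclose(ds.series[0].times, [0, 1, 2])
        assert np.allclose(ds.series[0].values, [[0.1, 0.5], [0.2, 0.6], [0.3, 0.7]])

    def test_na_cell_masked(self, tmp_path):
        path = _write(tmp_path, "s1.csv", "time,g1\n0,0.1\n1,NA\n2,0.3\n")
        ds = read_dataset([path])
        mask = ds.series[0].mask
        assert mask.sum() == 2
        assert not mask[1, 0]

    def test_blank_line_blocks(self, tmp_path):
        path = _write(
            tmp_path, "s.csv", "time,g1\n0,0.1\n1,0.2\n\ntime,g1\n0,0.5\n2,0.6\n"
        )
        ds = read_dataset([path])
        assert len(ds.series) == 2
        assert np.allclose(ds.series[1].times, [0, 2])

    def test_tsv_dialect(self, tmp_path):
        path = _write(tmp_path, "s1.tsv", "time\tg1\n0\t0.1\n1\t0.2\n")
        ds = read_dataset([path])
        assert np.allclose(ds.series[0].values[:, 0], [0.1, 0.2])

    def test_permuted_columns_aligned_by_name(self, tmp_path):
        p1 = _write(tmp_path, "a.csv", "time,g1,g2\n0,0.1,0.5\n1,0.2,0.6\n")
        p2 = _write(tmp_path, "b.csv", "time,g2,g1\n0,0.7,0.3\n1,0.8,0.4\n")
        ds = read_dataset([p1, p2])
        assert ds.gene_names == ["g1", "g2"]
        assert np.allclose(ds.series[1].values, [[0.3, 0.7], [0.4, 0.8]])

    def test_inconsistent_genes_schema_error(self, tmp_path):
        p1 = _write(tmp_path, "a.csv", "time,g1,g2\n0,0.1,0.5\n1,0.2,0.6\n")
        p2 = _write(tmp_path, "b.csv", "time,g1,g3\n0,0.3,0.7\n1,0.4,0.8\n")
        with pytest.raises(ValueError, match="g3"):
            read_dataset([p1, p2])

    def test_unsorted_times_invalid(self, tmp_path):
        path = _write(tmp_path, "s1.csv", "time,g1\n1,0.1\n0,0.2\n")
        with pytest.raises(ValueError):
            read_dataset([path])


class TestNormalize:
    def _ds(self, values):
        times = np.arange(float(len(values)))
        return TimeSeriesDataset([Series(times, np.asarray(values, float)[:, None])], ["g1"])

    def test_range_scaling(self):
        ds = normalize(self._ds([0.0, 2.0, 4.0]))
        assert np.allclose(ds.series[0].values[:, 0], [0.0, 0.5, 1.0])

    def test_idempotent(self):
        once = normalize(self._ds([0.0, 1.5, 3.0]))
        twice = normalize(once)
        assert np.allclose(once.series[0].values, twice.series[0].values)

    def test_range_one_unchanged(self):
        ds = normalize(self._ds([0.2, 0.7, 1.2]))
        assert np.allclose(ds.series[0].values[:, 0], [0.2, 0.7, 1.2])

    def test_constant_gene_warns_and_skips(self):
        with pytest.warns(UserWarning):
            ds = normalize(self._ds([0.5, 0.5, 0.5]))
        assert np.allclose(ds.series[0].values[:, 0], 0.5)

    def test_joint_range_across_series(self):
        times = np.array([0.0, 1.0])
        ds = TimeSeriesDataset(
            [
                Series(times, np.array([[0.0], [1.0]])),
                Series(times, np.array([[2.0], [4.0]])),
            ],
            ["g1"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # range-difference warning is separate
            out = normalize(ds)
        assert np.allclose(out.series[1].values[:, 0], [0.5, 1.0])


class TestConcatenate:
    def test_junction_increment_count(self):
        times1 = np.arange(4.0)
        times2 = np.arange(3.0)
        ds = TimeSeriesDataset(
            [Series(times1, np.zeros((4, 1))), Series(times2, np.zeros((3, 1)))], ["g1"]
        )
        asm = concatenate(ds, refine=1)
        total_increments = sum(p.dtau.size for p in asm.partitions)
        assert total_increments == 3 + 2  # M1 + M2, no junction increment

    def test_single_series_identity(self):
        rng = np.random.default_rng(0)
        times = np.arange(5.0)
        X = rng.normal(size=(5, 2))
        ds = TimeSeriesDataset([Series(times, X.copy())], ["g1", "g2"])
        asm = concatenate(ds, refine=1)
        tr = Trajectory(values=X, partition=asm.partitions[0])
        _, hyper = random_instance(rng, n=2, M=4)
        direct = log_trajectory_prior(tr, hyper)
        via_asm = log_trajectory_prior([tr], hyper)
        assert direct == pytest.approx(via_asm, abs=1e-12)

    def test_series_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t1, t2 = np.arange(5.0), np.arange(4.0)
        X1, X2 = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        ds12 = TimeSeriesDataset([Series(t1, X1), Series(t2, X2)], ["g1", "g2"])
        ds21 = TimeSeriesDataset([Series(t2, X2), Series(t1, X1)], ["g1", "g2"])
        a12 = concatenate(ds12, refine=1)
        a21 = concatenate(ds21, refine=1)
        _, hyper = random_instance(rng, n=2, M=4)
        tr12 = [Trajectory(X1, a12.partitions[0]), Trajectory(X2, a12.partitions[1])]
        tr21 = [Trajectory(X2, a21.partitions[0]), Trajectory(X1, a21.partitions[1])]
        assert log_trajectory_prior(tr12, hyper) == pytest.approx(
            log_trajectory_prior(tr21, hyper), abs=1e-10
        )

    def test_range_difference_warning(self):
        times = np.array([0.0, 1.0])
        ds = TimeSeriesDataset(
            [
                Series(times, np.array([[0.0], [1.0]])),
                Series(times, np.array([[0.0], [5.0]])),
            ],
            ["g1"],
        )
        with pytest.warns(UserWarning, match="2x"):
            concatenate(ds, refine=1)


class TestSteadyStates:
    def test_zero_steady_states_bit_exact(self):
        rng = np.random.default_rng(2)
        tr, hyper = random_instance(rng, n=1, M=4)
        assert log_trajectory_prior(tr, hyper, steady_points=None) == log_trajectory_prior(
            tr, hyper, steady_points=np.empty((0, 1))
        )

    def test_matches_block_gaussian_oracle(self):
        rng = np.random.default_rng(3)
        tr, hyper = random_instance(rng, n=1, M=5)
        ss = rng.normal(size=(1, 1))
        got = log_trajectory_prior(tr, hyper, steady_points=ss)
        assert got == pytest.approx(dense_trajectory_oracle(tr, hyper, steady_points=ss), abs=1e-8)

    def test_duplicate_steady_state_less_informative_than_distinct(self):
        rng = np.random.default_rng(4)
        tr, hyper = random_instance(rng, n=1, M=5)
        s1 = rng.normal(size=(1, 1))
        s2 = rng.normal(size=(1, 1)) + 2.0
        base = log_trajectory_prior(tr, hyper, steady_points=s1)
        dup = log_trajectory_prior(tr, hyper, steady_points=np.vstack([s1, s1]))
        distinct = log_trajectory_prior(tr, hyper, steady_points=np.vstack([s1, s2]))
        assert abs(dup - base) < abs(distinct - base)

    def test_dimension_mismatch_raises(self):
        times = np.arange(3.0)
        ds = TimeSeriesDataset([Series(times, np.zeros((3, 2)))], ["g1", "g2"])
        with pytest.raises(ValueError):
            add_steady_states(ds, np.array([[0.1, 0.2, 0.3]]))


class TestAttachInputs:
    def _ds(self):
        times = np.arange(4.0)
        rng = np.random.default_rng(5)
        return TimeSeriesDataset([Series(times, rng.normal(size=(4, 2)))], ["g1", "g2"])

    def test_constant_zero_input_leaves_density_unchanged(self):
        ds = self._ds()
        course = InputCourse(times=np.array([0.0]), values=np.zeros((1, 1)))
        with_input = attach_inputs(ds, [course], ["u"])
        asm0 = concatenate(ds, refine=1)
        asm1 = concatenate(with_input, refine=1)
        rng = np.random.default_rng(6)
        X = ds.series[0].values
        tr0 = Trajectory(X, asm0.partitions[0])
        tr1 = Trajectory(X, asm1.partitions[0])
        _, hyper2 = random_instance(rng, n=2, M=3)
        hyper3 = HyperState(
            S=np.hstack([hyper2.S, np.ones((2, 1), int)]),
            H=np.hstack([hyper2.H, np.full((2, 1), 0.7)]),
            gamma=hyper2.gamma, q=hyper2.q, r=hyper2.r, a=hyper2.a, b=hyper2.b,
        )
        v0 = log_trajectory_prior(tr0, hyper2)
        v1 = log_trajectory_prior(tr1, hyper3, grid_inputs=asm1.grid_inputs)
        assert v1 == pytest.approx(v0, abs=1e-10)

    def test_undefined_before_first_time_raises(self):
        ds = self._ds()
        course = InputCourse(times=np.array([1.0]), values=np.zeros((1, 1)))
        with_input = attach_inputs(ds, [course], ["u"])
        with pytest.raises(ValueError):
            concatenate(with_input, refine=1)

    def test_input_column_shape(self):
        ds = self._ds()
        course = InputCourse(times=np.array([0.0, 2.0]), values=np.array([[1.0], [0.0]]))
        with_input = attach_inputs(ds, [course], ["u"])
        asm = concatenate(with_input, refine=2)
        assert asm.grid_inputs[0].shape == (asm.partitions[0].grid_times.size, 1)
        # step interpolation: value 1 before t=2, then 0
        g = asm.grid_inputs[0][:, 0]
        t = asm.partitions[0].grid_times
        assert np.all(g[t < 2.0] == 1.0)
        assert np.all(g[t >= 2.0] == 0.0)


class TestWriteResults:
    def test_edge_list_example(self, tmp_path):
        cm = ConfidenceMatrix(
            probs=np.array([[0.0, 0.9], [0.4, 0.0]]), n_samples=10, gene_names=["g1", "g2"]
        )
        pm, pe = str(tmp_path / "m.csv"), str(tmp_path / "e.tsv")
        write_results(cm, pm, pe)
        rows = [line.split("\t") for line in open(pe).read().strip().splitlines()]
        # probs[0, 1] = 0.9 means regulator g2 acts on target g1
        assert rows[0][:2] == ["g2", "g1"] and float(rows[0][2]) == 0.9
        assert rows[1][:2] == ["g1", "g2"] and float(rows[1][2]) == 0.4

    def test_matrix_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        probs = rng.uniform(size=(3, 3))
        cm = ConfidenceMatrix(probs=probs, n_samples=5, gene_names=["a", "b", "c"])
        pm, pe = str(tmp_path / "m.csv"), str(tmp_path / "e.tsv")
        write_results(cm, pm, pe)
        back, targets, regulators = read_confidence_matrix(pm)
        assert np.allclose(back, probs, atol=1e-12)
        assert targets == ["a", "b", "c"] and regulators == ["a", "b", "c"]

    def test_tie_break_by_name(self, tmp_path):
        cm = ConfidenceMatrix(
            probs=np.full((2, 2), 0.5), n_samples=1, gene_names=["g2", "g1"]
        )
        pm, pe = str(tmp_path / "m.csv"), str(tmp_path / "e.tsv")
        write_results(cm, pm, pe)
        rows = [line.split("\t")[:2] for line in open(pe).read().strip().splitlines()]
        assert rows == sorted(rows)


class TestMissingValueEquivalence:
    def test_mask_equals_deletion(self):
        times = np.arange(3.0)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(3, 1))
        Y = X + 0.1
        Ym = Y.copy()
        Ym[2, 0] = np.nan
        from gpgrn import build_grid

        part = build_grid(times, 1)
        tr = Trajectory(values=X, partition=part)
        r = np.array([0.3])
        masked = log_measurement_likelihood(
            TimeSeriesDataset([Series(times, Ym)], ["g1"]), tr, r
        )
        part2 = build_grid(times[:2], 1)
        deleted = log_measurement_likelihood(
            TimeSeriesDataset([Series(times[:2], Y[:2])], ["g1"]),
            Trajectory(values=X[:2], partition=part2),
            r,
        )
        assert masked == deleted
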