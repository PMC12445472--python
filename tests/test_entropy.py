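"""Diagonal partitions and the classical/quantum Renyi entropy objectives."""

import numpy as np
import pytest

from qrseg import (
    PENALTY_FITNESS,
    EntropyParams,
    FitnessEvaluator,
    ThresholdVector,
    classical_renyi,
    fitness,
    make_random_histogram,
    make_uniform_histogram,
    partition_diagonal,
    quantum_renyi,
    quantum_subsystem,
)
from qrseg.entropy import DiagonalRectangle
from qrseg.histogram import JointHistogram


def whole_grid(L):
    return [DiagonalRectangle(index=1, row_range=(0, L - 1), col_range=(0, L - 1))]


class TestThresholdVector:
    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError):
            ThresholdVector(rows=(5, 5), cols=(1, 2))

    def test_rejects_boundary_values(self):
        with pytest.raises(ValueError):
            ThresholdVector(rows=(0,), cols=(1,))
        with pytest.raises(ValueError):
            ThresholdVector(rows=(1,), cols=(255,))


class TestPartitionDiagonal:
    def test_single_threshold_two_rectangles(self):
        X = ThresholdVector(rows=(100,), cols=(120,))
        r1, r2 = partition_diagonal(256, X)
        assert r1.row_range == (0, 100) and r1.col_range == (0, 120)
        assert r2.row_range == (101, 255) and r2.col_range == (121, 255)

    def test_smallest_admissible_case(self):
        X = ThresholdVector(rows=(1, 2), cols=(1, 2), levels=4)
        rects = partition_diagonal(4, X)
        assert [(r.row_range, r.col_range) for r in rects] == [
            ((0, 1), (0, 1)), ((2, 2), (2, 2)), ((3, 3), (3, 3))
        ]

    @pytest.mark.parametrize("rows,cols", [((3, 90), (10, 40)), ((128,), (7,))])
    def test_row_ranges_tile_gray_range(self, rows, cols):
        X = ThresholdVector(rows=rows, cols=cols)
        rects = partition_diagonal(256, X)
        covered = []
        for r in rects:
            covered.extend(range(r.row_range[0], r.row_range[1] + 1))
        assert covered == list(range(256))


class TestClassicalRenyi:
    @pytest.mark.parametrize("L", [4, 16])
    @pytest.mark.parametrize("alpha", [0.01, 0.5, 2.0, 10.0])
    def test_uniform_histogram_closed_form(self, L, alpha):
        H = make_uniform_histogram(L)
        value = classical_renyi(H, whole_grid(L), EntropyParams(alpha=alpha))
        assert value == pytest.approx(2 * np.log(L), abs=1e-9)

    def test_uniform_L4_matches_direct_summation(self):
        # independent route: sum the L**2 weight powers explicitly
        L, a = 4, 0.3
        w = 1.0 / L**2
        direct = np.log(L**2 * w**a) / (1 - a)
        H = make_uniform_histogram(L)
        assert classical_renyi(H, whole_grid(L), EntropyParams(alpha=a)) == \
            pytest.approx(direct, abs=1e-12)

    def test_single_occupied_cell_zero_entropy(self):
        H = make_random_histogram(8, occupied_cells=1, seed=0)
        params = EntropyParams(alpha=0.5, empty_cell_policy="occupied_only")
        assert classical_renyi(H, whole_grid(8), params) == pytest.approx(0.0)

    def test_shannon_limit(self):
        H = make_random_histogram(16, occupied_cells=64, seed=3)
        w = H.weights[H.weights > 0]
        shannon = float(-(w * np.log(w)).sum())
        for a in (0.999, 1.001):
            value = classical_renyi(H, whole_grid(16), EntropyParams(alpha=a))
            assert abs(value - shannon) <= 1e-3 * max(1.0, shannon)


class TestQuantumSubsystem:
    def test_empty_cells_contribute_cos_zero(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[7, 7] = 10  # mass outside the probed rectangle
        H = JointHistogram(counts=counts)
        rect = DiagonalRectangle(index=1, row_range=(0, 3), col_range=(0, 3))
        sub = quantum_subsystem(H, rect, EntropyParams(mode="quantum"))
        assert sub.cos_sum == pytest.approx(16.0)
        assert sub.sin_sum == pytest.approx(0.0)
        assert sub.trace == pytest.approx(256.0)

    def test_full_weight_cell_is_spin_up(self):
        H = JointHistogram(counts=np.array([[5]]))
        rect = DiagonalRectangle(index=1, row_range=(0, 0), col_range=(0, 0))
        sub = quantum_subsystem(H, rect, EntropyParams(mode="quantum"))
        assert sub.cos_sum == pytest.approx(0.0, abs=1e-15)
        assert sub.sin_sum == pytest.approx(1.0)
        np.testing.assert_allclose(sub.rho, [[0, 0], [0, 1]], atol=1e-15)

    def test_rho_is_rank_one(self):
        H = make_random_histogram(16, occupied_cells=50, seed=9)
        rect = DiagonalRectangle(index=1, row_range=(2, 11), col_range=(1, 13))
        sub = quantum_subsystem(H, rect, EntropyParams(mode="quantum"))
        eigvals = np.sort(np.linalg.eigvalsh(sub.rho))
        assert eigvals[0] == pytest.approx(0.0, abs=1e-9 * sub.trace)
        assert eigvals[1] == pytest.approx(sub.trace, rel=1e-12)


class TestQuantumRenyi:
    @pytest.mark.parametrize("alpha", [0.01, 0.5, 2.0])
    def test_rank_one_closed_form(self, alpha):
        H = make_random_histogram(16, occupied_cells=40, seed=4)
        params = EntropyParams(alpha=alpha, mode="quantum")
        rect = whole_grid(16)
        sub = quantum_subsystem(H, rect[0], params)
        closed = (alpha / (1 - alpha)) * np.log(sub.trace)
        assert quantum_renyi(H, rect, params) == pytest.approx(closed, abs=1e-9)

    def test_unit_trace_gives_zero(self):
        H = make_random_histogram(16, occupied_cells=40, seed=4)
        params = EntropyParams(alpha=0.5, mode="quantum",
                               rho_normalization="unit_trace")
        assert quantum_renyi(H, whole_grid(16), params) == pytest.approx(0.0)

    def test_single_full_weight_cell_zero(self):
        H = JointHistogram(counts=np.array([[3]]))
        params = EntropyParams(alpha=0.5, mode="quantum")
        rect = [DiagonalRectangle(index=1, row_range=(0, 0), col_range=(0, 0))]
        assert quantum_renyi(H, rect, params) == pytest.approx(0.0, abs=1e-12)


class TestFitness:
    def test_uniform_bounded_by_full_grid_entropy(self):
        H = make_uniform_histogram(16)
        X = ThresholdVector(rows=(5,), cols=(9,), levels=16)
        value = fitness(H, X, EntropyParams(alpha=0.5))
        assert value <= 2 * np.log(16) + 1e-12

    def test_empty_rectangle_penalized(self):
        counts = np.zeros((16, 16), dtype=int)
        counts[0, 0] = 4
        counts[15, 15] = 4  # nothing in the middle band
        H = JointHistogram(counts=counts)
        X = ThresholdVector(rows=(4, 9), cols=(4, 9), levels=16)
        params = EntropyParams(alpha=0.5, mode="quantum",
                               empty_cell_policy="occupied_only")
        assert fitness(H, X, params) == PENALTY_FITNESS
        assert fitness(H, X, EntropyParams(alpha=0.5)) == PENALTY_FITNESS

    def test_rectangle_order_irrelevant(self):
        H = make_random_histogram(32, occupied_cells=200, seed=5)
        params = EntropyParams(alpha=0.5)
        rects = partition_diagonal(32, ThresholdVector((8, 20), (9, 22), levels=32))
        total_fwd = classical_renyi(H, rects, params)
        total_rev = classical_renyi(H, rects[::-1], params)
        assert total_fwd == pytest.approx(total_rev, abs=1e-12)

    def test_deterministic(self):
        H = make_random_histogram(32, occupied_cells=100, seed=6)
        X = ThresholdVector(rows=(10,), cols=(12,), levels=32)
        params = EntropyParams(alpha=0.01, mode="quantum")
        assert fitness(H, X, params) == fitness(H, X, params)

    @pytest.mark.parametrize("mode,policy", [
        ("classical", "all_cells"),
        ("quantum", "all_cells"),
        ("quantum", "occupied_only"),
    ])
    def test_evaluator_agrees_with_direct_fitness(self, mode, policy, rng):
        H = make_random_histogram(32, occupied_cells=150, seed=8)
        params = EntropyParams(alpha=0.01, mode=mode, empty_cell_policy=policy)
        ev = FitnessEvaluator(H, params)
        for _ in range(20):
            rows = tuple(sorted(rng.choice(np.arange(1, 31), 2, replace=False)))
            cols = tuple(sorted(rng.choice(np.arange(1, 31), 2, replace=False)))
            X = ThresholdVector(rows=rows, cols=cols, levels=32)
            direct = fitness(H, X, params)
            assert ev.evaluate(X) == pytest.approx(direct, rel=1e-9, abs=1e-9)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            EntropyParams(alpha=1.0)
        with pytest.raises(ValueError):
            EntropyParams(alpha=-0.5)
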