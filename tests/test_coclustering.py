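import itertools
import math
from collections import Counter

import numpy as np
import pytest

import biradsrules as br
from biradsrules.coclustering import (
    Cocluster,
    CoclusterMiner,
    MiningParams,
    column_entropy,
    column_seeds,
    mes_score,
    mine,
    refine_cocluster,
)
from biradsrules.schema_io import minmax_normalize
from biradsrules.synthetic_data import generate, matching_rows
from conftest import make_recovery_config

LN2 = math.log(2.0)


def entropy_oracle(values):
    """Independent re-implementation: plain Python, Counter + math.log."""
    counts = Counter(values)
    r = len(values)
    return -sum((c / r) * math.log(c / r) for c in counts.values())


def mes_oracle(matrix, rows, cols):
    return sum(
        entropy_oracle([matrix[i][j] for i in rows]) for j in cols
    ) / len(cols)


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0, 0, 0, 0], 0.0),
            ([0, 1], LN2),
            ([0, 0, 0, 1], -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
        ],
    )
    def test_known_values(self, values, expected):
        assert column_entropy(values) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            column_entropy([])

    def test_matches_oracle_on_random_columns(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            col = rng.integers(0, 4, size=rng.integers(1, 30)).tolist()
            assert column_entropy(col) == pytest.approx(
                entropy_oracle(col), abs=1e-12
            )


class TestMesScore:
    def test_mean_of_column_entropies(self):
        m = np.array([[0.0, 0.0], [0.0, 1.0]])  # entropies (0, ln2)
        assert mes_score(m, [0, 1], [0, 1]) == pytest.approx(LN2 / 2)

    def test_constant_submatrix_zero(self):
        m = np.full((4, 3), 0.5)
        assert mes_score(m, range(4), range(3)) == 0.0

    def test_single_column_equals_entropy(self):
        m = np.array([[0.0], [1.0], [1.0]])
        assert mes_score(m, range(3), [0]) == pytest.approx(
            column_entropy([0.0, 1.0, 1.0])
        )

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            mes_score(np.ones((2, 2)), [], [0])


class TestColumnSeeds:
    def test_tight_group_becomes_seed(self):
        col = np.array([0, 0, 0, 0, 0, 1, 1], dtype=float).reshape(-1, 1)
        seeds = column_seeds(col, mic=0.1, min_rows=5)
        assert seeds == [(0, (0, 1, 2, 3, 4))]

    def test_spread_values_no_seed(self):
        col = np.linspace(0, 1, 5).reshape(-1, 1)  # gaps 0.25 > Mic
        assert column_seeds(col, mic=0.1, min_rows=2) == []

    def test_constant_column_one_seed_with_all_rows(self):
        col = np.zeros((8, 1))
        seeds = column_seeds(col, mic=0.1, min_rows=5)
        assert seeds == [(0, tuple(range(8)))]

    def test_matches_full_column_linkage(self):
        # clustering distinct values must equal clustering the full column
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(5)
        col = rng.choice([0.0, 0.2, 0.25, 0.8, 1.0], size=40)
        mic = 0.3
        seeds = column_seeds(col.reshape(-1, 1), mic=mic, min_rows=2)
        Z = fcluster(linkage(col.reshape(-1, 1), "complete"), mic, "distance")
        oracle_groups = {
            tuple(np.flatnonzero(Z == g))
            for g in np.unique(Z)
            if (Z == g).sum() >= 2
        }
        assert {rows for _, rows in seeds} == oracle_groups


class TestRefine:
    def test_constant_seed_emitted_unchanged(self):
        m = np.zeros((6, 3))
        cc = refine_cocluster(m, (0, range(6)), MiningParams(0.1, 0.0, 5, 3))
        assert cc is not None
        assert cc.row_indices == tuple(range(6))
        assert cc.col_indices == (0, 1, 2)
        assert cc.mes == 0.0

    def test_floor_blocks_shrinking(self):
        rng = np.random.default_rng(0)
        m = rng.random((5, 3))  # all values distinct -> high MES, cannot shrink
        cc = refine_cocluster(m, (0, range(5)), MiningParams(0.1, 0.01, 5, 3))
        assert cc is None

    def test_planted_block_recovered_from_own_columns(self, feature_index):
        # at least one of the block's own column seeds must refine to
        # exactly the planted rows x columns (mining uses all of them)
        cfg = make_recovery_config(feature_index, seed=12)
        table, gt = generate(cfg)
        norm = minmax_normalize(table)
        blk = gt[0]
        rows_true = set(matching_rows(table, blk).tolist())
        recovered = []
        for seed_col in blk.feature_indices:
            pattern_val = norm.values[blk.row_indices[0], seed_col]
            seed_rows = tuple(
                np.flatnonzero(norm.values[:, seed_col] == pattern_val).tolist()
            )
            cc = refine_cocluster(
                norm, (seed_col, seed_rows), MiningParams(0.1, 0.02, 5, 3)
            )
            if cc is not None:
                recovered.append(cc)
        assert any(
            set(cc.row_indices) == rows_true
            and set(cc.col_indices) == set(blk.feature_indices)
            for cc in recovered
        )


class TestMine:
    def test_two_planted_blocks_recovered(self, feature_index):
        cfg = make_recovery_config(feature_index, seed=0)
        table, gt = generate(cfg)
        norm = minmax_normalize(table)
        ccs = mine(norm, MiningParams(mic=0.1, delta=0.02))
        for blk in gt:
            rows_true = set(matching_rows(table, blk).tolist())
            assert any(
                set(c.row_indices) == rows_true
                and set(c.col_indices) == set(blk.feature_indices)
                for c in ccs
            )

    def test_deduplication(self, feature_index):
        cfg = make_recovery_config(feature_index, seed=0)
        table, _ = generate(cfg)
        ccs = mine(minmax_normalize(table), MiningParams(mic=0.1, delta=0.02))
        keys = [(c.row_indices, c.col_indices) for c in ccs]
        assert len(keys) == len(set(keys))

    def test_emitted_satisfy_constraints_on_noise(self):
        rng = np.random.default_rng(7)
        params = MiningParams(mic=0.1, delta=0.01)
        for _ in range(5):
            m = minmax_normalize(rng.integers(0, 3, (40, 14))).values
            for cc in mine(m, params):
                assert cc.mes <= params.delta
                assert cc.n_rows >= 5 and cc.n_cols >= 3

    def test_mes_matches_independent_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = minmax_normalize(rng.integers(0, 4, (30, 14))).values
            for cc in mine(m, MiningParams(mic=0.1, delta=0.3)):
                oracle = mes_oracle(m.tolist(), cc.row_indices, cc.col_indices)
                assert cc.mes == pytest.approx(oracle, abs=1e-12)

    def test_exhaustive_agreement_toy_scale(self):
        # on tiny matrices with relaxed floors every mined cocluster must
        # appear in the brute-force enumeration of admissible submatrices
        rng = np.random.default_rng(3)
        params = MiningParams(mic=0.1, delta=0.2, min_rows=2, min_cols=2)
        for _ in range(5):
            m = minmax_normalize(rng.integers(0, 3, (7, 4))).values
            admissible = set()
            nr, nc = m.shape
            for rows in itertools.chain.from_iterable(
                itertools.combinations(range(nr), k) for k in range(2, nr + 1)
            ):
                for cols in itertools.chain.from_iterable(
                    itertools.combinations(range(nc), k)
                    for k in range(2, nc + 1)
                ):
                    if mes_oracle(m.tolist(), rows, cols) <= params.delta:
                        admissible.add((rows, cols))
            for cc in mine(m, params):
                assert (cc.row_indices, cc.col_indices) in admissible


class TestMinerEstimator:
    def test_fit_sets_attributes(self, feature_index):
        cfg = make_recovery_config(feature_index, seed=4)
        table, _ = generate(cfg)
        miner = CoclusterMiner(delta=0.02).fit(minmax_normalize(table).values)
        assert miner.n_features_in_ == 14
        assert all(isinstance(c, Cocluster) for c in miner.coclusters_)

    def test_get_set_params(self):
        miner = CoclusterMiner()
        miner.set_params(delta=0.1)
        assert miner.get_params()["delta"] == 0.1
        with pytest.raises(ValueError):
            miner.set_params(bogus=1)


class TestGridSearch:
    def test_single_point_grid_returned(self, feature_index):
        from biradsrules.coclustering import grid_search_params

        cfg = make_recovery_config(feature_index, seed=2)
        table, _ = generate(cfg)
        params = grid_search_params(
            table, [0.1], [0.02], folds=2, seed=0, oversample=False
        )
        assert params.mic == 0.1 and params.delta == 0.02

    def test_empty_grid_rejected(self, small_table):
        from biradsrules.coclustering import grid_search_params

        with pytest.raises(ValueError):
            grid_search_params(small_table, [], [0.1])
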