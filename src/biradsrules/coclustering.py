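"""Mining column-nearly-constant coclusters under the mean entropy score.

A cocluster is a (row subset, column subset) of the normalized feature
matrix.  Quality is the mean entropy score (MES): for each selected column,
group its entries by exact value equality and take the Shannon entropy of
the group proportions (natural log); MES is the mean over the selected
columns.  A perfectly column-constant submatrix has MES 0.

Mining proceeds in three steps:

1. seed: 1-D agglomerative clustering (complete linkage, cut at the maximum
   intra-cluster distance Mic) of each feature column; each group of at
   least ``min_rows`` rows seeds a cocluster;
2. expand: each seed's rows paired with *all* feature columns form the
   starting submatrix;
3. refine: greedily delete the single row or column whose removal lowers
   MES the most, until MES <= delta (emit) or the size floor (5 rows x 3
   columns by default) blocks further deletion (discard).

Exact-equality grouping is used inside the entropy rather than re-running
distance-based clustering per column: the features are discrete and min-max
scaling preserves discreteness, so equality grouping is the deterministic
limit of any sufficiently fine cut and keeps the score independent of
cluster geometry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .schema_io import NormalizedMatrix

__all__ = [
    "Cocluster",
    "MiningParams",
    "column_entropy",
    "mes_score",
    "column_seeds",
    "refine_cocluster",
    "mine",
    "CoclusterMiner",
    "grid_search_params",
]


@dataclass(frozen=True)
class Cocluster:
    """An emitted (rows x columns) submatrix with its mean entropy score."""

    row_indices: tuple[int, ...]
    col_indices: tuple[int, ...]
    mes: float

    @property
    def n_rows(self) -> int:
        return len(self.row_indices)

    @property
    def n_cols(self) -> int:
        return len(self.col_indices)


@dataclass(frozen=True)
class MiningParams:
    """Mining controls: seed cut height Mic, MES ceiling delta, size floors."""

    mic: float = 0.1
    delta: float = 0.05
    min_rows: int = 5
    min_cols: int = 3

    def __post_init__(self) -> None:
        if self.mic <= 0:
            raise ValueError("Mic must be positive")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.min_rows < 1 or self.min_cols < 1:
            raise ValueError("size floors must be >= 1")


def _entropy_from_counts(counts: np.ndarray) -> float:
    r = counts.sum()
    if r == 0:
        raise ValueError("empty column")
    p = counts / r
    p = p[p > 0]
    return float(max(0.0, -(p * np.log(p)).sum()))


def column_entropy(values: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (nats) of a column's exact-value group proportions."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty column")
    _, counts = np.unique(values, return_counts=True)
    return _entropy_from_counts(counts)


def mes_score(
    norm: NormalizedMatrix | np.ndarray,
    rows: Iterable[int],
    cols: Iterable[int],
) -> float:
    """Mean of :func:`column_entropy` over the selected columns."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    rows = np.asarray(list(rows))
    cols = np.asarray(list(cols))
    if rows.size == 0 or cols.size == 0:
        raise ValueError("empty row or column selection")
    sub = values[np.ix_(rows, cols)]
    return float(np.mean([column_entropy(sub[:, j]) for j in range(sub.shape[1])]))


def column_seeds(
    norm: NormalizedMatrix | np.ndarray,
    mic: float,
    min_rows: int = 5,
) -> list[tuple[int, tuple[int, ...]]]:
    """Seed coclusters by 1-D AHC of each feature column.

    Complete linkage is cut at height ``mic`` (so each flat group has
    diameter <= mic); groups of at least ``min_rows`` rows become seeds.
    The linkage is computed on the column's distinct values — the diameter
    criterion does not depend on multiplicities — and mapped back to rows.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    if mic <= 0:
        raise ValueError("Mic must be positive")
    seeds: list[tuple[int, tuple[int, ...]]] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        uniq, inverse = np.unique(col, return_inverse=True)
        if uniq.size == 1:
            groups = np.zeros(uniq.size, dtype=int)
        else:
            Z = linkage(uniq.reshape(-1, 1), method="complete")
            groups = fcluster(Z, t=mic, criterion="distance")
        for g in np.unique(groups):
            rows = np.flatnonzero(np.isin(inverse, np.flatnonzero(groups == g)))
            if rows.size >= min_rows:
                seeds.append((j, tuple(int(i) for i in rows)))
    return seeds


class _Submatrix:
    """Mutable view used by the greedy refinement; tracks per-column entropies."""

    def __init__(self, values: np.ndarray, rows: np.ndarray, cols: np.ndarray):
        self.values = values
        self.rows = np.asarray(rows, dtype=int)
        self.cols = np.asarray(cols, dtype=int)

    @property
    def r(self) -> int:
        return self.rows.size

    @property
    def c(self) -> int:
        return self.cols.size

    def column_stats(self):
        """Per kept column: (entropy, entropy-after-removing-row_i array)."""
        sub = self.values[np.ix_(self.rows, self.cols)]
        r = self.r
        entropies = np.empty(self.c)
        # entropy after deleting each row, per column
        e_minus = np.empty((r, self.c)) if r > 1 else None
        for cj in range(self.c):
            uniq, inverse, counts = np.unique(
                sub[:, cj], return_inverse=True, return_counts=True
            )
            # e = log r - (1/r) * sum n_i log n_i
            nlogn = counts * np.log(counts)
            S = nlogn.sum()
            entropies[cj] = max(0.0, np.log(r) - S / r)
            if r > 1:
                n_v = counts.astype(float)
                new_term = (n_v - 1) * np.log(np.maximum(n_v - 1, 1.0))
                e_after = np.maximum(
                    0.0, np.log(r - 1) - (S - nlogn + new_term) / (r - 1)
                )
                e_minus[:, cj] = e_after[inverse]
        return entropies, e_minus


def refine_cocluster(
    norm: NormalizedMatrix | np.ndarray,
    seed: tuple[int, Iterable[int]],
    params: MiningParams,
) -> Cocluster | None:
    """Expand a (column, row-set) seed to all columns, then greedily shrink.

    Each step evaluates every single-row and single-column deletion that
    respects the size floors and applies the one minimizing the resulting
    MES (ties: rows before columns, then lowest index).  Emits when
    MES <= delta; returns ``None`` if the floors block further progress.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    _, seed_rows = seed
    rows = np.asarray(sorted(seed_rows), dtype=int)
    cols = np.arange(values.shape[1])
    if rows.size < params.min_rows or cols.size < params.min_cols:
        return None
    sm = _Submatrix(values, rows, cols)

    while True:
        entropies, e_minus = sm.column_stats()
        mes = float(entropies.mean())
        if mes <= params.delta:
            return Cocluster(
                tuple(int(i) for i in sm.rows),
                tuple(int(j) for j in sm.cols),
                mes,
            )
        best = None  # (mes_after, kind, position)
        if sm.r > params.min_rows and e_minus is not None:
            row_mes = e_minus.mean(axis=1)
            i = int(np.argmin(row_mes))
            best = (float(row_mes[i]), 0, i)
        if sm.c > params.min_cols:
            total = entropies.sum()
            col_mes = (total - entropies) / (sm.c - 1)
            j = int(np.argmin(col_mes))
            cand = (float(col_mes[j]), 1, j)
            # strict '<' keeps the row-deletion preference on ties
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            return None
        _, kind, pos = best
        if kind == 0:
            sm.rows = np.delete(sm.rows, pos)
        else:
            sm.cols = np.delete(sm.cols, pos)


def mine(
    norm: NormalizedMatrix | np.ndarray,
    params: MiningParams | None = None,
) -> list[Cocluster]:
    """Run seeding and refinement over every column; deduplicate results."""
    params = params or MiningParams()
    seeds = column_seeds(norm, params.mic, params.min_rows)
    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    out: list[Cocluster] = []
    for seed in seeds:
        cc = refine_cocluster(norm, seed, params)
        if cc is None:
            continue
        key = (cc.row_indices, cc.col_indices)
        if key not in seen:
            seen.add(key)
            out.append(cc)
    return out


class CoclusterMiner:
    """Estimator-style wrapper: ``fit(X)`` mines coclusters of ``X``.

    Parameters mirror :class:`MiningParams`.  ``X`` is expected to be a
    min-max normalized feature matrix (see ``schema_io.minmax_normalize``);
    after ``fit`` the results are in ``coclusters_``.
    """

    def __init__(
        self,
        mic: float = 0.1,
        delta: float = 0.05,
        min_rows: int = 5,
        min_cols: int = 3,
    ):
        self.mic = mic
        self.delta = delta
        self.min_rows = min_rows
        self.min_cols = min_cols

    def get_params(self, deep: bool = True) -> dict:
        return {
            "mic": self.mic,
            "delta": self.delta,
            "min_rows": self.min_rows,
            "min_cols": self.min_cols,
        }

    def set_params(self, **params) -> "CoclusterMiner":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _mining_params(self) -> MiningParams:
        return MiningParams(self.mic, self.delta, self.min_rows, self.min_cols)

    def fit(self, X: np.ndarray, y=None) -> "CoclusterMiner":
        X = np.asarray(X, dtype=float)
        self.coclusters_ = mine(X, self._mining_params())
        self.n_features_in_ = X.shape[1]
        return self


def grid_search_params(
    train,
    mic_grid: Sequence[float],
    delta_grid: Sequence[float],
    folds: int = 3,
    seed: int = 0,
    **classifier_params,
):
    """Pick (Mic, delta) by cross-validated accuracy of the full pipeline.

    Every grid pair is scored with a stratified ``folds``-fold CV of the
    boosted rule classifier on ``train`` (a SampleTable); a pair that mines
    no usable rules falls back to majority-class prediction for scoring.
    Ties break toward smaller delta, then smaller Mic.  Returns the winning
    :class:`MiningParams`.
    """
    from .evaluation import cross_validate
    from .model import IsccadClassifier

    if not mic_grid or not delta_grid:
        raise ValueError("empty parameter grid")
    best: tuple[float, float, float] | None = None  # (-acc, delta, mic)
    best_params: MiningParams | None = None
    for mic, delta in itertools.product(mic_grid, delta_grid):
        clf = IsccadClassifier(
            mic=mic, delta=delta, fallback="majority",
            random_state=seed, **classifier_params,
        )
        metrics = cross_validate(train, folds=folds, estimator=clf, seed=seed)
        acc = float(np.mean([m.accuracy for m in metrics]))
        key = (-acc, delta, mic)
        if best is None or key < best:
            best = key
            best_params = MiningParams(mic=mic, delta=delta)
    assert best_params is not None
    return best_params
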