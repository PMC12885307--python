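"""Discrete-safe minority oversampling (an improved SMOTE).

Classic SMOTE interpolates linearly between minority neighbours, which
produces values that do not exist on a discrete scoring scale.  Here the
*whole* input space (both classes) is first clustered with affinity
propagation; only "safe" clusters — those where minority samples strictly
outnumber majority ones — host synthesis.  Each synthetic sample copies,
feature by feature, the modal value among its seed sample's k nearest
in-cluster minority neighbours, so every generated value already occurs in
a real minority sample of the same cluster (a closed-world guarantee).

The amount generated is governed by the ratio r = (Nmaj - Nmin) / Ncsmin,
where Ncsmin is the minority total inside safe clusters; each safe cluster
with n minority members contributes round(n * r) rows, restoring balance up
to per-cluster rounding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .schema_io import NormalizedMatrix, SampleTable, minmax_normalize

__all__ = [
    "ClusterPartition",
    "OversampleReport",
    "cluster_input_space",
    "select_safe_clusters",
    "generating_ratio",
    "synthesize_minority",
    "DiscreteSMOTE",
]

logger = logging.getLogger(__name__)


class NoSafeClusterError(RuntimeError):
    """Raised when balance is requested but no cluster is minority-dominated."""


@dataclass
class ClusterPartition:
    """A partition of all rows plus the safe-cluster bookkeeping."""

    assignments: np.ndarray
    clusters: list[np.ndarray]
    safe_indices: tuple[int, ...] = ()
    n_maj: int = 0
    n_min: int = 0
    n_csmin: int = 0

    @property
    def safe_clusters(self) -> list[np.ndarray]:
        return [self.clusters[i] for i in self.safe_indices]


@dataclass
class OversampleReport:
    """What a resampling run produced, for logging and leakage checks."""

    ratio_r: float
    per_cluster_generated: dict[int, int] = field(default_factory=dict)
    synthetic_values: np.ndarray | None = None
    provenance: list[int] = field(default_factory=list)  # seed row per synthetic row

    @property
    def n_generated(self) -> int:
        return 0 if self.synthetic_values is None else self.synthetic_values.shape[0]


def cluster_input_space(
    norm: NormalizedMatrix | np.ndarray,
    damping: float = 0.9,
    preference: float | None = None,
    max_iter: int = 1000,
    random_state: int | None = 0,
) -> ClusterPartition:
    """Cluster every sample (labels excluded) with affinity propagation.

    The similarity is the negative squared Euclidean distance on the
    normalized features; the number of clusters is not predetermined.  If
    the message passing fails to converge, one retry at higher damping is
    attempted, then all rows fall into a single cluster with a warning.
    """
    X = norm.values if isinstance(norm, NormalizedMatrix) else np.asarray(norm)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")

    labels = None
    for attempt, (dmp, iters) in enumerate(
        [(damping, max_iter), (min(0.99, damping + 0.05), 2 * max_iter)]
    ):
        ap = AffinityPropagation(
            damping=dmp,
            preference=preference,
            max_iter=iters,
            random_state=random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap.fit(X)
        if ap.cluster_centers_indices_ is not None and len(
            np.atleast_1d(ap.cluster_centers_indices_)
        ):
            labels = ap.labels_
            if attempt > 0:
                logger.warning(
                    "affinity propagation converged only after damping retry"
                )
            break
    if labels is None or (np.asarray(labels) < 0).any():
        logger.warning(
            "affinity propagation did not converge; falling back to a single cluster"
        )
        labels = np.zeros(X.shape[0], dtype=int)

    labels = np.asarray(labels)
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    return ClusterPartition(assignments=labels, clusters=clusters)


def select_safe_clusters(part: ClusterPartition, labels: np.ndarray) -> ClusterPartition:
    """Keep clusters where minority strictly outnumbers majority members."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size == 1:
        minority = classes[0]
        n_min = n_maj = int(counts[0])
        n_maj = 0
    else:
        minority = classes[np.argmin(counts)]
        n_min = int(counts.min())
        n_maj = int(counts.max())
    safe = []
    n_csmin = 0
    for i, rows in enumerate(part.clusters):
        cl = labels[rows]
        k_min = int((cl == minority).sum())
        k_maj = rows.size - k_min
        if k_min > k_maj:
            safe.append(i)
            n_csmin += k_min
    part.safe_indices = tuple(safe)
    part.n_maj = n_maj
    part.n_min = n_min
    part.n_csmin = n_csmin
    return part


def generating_ratio(part: ClusterPartition) -> float:
    """r = (Nmaj - Nmin) / Ncsmin, the per-minority-sample generation rate."""
    if part.n_maj <= part.n_min:
        return 0.0
    if part.n_csmin == 0:
        raise NoSafeClusterError("no safe clusters: cannot oversample")
    return (part.n_maj - part.n_min) / part.n_csmin


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def synthesize_minority(
    table: SampleTable,
    part: ClusterPartition,
    r: float,
    k: int = 5,
    seed: int = 0,
    norm: NormalizedMatrix | None = None,
) -> OversampleReport:
    """Generate round(n*r) synthetic minority rows per safe cluster.

    Each synthetic row starts from a randomly drawn minority seed of the
    cluster; for every feature it copies the modal value among the seed's
    ``k`` nearest in-cluster minority neighbours (Euclidean distance on
    normalized features; ties go to the value held by the nearest
    neighbour).  A cluster with a lone minority member contributes copies
    of that member.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if r < 0:
        raise ValueError("generating ratio must be >= 0")
    labels = table.labels
    classes, counts = np.unique(labels, return_counts=True)
    minority = classes[np.argmin(counts)] if classes.size > 1 else classes[0]
    norm = norm or minmax_normalize(table)
    rng = np.random.default_rng(seed)

    synth_rows: list[np.ndarray] = []
    provenance: list[int] = []
    per_cluster: dict[int, int] = {}
    for ci in part.safe_indices:
        rows = part.clusters[ci]
        minority_rows = rows[labels[rows] == minority]
        n = minority_rows.size
        g = _round_half_up(n * r)
        per_cluster[int(ci)] = g
        if g == 0 or n == 0:
            continue
        seeds = rng.choice(minority_rows, size=g, replace=g > n)
        X = norm.values[minority_rows]
        # pairwise distances within the cluster's minority members
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        pos = {int(row): p for p, row in enumerate(minority_rows)}
        for s in seeds:
            p = pos[int(s)]
            if n == 1:
                synth_rows.append(table.values[s].copy())
                provenance.append(int(s))
                continue
            order = np.argsort(d2[p], kind="stable")
            neigh = [q for q in order if q != p][:k]
            neigh_vals = table.values[minority_rows[neigh]]  # (k', F)
            row = np.empty(table.values.shape[1], dtype=np.int64)
            for f in range(row.size):
                col = neigh_vals[:, f]
                vals, cnts = np.unique(col, return_counts=True)
                top = vals[cnts == cnts.max()]
                if top.size == 1:
                    row[f] = top[0]
                else:
                    # tie: take the tied value held by the nearest neighbour
                    for q in range(len(neigh)):
                        if col[q] in top:
                            row[f] = col[q]
                            break
            synth_rows.append(row)
            provenance.append(int(s))

    synthetic = (
        np.vstack(synth_rows) if synth_rows else np.empty((0, table.values.shape[1]), int)
    )
    return OversampleReport(
        ratio_r=float(r),
        per_cluster_generated=per_cluster,
        synthetic_values=synthetic,
        provenance=provenance,
    )


class DiscreteSMOTE:
    """Resampler: balance a discrete table by modal-value minority synthesis.

    Estimator-style interface in the imblearn tradition:
    ``fit_resample(X, y)`` returns the augmented ``(X, y)`` with synthetic
    minority rows appended.  The run's bookkeeping (ratio, per-cluster
    counts, seed-row provenance) lands in ``report_``.
    """

    def __init__(
        self,
        k_neighbors: int = 5,
        damping: float = 0.9,
        preference: float | None = None,
        max_iter: int = 1000,
        random_state: int | None = 0,
    ):
        self.k_neighbors = k_neighbors
        self.damping = damping
        self.preference = preference
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k_neighbors": self.k_neighbors,
            "damping": self.damping,
            "preference": self.preference,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "DiscreteSMOTE":
        for key, v in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit_resample(self, X: np.ndarray, y: np.ndarray, schema=None):
        from .schema_io import default_schema

        X = np.asarray(X)
        y = np.asarray(y)
        table = SampleTable(X, y, schema or default_schema())
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2 or counts.min() == counts.max():
            self.report_ = OversampleReport(ratio_r=0.0)
            self.partition_ = None
            return X, y
        norm = minmax_normalize(table)
        part = cluster_input_space(
            norm,
            damping=self.damping,
            preference=self.preference,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        part = select_safe_clusters(part, y)
        if part.n_csmin == 0:
            logger.warning("no safe clusters found; returning data unchanged")
            self.report_ = OversampleReport(ratio_r=0.0)
            self.partition_ = part
            return X, y
        r = generating_ratio(part)
        seed = self.random_state if self.random_state is not None else 0
        report = synthesize_minority(table, part, r, k=self.k_neighbors, seed=seed, norm=norm)
        self.report_ = report
        self.partition_ = part
        minority = classes[np.argmin(counts)]
        X_out = np.vstack([X, report.synthetic_values])
        y_out = np.concatenate(
            [y, np.full(report.n_generated, minority, dtype=y.dtype)]
        )
        return X_out, y_out
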