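"""PAM (k-medoids) clustering of androgen-responsive clones.

Classical deterministic BUILD + SWAP: BUILD seeds medoids greedily (the first
minimizes total distance, each next minimizes marginal cost), SWAP repeatedly
applies the best strictly cost-reducing (medoid, non-medoid) exchange.  Ties
are always broken toward the lowest row index, so the result is a pure
function of the input order.

Also provides the heatmap row standardization, the semantic labelling of the
four response clusters (1 down, 2 up at day 7, 3 up at day 14, 4 down-then-up)
and per-cluster fold-change summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, InvalidConfigError

logger = logging.getLogger(__name__)

CLUSTER_LABEL_MEANING = {
    1: "down",
    2: "up at day 7",
    3: "up at day 14",
    4: "down d7 / up d14",
}


@dataclass
class ClusterModel:
    """k-medoids partition of the responsive clones."""

    k: int
    medoids: list[int]  # row indices into the clustered matrix
    assignment: np.ndarray  # row -> cluster id (0..k-1)
    total_cost: float
    clone_ids: list | None = None
    labels: dict[int, int] = field(default_factory=dict)  # cluster id -> semantic label 1..4

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster)


def _total_cost(dist: np.ndarray, medoids: list[int]) -> tuple[float, np.ndarray]:
    sub = dist[:, medoids]
    assign = sub.argmin(axis=1)
    return float(sub.min(axis=1).sum()), assign


def _build(dist: np.ndarray, k: int, first: int | None = None) -> list[int]:
    """Greedy BUILD: the first medoid minimizes total distance (unless forced),
    each next minimizes the marginal cost; ties break to the lowest index."""
    medoids: list[int] = [int(dist.sum(axis=1).argmin()) if first is None else first]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.minimum(dist, current[:, None]).sum(axis=0)
        gains[medoids] = np.inf
        medoids.append(int(gains.argmin()))
    return medoids


def _swap(dist: np.ndarray, medoids: list[int]) -> tuple[list[int], float, np.ndarray]:
    """Steepest-descent SWAP: apply the best strictly cost-reducing
    (medoid, non-medoid) exchange until none exists."""
    n = dist.shape[0]
    cost, assign = _total_cost(dist, medoids)
    while True:
        best = (0.0, None)  # (delta, (position in medoids, new medoid))
        for mi, m in enumerate(medoids):
            trial = list(medoids)
            for h in range(n):
                if h in medoids:
                    continue
                trial[mi] = h
                new_cost, _ = _total_cost(dist, trial)
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
            trial[mi] = m
        if best[1] is None:
            return medoids, cost, assign
        mi, h = best[1]
        medoids[mi] = h
        cost, assign = _total_cost(dist, medoids)


#: below this size every point seeds a BUILD restart (SWAP alone is a local
#: search and can miss the optimum on tiny inputs)
MULTISTART_MAX_N = 60


def pam_cluster(
    rows: np.ndarray | pd.DataFrame, k: int = 4, n_starts: int | str = "auto"
) -> ClusterModel:
    """Partition rows into k clusters around medoids (Euclidean distance).

    Deterministic BUILD + SWAP.  Because SWAP is a steepest-descent local
    search, small inputs additionally restart BUILD from every point as the
    forced first medoid and keep the cheapest converged solution
    (``n_starts="auto"``: all-point restarts for n <= 60, a single greedy
    BUILD otherwise; an integer forces that many restarts).
    """
    clone_ids = list(rows.index) if isinstance(rows, pd.DataFrame) else None
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise InvalidConfigError("k must be >= 1")
    if n < k:
        raise InvalidConfigError(f"need at least k={k} rows, got {n}")
    dist = cdist(X, X)

    if n_starts == "auto":
        starts = n if n <= MULTISTART_MAX_N else 1
    else:
        starts = max(1, min(int(n_starts), n))
    firsts: list[int | None] = [None] if starts == 1 else list(range(starts))
    best: tuple[float, list[int], np.ndarray] | None = None
    for first in firsts:
        medoids, cost, assign = _swap(dist, _build(dist, k, first=first))
        if best is None or cost < best[0] - 1e-12:
            best = (cost, medoids, assign)
    cost, medoids, assign = best
    return ClusterModel(k=k, medoids=medoids, assignment=assign, total_cost=cost, clone_ids=clone_ids)


def standardize_rows(m: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Heatmap standardization: (value - row mean) / row sample-sd.

    Constant rows map to all zeros.
    """
    arr = np.asarray(m, dtype=float)
    if arr.shape[1] < 2:
        raise InvalidConfigError("rows need at least 2 values")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (arr - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    return out


def _sign_pattern_label(fc7: float, fc14: float) -> tuple[int, bool]:
    """Map a (day-7, day-14) mean fold-change pair to a semantic label.

    Returns (label, matched); unmatched patterns fall back to the nearest
    pattern by sign agreement, ties broken toward the time point with the
    larger |log2 FC|.
    """
    up7, up14 = fc7 > 1.0, fc14 > 1.0
    if not up7 and not up14:
        return 1, True
    if up7 and up14:
        return (2 if fc7 >= fc14 else 3), True
    if not up7 and up14:
        return 4, True
    # (+, -): no archetype; lean on the dominant time point
    if abs(np.log2(fc7)) >= abs(np.log2(fc14)):
        return 2, False
    return 1, False


def label_clusters(
    model: ClusterModel,
    fold_changes: pd.DataFrame,
    day7_col: str = "T2d7",
    day14_col: str = "T2d14",
) -> ClusterModel:
    """Assign semantic labels 1-4 from each cluster's mean fold-change pattern.

    ``fold_changes`` holds per-clone unlogged fold changes vs control, indexed
    like the clustered rows, with one column per treated group.
    """
    if model.k != 4:
        logger.warning("label_clusters designed for k=4, got k=%d", model.k)
    fc = fold_changes[[day7_col, day14_col]].to_numpy(dtype=float)
    for c in range(model.k):
        rows = model.members(c)
        mean7, mean14 = fc[rows, 0].mean(), fc[rows, 1].mean()
        label, matched = _sign_pattern_label(mean7, mean14)
        if not matched:
            logger.warning(
                "cluster %d: unmatched sign pattern (FC d7=%.3g, d14=%.3g), nearest label %d",
                c, mean7, mean14, label,
            )
        model.labels[c] = label
    if len(set(model.labels.values())) < model.k:
        logger.warning("duplicate semantic labels among clusters: %s", model.labels)
    return model


def cluster_fold_changes(
    group_means: pd.DataFrame,
    assignment: pd.Series,
    control: str = "control",
) -> pd.DataFrame:
    """Per-cluster mean fold change to control +/- SEM, per treated group.

    ``group_means`` are unlogged per-clone per-group means.  Per clone,
    FC = treated mean / control mean; per cluster, the arithmetic mean and the
    standard error over member clones.
    """
    if control not in group_means.columns:
        raise InvalidConfigError(f"control group {control!r} not in group means")
    ctrl = group_means[control]
    if (ctrl <= 0).any():
        bad = ctrl.index[(ctrl <= 0).to_numpy()][0]
        raise DegenerateInputError(f"non-positive control mean for clone {bad!r}")
    fc = group_means.div(ctrl, axis=0)
    assignment = assignment.loc[group_means.index]
    records = []
    for cluster, block in fc.groupby(assignment):
        n = len(block)
        for g in group_means.columns:
            vals = block[g].to_numpy()
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            records.append({"cluster": cluster, "group": g, "mean_fc": float(vals.mean()),
                            "sem": sem, "n": n})
    return pd.DataFrame.from_records(records).set_index(["cluster", "group"])
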