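"""Multivariate catch-composition analyses.

Species abundance/biomass tables (samples x species) are
Hellinger-transformed — square root of the row-normalised profile — so
Euclidean-geometry methods behave sensibly on composition data.  On the
transformed table:

* PCA summarises between-sample similarity (used to check that the few
  sampled boats are representative of the fleet, via per-boat centroids
  and convex hulls of trip scores);
* redundancy analysis (RDA) on a gear-type factor measures how much
  composition variance the gear explains, with significance from a free
  permutation of rows (the group structure is deliberately ignored at
  this step);
* a lag-1 within-net autocorrelation check tests whether consecutive
  netting walls can be treated as exchangeable sample units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OrdinationResult",
    "RDAResult",
    "hellinger",
    "pca",
    "boat_summary",
    "rda",
    "rda_permutation_test",
    "lag1_autocorrelation_test",
]


def hellinger(matrix) -> np.ndarray:
    """Hellinger transform: h_ij = sqrt(y_ij / row_total_i).

    Accepts any nonnegative 2-D array-like (a DataFrame passes through
    with labels preserved).  All-zero rows map to all-zero rows.
    Non-zero output rows have unit Euclidean norm.
    """
    import pandas as pd

    is_df = isinstance(matrix, pd.DataFrame)
    arr = np.asarray(matrix, dtype=float)
    if np.any(arr < 0):
        raise ValueError("species matrix must be nonnegative")
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0), 0.0))
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


@dataclass(frozen=True)
class OrdinationResult:
    """PCA scores, eigenvalues and variance proportions."""

    scores: np.ndarray            # samples x axes
    eigenvalues: np.ndarray       # nonincreasing, >= 0
    proportion_explained: np.ndarray
    loadings: np.ndarray          # species x axes
    sample_ids: list | None = None


def pca(matrix, center: bool = True, sample_ids: Sequence | None = None
        ) -> OrdinationResult:
    """Principal component analysis by SVD of the (centered) matrix.

    Eigenvalues are squared singular values / (n - 1) (sample-variance
    normalisation); scores live in sample space (U * s).  Axis signs
    are fixed by making the largest-magnitude loading of each axis
    positive, so score files are reproducible.
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n = arr.shape[0]
    centered = arr - arr.mean(axis=0) if center else arr.copy()
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = min(n - 1, arr.shape[1]) if center else min(arr.shape)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # deterministic axis orientation
    for k in range(rank):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    prop = eig / total if total > 0 else np.zeros_like(eig)
    return OrdinationResult(
        scores=u * s, eigenvalues=eig, proportion_explained=prop,
        loadings=vt.T, sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def boat_summary(result: OrdinationResult, groups: Mapping) -> dict:
    """Per-group centroid and convex hull of scores on axes 1-2.

    ``groups`` maps each sample id (or row index when the result has no
    ids) to a group label, e.g. trips to boats.  Returns
    ``{group: {"centroid": (2,), "hull": (k, 2)}}``; hulls of one or
    two points (or collinear sets) degenerate to the unique points.
    """
    ids = result.sample_ids if result.sample_ids is not None else list(range(len(result.scores)))
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValueError(f"samples without a group: {missing[:5]}")
    xy = result.scores[:, :2]
    by_group: dict = {}
    for row, sid in zip(xy, ids):
        by_group.setdefault(groups[sid], []).append(row)
    out = {}
    for g, rows in by_group.items():
        pts = np.asarray(rows)
        out[g] = {"centroid": pts.mean(axis=0), "hull": _hull(pts)}
    return out


def _hull(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    uniq = np.unique(pts, axis=0)
    if len(uniq) <= 2:
        return uniq
    try:
        h = ConvexHull(uniq)
    except QhullError:  # collinear points
        return uniq
    return uniq[h.vertices]


@dataclass(frozen=True)
class RDAResult:
    """Variance decomposition of composition onto a factor."""

    constrained_variance: float
    residual_variance: float
    df1: int
    df2: int
    F: float
    p_perm: float | None = None
    n_perm: int | None = None

    @property
    def total_variance(self) -> float:
        return self.constrained_variance + self.residual_variance


def rda(Y, factor: Sequence) -> RDAResult:
    """Redundancy analysis of Y on a single categorical factor.

    Projects the column-centered response onto the factor's indicator
    space; constrained variance is the variance of the fitted values,
    residual variance the remainder (both on the n-1 denominator, so
    they sum to the total PCA variance of Y).  The pseudo-F statistic is
    (SS_constrained / df1) / (SS_residual / df2) with df1 = levels - 1
    and df2 = n - levels.
    """
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    labels = list(factor)
    n = arr.shape[0]
    if len(labels) != n:
        raise ValueError("factor length must match rows of Y")
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")
    df1 = len(levels) - 1
    df2 = n - len(levels)
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    yc = arr - arr.mean(axis=0)
    fitted = np.empty_like(yc)
    for lev in levels:
        sel = np.array([lab == lev for lab in labels])
        fitted[sel] = yc[sel].mean(axis=0)
    ss_con = float((fitted ** 2).sum())
    ss_res = float(((yc - fitted) ** 2).sum())
    f_stat = (ss_con / df1) / (ss_res / df2) if ss_res > 0 else np.inf
    return RDAResult(
        constrained_variance=ss_con / (n - 1),
        residual_variance=ss_res / (n - 1),
        df1=df1, df2=df2, F=float(f_stat),
    )


def rda_permutation_test(Y, factor: Sequence, n_perm: int = 1000,
                         seed: int = 0) -> RDAResult:
    """Permutation test of the RDA pseudo-F.

    Rows are permuted freely against the factor labels; the p-value
    follows the add-one rule p = (1 + #{F* >= F}) / (n_perm + 1), so
    the smallest attainable p with 999 permutations is 1/1000.
    Degenerate responses with zero total variance give p = 1 with a
    warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    observed = rda(arr, factor)
    if observed.total_variance <= 0:
        warnings.warn("zero total variance; permutation test degenerate", stacklevel=2)
        return RDAResult(**{**observed.__dict__, "p_perm": 1.0, "n_perm": n_perm})
    rng = np.random.default_rng(seed)
    labels = np.asarray(list(factor))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        if rda(arr, labels[perm]).F >= observed.F:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return RDAResult(
        constrained_variance=observed.constrained_variance,
        residual_variance=observed.residual_variance,
        df1=observed.df1, df2=observed.df2, F=observed.F,
        p_perm=p, n_perm=n_perm,
    )


def lag1_autocorrelation_test(values_by_net: Mapping[str, Sequence[float]],
                              n_perm: int = 999, seed: int = 0
                              ) -> tuple[float, float]:
    """Pooled lag-1 autocorrelation between consecutive walls within nets.

    ``values_by_net`` maps each net to its per-wall amounts ordered by
    wall position.  The statistic is the Pearson correlation over all
    within-net consecutive pairs (nets with < 3 walls are ignored); the
    null distribution permutes wall order independently within each
    net, and the two-sided p-value uses the add-one rule.  A constant
    series (undefined correlation) returns (nan, 1.0) with a warning.
    """
    series = [np.asarray(v, dtype=float) for v in values_by_net.values()
              if len(v) >= 3]
    if not series:
        raise ValueError("no net with >= 3 walls")

    def pooled_r(parts: list[np.ndarray]) -> float:
        a = np.concatenate([p[:-1] for p in parts])
        b = np.concatenate([p[1:] for p in parts])
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    observed = pooled_r(series)
    if not np.isfinite(observed):
        warnings.warn("constant series; lag-1 correlation undefined", stacklevel=2)
        return float("nan"), 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        shuffled = [s[rng.permutation(len(s))] for s in series]
        r = pooled_r(shuffled)
        if np.isfinite(r) and abs(r) >= abs(observed):
            exceed += 1
    return observed, (1 + exceed) / (n_perm + 1)
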