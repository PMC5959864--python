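"""Feature standardization, PCA reduction and Kennard-Stone partitioning.

All three steps operate on a "feature table": a DataFrame carrying the 15
canonical feature columns plus ``sample_id`` and ``moisture``.  The
standardizer and PCA projection are fitted objects so they can be learned
on the calibration rows only and replayed on prediction rows without
leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA as _SkPCA

from .features import FEATURE_NAMES


def feature_matrix(table: pd.DataFrame,
                   features: tuple[str, ...] = FEATURE_NAMES) -> np.ndarray:
    """Extract the (n, p) float matrix, erroring on missing columns or NaNs."""
    missing = [c for c in features if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    X = table.loc[:, list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return X


@dataclass
class Standardizer:
    """Per-feature location/scale learned from a calibration table."""

    means: np.ndarray
    sds: np.ndarray
    feature_names: tuple[str, ...]
    ddof: int = 1


def zscore_fit(table: pd.DataFrame,
               features: tuple[str, ...] = FEATURE_NAMES,
               ddof: int = 1) -> Standardizer:
    """Learn per-feature mean and standard deviation (``ddof=1`` by default).

    A zero-variance feature is rejected by name: it carries no information
    and would make the transform ill-defined.
    """
    X = feature_matrix(table, features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    zero = [features[j] for j in np.flatnonzero(sds == 0)]
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    return Standardizer(means=means, sds=sds, feature_names=tuple(features), ddof=ddof)


def zscore_apply(std: Standardizer, table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the table with the fitted features standardized."""
    X = feature_matrix(table, std.feature_names)
    Z = (X - std.means) / std.sds
    out = table.copy()
    out.loc[:, list(std.feature_names)] = Z
    return out


@dataclass
class PCAProjection:
    """Orthonormal loadings with the centering offset of the fit table."""

    loadings: np.ndarray  # (n_components, p)
    mean: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_fit(table: pd.DataFrame, n_components: int = 10,
            features: tuple[str, ...] = FEATURE_NAMES) -> PCAProjection:
    """Principal components of the (standardized) feature table."""
    X = feature_matrix(table, features)
    p = X.shape[1]
    if not (1 <= n_components <= p):
        raise ValueError(f"n_components must be in [1, {p}], got {n_components}")
    sk = _SkPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    return PCAProjection(
        loadings=sk.components_,
        mean=sk.mean_,
        explained_variance=sk.explained_variance_,
        explained_variance_ratio=sk.explained_variance_ratio_,
        feature_names=tuple(features),
    )


def pca_apply(proj: PCAProjection, table: pd.DataFrame) -> np.ndarray:
    """Score matrix (n, n_components) of a table under a fitted projection."""
    X = feature_matrix(table, proj.feature_names)
    return (X - proj.mean) @ proj.loadings.T


@dataclass
class SplitResult:
    """Calibration/prediction index partition (positional indices)."""

    calibration: np.ndarray
    prediction: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration, dtype=int)
        pred = np.asarray(self.prediction, dtype=int)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")
        self.calibration = cal
        self.prediction = pred

    @property
    def n_calibration(self) -> int:
        return len(self.calibration)

    def to_frame(self, sample_ids) -> pd.DataFrame:
        ids = np.asarray(sample_ids)
        rows = [(ids[i], "calibration") for i in sorted(self.calibration)]
        rows += [(ids[i], "prediction") for i in sorted(self.prediction)]
        return pd.DataFrame(rows, columns=["sample_id", "set"])


def _whiten_mahalanobis(X: np.ndarray, regularize: bool) -> np.ndarray:
    """Transform so Euclidean distance equals Mahalanobis distance.

    Uses the covariance of the full matrix; a small ridge
    (1e-8 * trace / p) is added when the condition number exceeds 1e12.
    """
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    p = C.shape[0]
    cond = np.linalg.cond(C)
    if cond > 1e12 or not np.isfinite(cond):
        if not regularize:
            raise ValueError(
                "feature covariance is singular or near-singular; enable "
                "regularization or drop collinear/constant features"
            )
        C = C + np.eye(p) * (1e-8 * np.trace(C) / p)
    L = cholesky(C, lower=True)
    return solve_triangular(L, X.T, lower=True).T


def kennard_stone_split(
    table: pd.DataFrame | np.ndarray,
    n_calibration: int,
    metric: str = "mahalanobis",
    features: tuple[str, ...] = FEATURE_NAMES,
    regularize: bool = True,
) -> SplitResult:
    """Deterministic max-min-distance calibration subset selection.

    The two samples at maximal pairwise distance seed the calibration set;
    each subsequent pick maximizes its minimal distance to the current set.
    Distance ties resolve to the lowest sample index.  ``metric`` is
    ``"mahalanobis"`` (covariance of the full matrix, ridge-regularized when
    near-singular) or ``"euclidean"``.
    """
    if isinstance(table, pd.DataFrame):
        X = feature_matrix(table, features)
    else:
        X = np.atleast_2d(np.asarray(table, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
    n = X.shape[0]
    if not (2 <= n_calibration <= n):
        raise ValueError(f"n_calibration must be in [2, {n}], got {n_calibration}")
    if metric == "mahalanobis":
        Xw = _whiten_mahalanobis(X, regularize=regularize)
    elif metric == "euclidean":
        Xw = X
    else:
        raise ValueError(f"unknown metric: {metric!r}")

    D = squareform(pdist(Xw))
    # seed pair: first occurrence of the global maximum (lowest indices)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[selected] = True
    dmin = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_calibration:
        dmin_masked = np.where(in_cal, -np.inf, dmin)
        k = int(np.argmax(dmin_masked))  # argmax takes the lowest index on ties
        selected.append(k)
        in_cal[k] = True
        dmin = np.minimum(dmin, D[k])
    prediction = np.flatnonzero(~in_cal)
    return SplitResult(calibration=np.array(selected), prediction=prediction)


def random_split(n: int, n_calibration: int, seed: int = 0) -> SplitResult:
    """Plain random partition; baseline against Kennard-Stone in tests."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitResult(calibration=perm[:n_calibration],
                       prediction=np.sort(perm[n_calibration:]))
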