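"""Calibration models: PLS with latent-dimension selection, epsilon-SVR with
(c, g) grid search, and random-forest regression with (PCs, N) optimization.

Model fitting proper is delegated to scikit-learn estimators
(:class:`~sklearn.cross_decomposition.PLSRegression`,
:class:`~sklearn.svm.SVR`, :class:`~sklearn.ensemble.RandomForestRegressor`);
this module owns the tuning protocols, the tie-break rules and the
train/predict contract that chains standardizer -> PCA -> regressor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .features import FEATURE_NAMES
from .prep import PCAProjection, Standardizer, feature_matrix, pca_apply, zscore_apply

VALID_KERNELS = ("linear", "polynomial", "rbf", "sigmoid")


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return X, y


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y) - np.asarray(yhat)) ** 2)))


# ---------------------------------------------------------------- PLS ----

@dataclass
class PLSModel:
    """Fitted partial-least-squares regression with ``npc`` latent factors."""

    npc: int
    _sk: PLSRegression

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._sk.predict(np.asarray(X, dtype=float)).ravel()

    @property
    def x_scores(self) -> np.ndarray:
        return self._sk.x_scores_

    @property
    def coef(self) -> np.ndarray:
        return self._sk.coef_.ravel()


def fit_pls(X: np.ndarray, y: np.ndarray, npc: int) -> PLSModel:
    """NIPALS-style PLS1 fit; at full rank it coincides with least squares."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if not (1 <= npc <= min(n - 1, p)):
        raise ValueError(
            f"npc must be in [1, {min(n - 1, p)}] for n={n}, p={p}; got {npc}"
        )
    sk = PLSRegression(n_components=npc, scale=False)
    with warnings.catch_warnings():
        # scanning npc past the informative rank is part of the selection
        # protocol; the residual-exhausted warning is expected there
        warnings.filterwarnings("ignore", message="y residual is constant")
        sk.fit(X, y)
    return PLSModel(npc=npc, _sk=sk)


def select_npc(
    X: np.ndarray,
    y: np.ndarray,
    npc_range: Sequence[int] = range(1, 11),
    criterion: str = "rmsecv",
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the PLS latent dimension minimizing RMSECV (or RMSEC).

    Returns ``(best_npc, curve)`` where ``curve`` has columns
    ``npc, error``.  Ties go to the smallest npc.  Raw RMSEC decreases
    monotonically with npc, so cross-validation is the default criterion.
    """
    X, y = _check_xy(X, y)
    n = X.shape[0]
    npcs = [int(k) for k in npc_range]
    if not npcs:
        raise ValueError("npc_range is empty")
    if criterion not in ("rmsec", "rmsecv"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    if criterion == "rmsecv" and n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")

    errors = []
    for npc in npcs:
        if criterion == "rmsec":
            model = fit_pls(X, y, npc)
            errors.append(_rmse(y, model.predict(X)))
        else:
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
            preds = np.empty_like(y)
            for tr, te in kf.split(X):
                k = min(npc, min(len(tr) - 1, X.shape[1]))
                preds[te] = fit_pls(X[tr], y[tr], k).predict(X[te])
            errors.append(_rmse(y, preds))
    curve = pd.DataFrame({"npc": npcs, "error": errors})
    best_npc = npcs[int(np.argmin(errors))]
    return best_npc, curve


# ---------------------------------------------------------------- SVR ----

@dataclass(frozen=True)
class SVRSpec:
    """Support-vector-regression hyperparameters.

    ``c`` is the penalty (cost) parameter, ``g`` the kernel parameter
    (gamma), ``epsilon`` the insensitive-tube half width on the moisture
    scale.
    """

    kernel: str = "rbf"
    c: float = 1.0
    g: float = 0.1
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.kernel not in VALID_KERNELS:
            raise ValueError(f"kernel must be one of {VALID_KERNELS}")
        if self.c <= 0 or self.g <= 0 or self.epsilon <= 0:
            raise ValueError("c, g and epsilon must be strictly positive")

    def _sk_kernel(self) -> str:
        return "poly" if self.kernel == "polynomial" else self.kernel


@dataclass
class SVRModel:
    """Fitted epsilon-SVR."""

    spec: SVRSpec
    _sk: SVR

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._sk.predict(np.asarray(X, dtype=float))


def fit_svr(X: np.ndarray, y: np.ndarray, spec: SVRSpec) -> SVRModel:
    X, y = _check_xy(X, y)
    sk = SVR(kernel=spec._sk_kernel(), C=spec.c, gamma=spec.g,
             epsilon=spec.epsilon)
    sk.fit(X, y)
    return SVRModel(spec=spec, _sk=sk)


def default_cg_grid() -> np.ndarray:
    """Logarithmic grid 2^-10 ... 2^10 for both c and g."""
    return 2.0 ** np.arange(-10, 11)


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] | None = None,
    g_grid: Sequence[float] | None = None,
    kernel: str = "rbf",
    epsilon: float = 0.01,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SVRSpec, pd.DataFrame]:
    """Exhaustive (c, g) search by cross-validated RMSE.

    Returns the winning spec and the full error surface (columns
    ``c, g, rmse``).  Ties resolve to smaller c, then smaller g.
    """
    X, y = _check_xy(X, y)
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to regress")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    c_grid = np.sort(np.asarray(c_grid if c_grid is not None else default_cg_grid(), dtype=float))
    g_grid = np.sort(np.asarray(g_grid if g_grid is not None else default_cg_grid(), dtype=float))
    if c_grid.size == 0 or g_grid.size == 0:
        raise ValueError("grids must be non-empty")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    rows = []
    best: tuple[float, float, float] | None = None
    for c in c_grid:
        for g in g_grid:
            spec = SVRSpec(kernel=kernel, c=float(c), g=float(g), epsilon=epsilon)
            preds = np.empty_like(y)
            for tr, te in splits:
                preds[te] = fit_svr(X[tr], y[tr], spec).predict(X[te])
            err = _rmse(y, preds)
            rows.append({"c": float(c), "g": float(g), "rmse": err})
            if best is None or err < best[0]:
                best = (err, float(c), float(g))
    surface = pd.DataFrame(rows)
    assert best is not None
    best_spec = SVRSpec(kernel=kernel, c=best[1], g=best[2], epsilon=epsilon)
    return best_spec, surface


# ----------------------------------------------------------------- RF ----

@dataclass(frozen=True)
class RFSpec:
    """Random-forest hyperparameters: ``n_trees`` (N) and the number of
    leading principal components used as inputs (``n_input_pcs``)."""

    n_trees: int = 500
    n_input_pcs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (1 <= self.n_input_pcs <= 15):
            raise ValueError("n_input_pcs must be in [1, 15]")


@dataclass
class RFModel:
    """Fitted random forest (consumes the first ``n_input_pcs`` score columns)."""

    spec: RFSpec
    _sk: RandomForestRegressor

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._sk.predict(X[:, : self.spec.n_input_pcs])


def fit_rf(X: np.ndarray, y: np.ndarray, spec: RFSpec,
           oob: bool = False) -> RFModel:
    X, y = _check_xy(X, y)
    sk = RandomForestRegressor(
        n_estimators=spec.n_trees, random_state=spec.seed,
        oob_score=oob, bootstrap=True, n_jobs=1,
    )
    sk.fit(X[:, : spec.n_input_pcs], y)
    return RFModel(spec=spec, _sk=sk)


def optimize_rf(
    X_full_pcs: np.ndarray,
    y: np.ndarray,
    pc_range: Sequence[int] = range(1, 11),
    n_range: Sequence[int] = range(50, 1001, 50),
    criterion: str = "oob",
    seed: int = 0,
) -> tuple[RFSpec, pd.DataFrame]:
    """Grid search over (number of input PCs, number of trees).

    ``criterion="oob"`` (default) scores each cell by out-of-bag RMSE;
    ``"rmsec"`` scores by in-sample RMSE, which is near zero for large
    forests and is kept only for protocol compatibility.  Ties resolve to
    fewer PCs, then fewer trees.
    """
    X, y = _check_xy(X_full_pcs, y)
    pcs = [int(k) for k in pc_range]
    ns = [int(k) for k in n_range]
    if not pcs or not ns:
        raise ValueError("pc_range and n_range must be non-empty")
    if criterion not in ("oob", "rmsec"):
        raise ValueError(f"unknown criterion: {criterion!r}")
    rows = []
    best: tuple[float, int, int] | None = None
    for p in pcs:
        if p > X.shape[1]:
            raise ValueError(f"requested {p} PCs but X has {X.shape[1]} columns")
        for ntree in ns:
            spec = RFSpec(n_trees=ntree, n_input_pcs=p, seed=seed)
            model = fit_rf(X, y, spec, oob=(criterion == "oob"))
            if criterion == "oob":
                oob_pred = model._sk.oob_prediction_
                ok = np.isfinite(oob_pred)
                err = _rmse(y[ok], oob_pred[ok])
            else:
                err = _rmse(y, model.predict(X))
            rows.append({"pcs": p, "n_trees": ntree, "error": err})
            if best is None or err < best[0]:
                best = (err, p, ntree)
    grid = pd.DataFrame(rows)
    assert best is not None
    return RFSpec(n_trees=best[2], n_input_pcs=best[1], seed=seed), grid


# ------------------------------------------------------- FittedModel ----

@dataclass
class FittedModel:
    """A trained regressor bundled with its preprocessing state.

    ``predict`` consumes a raw feature table: columns are aligned by the
    canonical feature names, standardized with the stored z-score state,
    projected onto the stored principal components (first ``n_input_pcs``
    columns) and passed to the regressor.
    """

    family: str  # "pls" | "svr" | "rf"
    regressor: PLSModel | SVRModel | RFModel
    standardizer: Standardizer
    pca: PCAProjection
    n_input_pcs: int
    spec: dict = field(default_factory=dict)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.standardizer.feature_names
                   if c not in table.columns]
        if missing:
            raise ValueError(f"table is missing feature columns: {missing}")
        z = zscore_apply(self.standardizer, table)
        scores = pca_apply(self.pca, z)
        return scores[:, : self.n_input_pcs]

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.regressor.predict(self.transform(table)), dtype=float)


def predict(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Moisture predictions for a raw feature table (name-aligned columns)."""
    return model.predict_table(table)


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize to a directory bundle: JSON metadata + array payloads."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "family": model.family,
        "n_input_pcs": model.n_input_pcs,
        "spec": model.spec,
        "feature_names": list(model.standardizer.feature_names),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, default=float))
    np.savez(
        path / "preprocessing.npz",
        means=model.standardizer.means,
        sds=model.standardizer.sds,
        loadings=model.pca.loadings,
        pca_mean=model.pca.mean,
        explained_variance=model.pca.explained_variance,
        explained_variance_ratio=model.pca.explained_variance_ratio,
    )
    joblib.dump(model.regressor, path / "regressor.joblib")


def load_model(path: str | Path) -> FittedModel:
    import joblib

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    arrs = np.load(path / "preprocessing.npz")
    names = tuple(meta["feature_names"])
    std = Standardizer(means=arrs["means"], sds=arrs["sds"], feature_names=names)
    pca = PCAProjection(
        loadings=arrs["loadings"], mean=arrs["pca_mean"],
        explained_variance=arrs["explained_variance"],
        explained_variance_ratio=arrs["explained_variance_ratio"],
        feature_names=names,
    )
    regressor = joblib.load(path / "regressor.joblib")
    return FittedModel(
        family=meta["family"], regressor=regressor, standardizer=std,
        pca=pca, n_input_pcs=meta["n_input_pcs"], spec=meta["spec"],
    )
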