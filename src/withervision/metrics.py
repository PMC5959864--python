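"""Chemometric evaluation: calibration/prediction metrics, the
feature-moisture correlation table with significance stars, and the
model-comparison report.

Definitions (documented because conventions vary across the literature):

* ``R``    -- Pearson correlation between measured and predicted values.
* ``RMSE`` -- root of the mean squared residual.
* ``Bias`` -- mean of (predicted - measured) on the prediction set.
* ``SEP``  -- bias-corrected standard error of prediction,
  ``sqrt(sum((res - Bias)^2) / (n - 1))``; hence the algebraic identity
  ``RMSEP^2 = Bias^2 + SEP^2 * (n - 1) / n``.
* ``RPD``  -- sd of the measured prediction-set values (n-1 denominator)
  divided by RMSEP; values above ~1.5 indicate a usable calibration.
* ``CV``   -- coefficient of variation of the measured prediction-set
  values, sd / mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES


@dataclass
class MetricsReport:
    """The eight evaluation indicators for one fitted model."""

    Rc: float
    RMSEC: float
    Rp: float
    RMSEP: float
    Bias: float
    SEP: float
    CV: float
    RPD: float
    n_cal: int
    n_pred: int
    model: str = ""
    spec: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "spec": self.spec,
            "n_cal": self.n_cal, "n_pred": self.n_pred,
            "Rc": self.Rc, "RMSEC": self.RMSEC,
            "Rp": self.Rp, "RMSEP": self.RMSEP, "Bias": self.Bias,
            "SEP": self.SEP, "CV": self.CV, "RPD": self.RPD,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def regression_metrics(
    y_cal: np.ndarray,
    yhat_cal: np.ndarray,
    y_pred: np.ndarray,
    yhat_pred: np.ndarray,
    model: str = "",
    spec: dict | None = None,
) -> MetricsReport:
    """Compute all eight indicators from measured/predicted pairs.

    A perfect prediction set gives RMSEP = SEP = Bias = 0 and an infinite
    RPD (reported as ``inf``).  Constant measured vectors are rejected:
    correlation and RPD are undefined there.
    """
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    yhat_cal = np.asarray(yhat_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    yhat_pred = np.asarray(yhat_pred, dtype=float).ravel()
    for a, b, name in ((y_cal, yhat_cal, "calibration"),
                       (y_pred, yhat_pred, "prediction")):
        if a.shape != b.shape or a.size < 2:
            raise ValueError(f"{name} vectors must be paired with n >= 2")
        if np.ptp(a) == 0:
            raise ValueError(
                f"measured {name} values are constant; R and RPD undefined"
            )

    res = yhat_pred - y_pred
    n = res.size
    bias = float(res.mean())
    rmsep = float(np.sqrt(np.mean(res**2)))
    sep = float(np.sqrt(np.sum((res - bias) ** 2) / (n - 1)))
    sd_ref = float(np.std(y_pred, ddof=1))
    rpd = float("inf") if rmsep == 0 else sd_ref / rmsep
    cv = sd_ref / float(np.mean(y_pred))
    return MetricsReport(
        Rc=_pearson(y_cal, yhat_cal),
        RMSEC=float(np.sqrt(np.mean((yhat_cal - y_cal) ** 2))),
        Rp=_pearson(y_pred, yhat_pred),
        RMSEP=rmsep, Bias=bias, SEP=sep, CV=cv, RPD=rpd,
        n_cal=y_cal.size, n_pred=n, model=model, spec=spec or {},
    )


@dataclass
class CorrelationReport:
    """Pairwise Pearson structure over moisture plus the 15 features."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def formatted(self) -> pd.DataFrame:
        """Correlation coefficients with significance stars appended."""
        out = self.r.round(3).astype(str)
        return out + self.stars


def correlation_table(
    table: pd.DataFrame,
    features: tuple[str, ...] = FEATURE_NAMES,
    target: str = "moisture",
    bonferroni: bool = False,
) -> CorrelationReport:
    """Pearson correlation matrix with two-sided t-test significance flags.

    Flags: ``**`` at p < 0.01, ``*`` at p < 0.05.  A constant column yields
    NaN correlations flagged ``n/a`` rather than silent zeros.  With
    ``bonferroni=True`` the p-value thresholds are divided by the number of
    off-diagonal pairs.
    """
    cols = [target, *features]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    n = len(table)
    if n < 4:
        raise ValueError("need at least 4 samples for correlation analysis")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
            else:
                res = stats.pearsonr(x, y)
                r[i, j] = r[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    alpha1, alpha2 = 0.01, 0.05
    if bonferroni:
        m = k * (k - 1) / 2
        alpha1, alpha2 = alpha1 / m, alpha2 / m
    stars = np.full((k, k), "", dtype=object)
    stars[np.isnan(p)] = "n/a"
    stars[(p < alpha2) & ~np.isnan(p)] = "*"
    stars[(p < alpha1) & ~np.isnan(p)] = "**"
    np.fill_diagonal(stars, "")
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sdf = pd.DataFrame(stars, index=cols, columns=cols)
    return CorrelationReport(r=rdf, p=pdf, stars=sdf)


def model_comparison(reports: list[MetricsReport]) -> pd.DataFrame:
    """One row per model, sorted by descending RPD; the first row is best."""
    if not reports:
        raise ValueError("need at least one metrics report")
    rows = []
    for rep in reports:
        d = rep.to_dict()
        d["spec"] = "; ".join(f"{k}={v}" for k, v in rep.spec.items())
        rows.append(d)
    df = pd.DataFrame(rows)
    df = df.sort_values("RPD", ascending=False, kind="mergesort").reset_index(drop=True)
    df["best"] = [i == 0 for i in range(len(df))]
    return df
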