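"""Robust weighted regression and the headline correlation analyses.

All reported fits are simple linear regressions estimated by
iteratively reweighted least squares with the bisquare (Tukey biweight)
influence function at the conventional tuning constant 4.685, so
outliers are down-weighted rather than removed.  Observation weights
(e.g. the number of muscles behind an aggregated point) multiply the
robust weights.  R^2 is computed on the final weighted fit (weighted
SSE over weighted SST), and the F statistic and p-value follow from it
with df = (1, n - 2).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .hypergraph import DegreeProfile
from .ordering import LinearOrdering

__all__ = [
    "RegressionResult", "RobustWeightedRegression", "robust_weighted_fit",
    "aggregate_group_deviation", "recovery_regression", "volume_regression",
    "homunculus_regression", "ordering_regression", "ks_degree_test",
    "load_homunculus_categories", "load_recovery_table", "load_volume_table",
    "regression_report",
]


@dataclass
class RegressionResult:
    """Summary of a robust weighted simple linear fit."""

    slope: float
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["df"] = list(self.df)
        return d


class RobustWeightedRegression(BaseEstimator, RegressorMixin):
    """Bisquare IRLS simple linear regression with observation weights.

    Parameters
    ----------
    tuning : bisquare tuning constant (default 4.685, ~95% Gaussian
        efficiency).
    max_iter, tol : IRLS stopping rule on the coefficient change.

    Attributes
    ----------
    coef_, intercept_ : fitted line.
    r_squared_, f_statistic_, p_value_, df_ : weighted-fit summary.
    robust_weights_ : final bisquare weights (before observation
        weights are folded in).
    """

    def __init__(self, tuning: float = 4.685, max_iter: int = 100,
                 tol: float = 1e-10):
        self.tuning = tuning
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise ValueError("x and y must have equal length")
        n = len(x)
        if n < 3:
            raise ValueError("need at least 3 observations")
        if np.ptp(x) == 0:
            raise ValueError("rank-deficient predictor (constant x)")
        w_obs = (np.ones(n) if sample_weight is None
                 else np.asarray(sample_weight, dtype=float))
        if np.any(w_obs <= 0):
            raise ValueError("observation weights must be positive")

        A = np.column_stack([np.ones(n), x])

        def wls(w):
            Aw = A * w[:, None]
            beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
            return beta

        beta = wls(w_obs)
        rw = np.ones(n)
        for _ in range(self.max_iter):
            resid = y - A @ beta
            scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
            if scale <= np.finfo(float).eps * max(1.0, np.abs(y).max()):
                rw = np.ones(n)
                break
            u = resid / (self.tuning * scale)
            rw = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
            if rw.sum() == 0:
                rw = np.ones(n)
            new_beta = wls(rw * w_obs)
            if np.max(np.abs(new_beta - beta)) < self.tol:
                beta = new_beta
                break
            beta = new_beta

        w = rw * w_obs
        yhat = A @ beta
        wbar = np.sum(w * y) / np.sum(w)
        sse = float(np.sum(w * (y - yhat) ** 2))
        sst = float(np.sum(w * (y - wbar) ** 2))
        r2 = 0.0 if sst == 0 else max(0.0, min(1.0, 1 - sse / sst))
        df1, df2 = 1, n - 2
        if r2 >= 1.0:
            f, p = np.inf, 0.0
        else:
            f = (r2 / df1) / ((1 - r2) / df2)
            p = float(sps.f.sf(f, df1, df2))
        self.intercept_, self.coef_ = float(beta[0]), np.array([beta[1]])
        self.robust_weights_ = rw
        self.weights_ = w
        self.r_squared_ = r2
        self.f_statistic_ = float(f)
        self.p_value_ = p
        self.df_ = (df1, df2)
        self.n_ = n
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.coef_[0] * x

    def result(self) -> RegressionResult:
        return RegressionResult(float(self.coef_[0]), self.intercept_,
                                self.f_statistic_, self.df_, self.r_squared_,
                                self.p_value_, self.n_)


def robust_weighted_fit(x, y, weights=None) -> RegressionResult:
    """Robust weighted simple regression of y on x (bisquare IRLS)."""
    return RobustWeightedRegression().fit(x, y, sample_weight=weights).result()


# -- aggregation and the four headline regressions ---------------------

def aggregate_group_deviation(dev: pd.DataFrame,
                              groups: Mapping[str, Sequence[str]]
                              ) -> pd.DataFrame:
    """Mean impact deviation and member count per named muscle group.

    Groups whose members do not resolve against the deviation table are
    excluded with a warning.
    """
    by_muscle = dict(zip(dev["muscle"], dev["deviation"]))
    rows = []
    for g, members in groups.items():
        vals = [by_muscle[m] for m in members
                if m in by_muscle and np.isfinite(by_muscle[m])]
        if not vals:
            warnings.warn(f"group {g!r}: no resolvable muscles, excluded")
            continue
        rows.append({"group": g, "mean_deviation": float(np.mean(vals)),
                     "n_muscles": len(vals)})
    return pd.DataFrame(rows)


def recovery_regression(dev: pd.DataFrame, recovery: pd.DataFrame,
                        groups: Mapping[str, Sequence[str]]
                        ) -> RegressionResult:
    """Recovery weeks ~ mean impact deviation, points weighted by the
    number of muscles in each injury group."""
    agg = aggregate_group_deviation(dev, groups)
    merged = agg.merge(recovery, on="group", how="inner")
    if merged.empty:
        raise ValueError("no overlap between deviation groups and "
                         "recovery table")
    return robust_weighted_fit(merged["mean_deviation"],
                               merged["weeks_recovery"],
                               merged["n_muscles"])


def volume_regression(dev: pd.DataFrame, volumes: pd.DataFrame,
                      groups: Mapping[str, Sequence[str]]
                      ) -> RegressionResult:
    """Mean impact deviation ~ motor-strip activation volume (mm^3),
    points weighted by the number of muscles behind each movement."""
    agg = aggregate_group_deviation(dev, groups)
    merged = agg.merge(volumes, on="group", how="inner")
    if merged.empty:
        raise ValueError("no overlap between deviation groups and "
                         "volume table")
    return robust_weighted_fit(merged["volume_mm3"],
                               merged["mean_deviation"],
                               merged["n_muscles"])


def homunculus_regression(ratios: pd.DataFrame) -> RegressionResult:
    """Deviation ratio ~ medial-to-lateral homunculus position index."""
    if len(ratios) < 3:
        raise ValueError("need at least 3 categories with defined ratios")
    return robust_weighted_fit(ratios["category_id"], ratios["ratio"])


def ordering_regression(ordering: LinearOrdering | pd.DataFrame,
                        categories: Mapping[str, int]) -> RegressionResult:
    """MDS linear coordinate ~ homunculus category id, across muscles.

    The coordinate's global sign is arbitrary; R^2, F and p are
    sign-free, and the slope is reported for the orientation fitted.
    """
    if isinstance(ordering, LinearOrdering):
        frame = pd.DataFrame({"muscle": ordering.labels,
                              "coordinate": ordering.coordinate})
    else:
        frame = ordering
    frame = frame[np.isfinite(frame["coordinate"])]
    missing = [m for m in frame["muscle"] if m not in categories]
    if missing:
        raise ValueError(f"muscles without homunculus category: {missing[:10]}")
    cats = np.array([categories[m] for m in frame["muscle"]], dtype=float)
    return robust_weighted_fit(cats, frame["coordinate"].to_numpy())


def ks_degree_test(real: DegreeProfile | np.ndarray,
                   null: DegreeProfile | np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on hyperedge degree samples."""
    a = real.degrees if isinstance(real, DegreeProfile) else np.asarray(real)
    b = null.degrees if isinstance(null, DegreeProfile) else np.asarray(null)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("degree samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# -- packaged clinical fixtures (printed tables) -----------------------

def _load_data_csv(name: str) -> pd.DataFrame:
    with resources.files("musclenet.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_homunculus_categories() -> pd.DataFrame:
    """The 22 motor-homunculus categories with their medial-to-lateral
    identification numbers (1 = Toes ... 22 = Swallowing)."""
    return _load_data_csv("homunculus_categories.csv")


def load_recovery_table() -> pd.DataFrame:
    """Published average sports-injury recovery times (weeks) per muscle
    or muscle group; columns group, weeks_recovery, source."""
    return _load_data_csv("recovery_table.csv")


def load_volume_table() -> pd.DataFrame:
    """Published fMRI motor-strip activation volumes (mm^3) per joint
    movement; columns group, volume_mm3, source."""
    return _load_data_csv("volume_table.csv")


def regression_report(results: Mapping[str, RegressionResult],
                      inputs: Mapping[str, pd.DataFrame] | None = None
                      ) -> dict:
    """Machine-readable record of named regressions with input hashes."""
    report = {"regressions": {name: res.to_dict()
                              for name, res in results.items()}}
    if inputs:
        hashes = {}
        for name, df in inputs.items():
            payload = df.to_csv(index=False).encode()
            hashes[name] = hashlib.sha256(payload).hexdigest()[:16]
        report["input_hashes"] = hashes
    return report
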