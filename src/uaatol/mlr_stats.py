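"""Correlation screening and backward-selection multiple linear regression.

Features are first screened by their Pearson (continuous response) or
point-biserial (binary response) correlation coefficient R.  The top
candidates then enter an ordinary-least-squares model which is pruned
by backward elimination: the least significant coefficient is dropped
and the model refit until every remaining coefficient is significant.

Because the candidate features are pre-selected by |R| out of a pool
that is typically much larger than the sample size, the per-coefficient
significance threshold is Bonferroni-corrected by the number of
screened candidates by default; without this, a spurious "most
correlated noise feature" survives elimination in a large fraction of
null datasets.  Set ``multiplicity='none'`` for the uncorrected rule.

Reported summary statistics follow the regression-table convention:
multiple correlation R = sqrt(R^2), adjusted R as the sign-preserving
square root of adjusted R^2 (floored at 0), the overall F statistic
and its p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "CorrelationReport",
    "MlrReport",
    "pearson_r",
    "point_biserial",
    "rank_features",
    "fit_mlr",
    "backward_select",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def point_biserial(x, y) -> float:
    """Correlation between a continuous vector and binary labels (0/1)."""
    y = np.asarray(y)
    if y.dtype != bool:
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("labels must be binary (bool or 0/1)")
        y = y.astype(bool)
    if y.all() or not y.any():
        warnings.warn("only one class present; point-biserial undefined")
        return float("nan")
    return float(stats.pointbiserialr(y.astype(int), np.asarray(x, float)).correlation)


@dataclass
class CorrelationReport:
    """Features ordered by |R| descending (ties keep column order)."""

    method: str  # "pearson" | "point_biserial"
    r_values: list  # list of (feature name, R)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_values, columns=["feature", "R"])


def rank_features(X: pd.DataFrame, y, method: str = "auto") -> CorrelationReport:
    """Correlation screen of every feature column against the response.

    ``method`` is ``'pearson'``, ``'point_biserial'`` or ``'auto'``
    (point-biserial when the response is binary).  Constant features
    are omitted with a warning.
    """
    y_arr = np.asarray(y)
    if method == "auto":
        binary = y_arr.dtype == bool or len(np.unique(y_arr)) <= 2
        method = "point_biserial" if binary else "pearson"
    corr = point_biserial if method == "point_biserial" else pearson_r
    rows = []
    for j, col in enumerate(X.columns):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = corr(X[col].to_numpy(), y_arr)
        if np.isnan(r):
            warnings.warn(f"feature {col!r}: correlation undefined; omitted")
            continue
        rows.append((j, col, float(r)))
    rows.sort(key=lambda t: (-abs(t[2]), t[0]))
    return CorrelationReport(method=method, r_values=[(c, r) for _, c, r in rows])


@dataclass
class MlrReport:
    features: list
    coefficients: dict  # feature -> coefficient (plus "intercept")
    R: float
    adjR: float
    F: float
    probF: float
    n_features: int
    coef_pvalues: dict | None = None

    def as_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "R": self.R,
            "adjR": self.adjR,
            "F": self.F,
            "probF": self.probF,
            "n_features": self.n_features,
        }


def fit_mlr(X: pd.DataFrame, y) -> MlrReport:
    """Ordinary least squares with intercept and regression summary stats."""
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > n_features + 1 (n={n}, k={k})")
    mat = X.to_numpy(dtype=float)
    if k:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), mat]))
        if rank < k + 1:
            # name columns involved in collinearity via pairwise correlation
            cc = np.corrcoef(mat, rowvar=False)
            pairs = [
                (X.columns[i], X.columns[j])
                for i in range(k)
                for j in range(i + 1, k)
                if abs(cc[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"design matrix rank deficient; collinear columns: {pairs}")
    model = sm.OLS(y, sm.add_constant(mat, has_constant="add")).fit()
    r2 = model.rsquared if k else 0.0
    adj = model.rsquared_adj if k else 0.0
    coefs = {"intercept": model.params[0]}
    pvals = {}
    for j, col in enumerate(X.columns):
        coefs[col] = model.params[j + 1]
        pvals[col] = float(model.pvalues[j + 1])
    return MlrReport(
        features=list(X.columns),
        coefficients=coefs,
        R=float(np.sqrt(max(r2, 0.0))),
        adjR=float(np.sqrt(adj)) if adj > 0 else 0.0,
        F=float(model.fvalue) if k else 0.0,
        probF=float(model.f_pvalue) if k else float("nan"),
        n_features=k,
        coef_pvalues=pvals,
    )


def backward_select(
    X: pd.DataFrame,
    y,
    p_threshold: float = 0.05,
    max_features: int = 10,
    multiplicity: str = "bonferroni",
    screen: bool = True,
) -> MlrReport:
    """Backward elimination from the most |R|-correlated candidate features.

    Starts from the ``max_features`` top columns of ``X`` by absolute
    correlation with ``y`` (capped at ``n - 2``), then repeatedly drops
    the coefficient with the largest p-value until all remaining
    coefficients are significant.  With ``multiplicity='bonferroni'``
    (default) the per-coefficient threshold is
    ``p_threshold / n_screened_candidates``.  If every feature is
    dropped an intercept-only report is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if multiplicity not in ("bonferroni", "none"):
        raise ValueError("multiplicity must be 'bonferroni' or 'none'")
    n_candidates = X.shape[1]
    cap = min(max_features, n - 2)
    if screen:
        report = rank_features(X, y, method="pearson")
        selected = [name for name, _ in report.r_values[:cap]]
    else:
        selected = list(X.columns[:cap])
    threshold = (
        p_threshold / n_candidates if multiplicity == "bonferroni" else p_threshold
    )
    while selected:
        fit = fit_mlr(X[selected], y)
        worst = max(selected, key=lambda c: fit.coef_pvalues[c])
        if fit.coef_pvalues[worst] <= threshold:
            return fit
        selected.remove(worst)
    warnings.warn("backward selection eliminated every feature; intercept-only model")
    return fit_mlr(X[[]], y)
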