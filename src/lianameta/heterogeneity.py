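"""Residual heterogeneity of effect sizes: Cochran Q and I-squared.

Q is computed from the *fixed-effects* (tau2 = 0) inverse-variance
weighted fit of the model's design matrix, so for covariate-bearing
models it measures residual heterogeneity beyond the moderators (a
QE-style statistic). I2 = max(0, (Q - df)/Q) * 100 expresses the excess
variation as a percentage, read against the conventional anchors
25 (low) / 50 (moderate) / 75 (high).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p_value: float
    I2: float
    classification: str
    Q_ci: tuple[float, float] | None = None
    I2_ci: tuple[float, float] | None = None

    def as_row(self, label: str = "") -> dict:
        return {
            "model_label": label, "Q": self.Q, "df": self.df, "p": self.p_value,
            "Q_ci_low": None if self.Q_ci is None else self.Q_ci[0],
            "Q_ci_high": None if self.Q_ci is None else self.Q_ci[1],
            "I2": self.I2,
            "I2_ci_low": None if self.I2_ci is None else self.I2_ci[0],
            "I2_ci_high": None if self.I2_ci is None else self.I2_ci[1],
            "classification": self.classification,
        }


def _wls_residuals(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> np.ndarray:
    w = 1.0 / v
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return y - X @ beta


def q_statistic(estimates, variances, design=None) -> tuple[float, int, float]:
    """Weighted residual sum of squares of the tau2=0 fit.

    Parameters
    ----------
    design : ndarray, optional
        Fixed-effects design matrix (with intercept). Default intercept-only,
        which gives the textbook Cochran Q about the inverse-variance mean.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 effects")
    if (v <= 0).any() or np.isnan(v).any():
        raise ValueError("variances must be present and > 0")
    X = np.ones((len(y), 1)) if design is None else np.asarray(design, dtype=float)
    k, p = X.shape
    if k <= p:
        raise ValueError(f"Q degrees of freedom undefined: k={k} <= p={p}")
    resid = _wls_residuals(y, v, X)
    Q = float(np.sum(resid**2 / v))
    df = k - p
    return Q, df, float(stats.chi2.sf(Q, df))


def i_squared(Q: float, df: int) -> tuple[float, str]:
    """I2 percentage and its qualitative band.

    The anchors 25/50/75 map to low/moderate/high; band edges sit at the
    midpoints 37.5 and 62.5.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    if I2 < 37.5:
        cls = "low"
    elif I2 < 62.5:
        cls = "moderate"
    else:
        cls = "high"
    return I2, cls


def heterogeneity_ci(estimates, variances, design=None, level: float = 0.95,
                     n_boot: int = 2000, seed: int = 0
                     ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile bootstrap intervals for Q and I2 (resampling effect rows).

    The construction used for the published intervals is not documented;
    a nonparametric row bootstrap is the package's choice (a Q-profile
    analytic interval is a possible future alternative).
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 effects for a bootstrap interval")
    if n_boot < 100:
        import warnings
        warnings.warn("n_boot < 100: bootstrap intervals will be unstable")
    X = np.ones((len(y), 1)) if design is None else np.asarray(design, dtype=float)
    rng = np.random.default_rng(seed)
    k, p = X.shape
    qs = np.empty(n_boot)
    i2s = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        idx = rng.integers(0, k, size=k)
        Xb = X[idx]
        if np.linalg.matrix_rank(Xb) < p:
            continue  # resample produced a degenerate design; redraw
        resid = _wls_residuals(y[idx], v[idx], Xb)
        Q = float(np.sum(resid**2 / v[idx]))
        qs[filled] = Q
        i2s[filled], _ = i_squared(Q, k - p)
        filled += 1
    alpha = 1.0 - level
    q_ci = tuple(np.quantile(qs, [alpha / 2, 1 - alpha / 2]))
    i2_ci = tuple(np.quantile(i2s, [alpha / 2, 1 - alpha / 2]))
    return (float(q_ci[0]), float(q_ci[1])), (float(i2_ci[0]), float(i2_ci[1]))


def assess_heterogeneity(table: pd.DataFrame, design=None, n_boot: int = 2000,
                         seed: int = 0, with_ci: bool = True
                         ) -> HeterogeneityResult:
    """Q, I2 and (optionally bootstrap) CIs for one completed effect table."""
    y = table["estimate"].to_numpy()
    v = table["variance"].to_numpy()
    Q, df, p = q_statistic(y, v, design)
    I2, cls = i_squared(Q, df)
    q_ci = i2_ci = None
    if with_ci:
        q_ci, i2_ci = heterogeneity_ci(y, v, design, n_boot=n_boot, seed=seed)
    return HeterogeneityResult(Q, df, p, I2, cls, q_ci, i2_ci)


def average_heterogeneity(results: list[HeterogeneityResult]) -> HeterogeneityResult:
    """Average Q/I2 (and CI endpoints) across imputations, following the
    same averaging convention as the coefficient pooling."""
    Q = float(np.mean([r.Q for r in results]))
    df = results[0].df
    p = float(stats.chi2.sf(Q, df))
    I2, cls = i_squared(Q, df)
    def _avg(attr):
        vals = [getattr(r, attr) for r in results]
        if any(v is None for v in vals):
            return None
        return (float(np.mean([v[0] for v in vals])),
                float(np.mean([v[1] for v in vals])))
    return HeterogeneityResult(Q, df, p, I2, cls, _avg("Q_ci"), _avg("I2_ci"))
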