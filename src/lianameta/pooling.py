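"""Combining the m per-imputation model fits into one set of results.

The published convention is plain arithmetic averaging of coefficients,
standard errors and degrees of freedom across the 10 imputed-data fits,
with confidence intervals and p-values recomputed from those averages.
Rubin's rules (within + between-imputation variance) are provided as a
diagnostic alternative; they widen the SEs when imputations disagree.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import MetaRegressionResults


class PooledResults:
    """Cross-imputation pooled coefficients with t-based inference."""

    def __init__(self, params: pd.Series, bse: pd.Series, df: pd.Series,
                 rule: str, m: int, tau2: float, sigma2: float):
        self.params = params
        self.bse = bse
        self.df = df
        self.pooling_rule = rule
        self.m = m
        self.tau2 = tau2        # mean across imputations
        self.sigma2 = sigma2

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * stats.t.sf(np.abs(self.tvalues), self.df),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2.0, self.df)
        return pd.DataFrame({"ci_low": self.params - tcrit * self.bse,
                             "ci_high": self.params + tcrit * self.bse})

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse, "df": self.df,
            "ci_low": ci["ci_low"], "ci_high": ci["ci_high"],
            "p": self.pvalues,
        })

    def summary(self, alpha: float = 0.05) -> str:
        head = (f"Pooled meta-regression over m={self.m} imputations "
                f"(rule={self.pooling_rule})\n"
                f"  mean tau2: {self.tau2:.6g}   mean sigma2: {self.sigma2:.6g}\n")
        return head + self.summary_frame(alpha).round(4).to_string()

    def summary_effect(self, alpha: float = 0.05) -> dict:
        """Intercept as the overall summary effect, on the SMD, percent
        (100*SMD) and fold-change (1+SMD) presentation scales."""
        if "intercept" not in self.params.index:
            raise ValueError("model has no intercept; no summary effect")
        est = float(self.params["intercept"])
        ci = self.conf_int(alpha).loc["intercept"]
        lo, hi = float(ci["ci_low"]), float(ci["ci_high"])
        return {
            "smd": est, "smd_ci": (lo, hi),
            "percent": 100.0 * est, "percent_ci": (100.0 * lo, 100.0 * hi),
            "fold": 1.0 + est, "fold_ci": (1.0 + lo, 1.0 + hi),
        }


def pool_fits(fits: Sequence[MetaRegressionResults],
              rule: str = "average") -> PooledResults:
    """Pool m fits sharing the same coefficient names.

    rule="average": arithmetic mean of estimate, SE and df per coefficient.
    rule="rubin": total variance W + (1 + 1/m) B with W the mean squared SE
    and B the between-imputation variance of estimates; Barnard-Rubin-style
    df reduces to the average df when B = 0.
    """
    if len(fits) == 0:
        raise ValueError("no fits to pool")
    names = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != names:
            raise ValueError("fits have mismatched coefficient sets")
    m = len(fits)
    est = np.stack([f.params.to_numpy() for f in fits])
    ses = np.stack([f.bse.to_numpy() for f in fits])
    dfs = np.stack([f.df.to_numpy() for f in fits])
    mean_est = est.mean(axis=0)
    tau2 = float(np.mean([f.tau2 for f in fits]))
    sigma2 = float(np.mean([f.sigma2 for f in fits]))

    if rule == "average":
        pooled_se = ses.mean(axis=0)
        pooled_df = dfs.mean(axis=0)
    elif rule == "rubin":
        W = (ses**2).mean(axis=0)
        B = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(mean_est)
        T = W + (1.0 + 1.0 / m) * B
        pooled_se = np.sqrt(T)
        with np.errstate(divide="ignore"):
            r = (1.0 + 1.0 / m) * B / np.where(W > 0, W, np.inf)
            nu = np.where(B > 0, (m - 1) * (1.0 + 1.0 / r)**2, np.inf)
        pooled_df = np.minimum(nu, dfs.mean(axis=0))
        pooled_df = np.where(np.isfinite(pooled_df), pooled_df, dfs.mean(axis=0))
    else:
        raise ValueError(f"unknown pooling rule {rule!r}")

    idx = pd.Index(names)
    return PooledResults(pd.Series(mean_est, idx), pd.Series(pooled_se, idx),
                         pd.Series(pooled_df, idx), rule, m, tau2, sigma2)
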