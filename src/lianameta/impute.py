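"""Stochastic regression imputation of missing effect-size variances.

Sampling variances that could not be computed (group SDs unreported) are
filled in m times from a log-linear model fitted to the complete rows:

    log(variance) = a + b * log(n_t + n_c)... -- here: b1*log(total n)
                    + b2*|estimate| + Normal(0, sigma_resid)

The log scale guarantees positive imputed variances; the fresh Normal
draw per row per imputation propagates imputation uncertainty into the
across-imputation spread of the fitted models. Draws come from named
substreams of the master seed keyed by (imputation index, row key), so
adding or reordering rows does not perturb other rows' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class VarianceModel:
    """OLS fit of log-variance on log total n and |estimate|."""
    params: np.ndarray          # intercept, coef(log n), coef(|estimate|)
    resid_sd: float
    n_complete: int
    fallback: bool = False      # True -> hot-deck (empirical draw) mode
    observed_variances: np.ndarray | None = None

    def predict_log_variance(self, total_n: np.ndarray,
                             abs_estimate: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(total_n, dtype=float),
                             np.log(total_n.astype(float)),
                             abs_estimate.astype(float)])
        return X @ self.params


class ImputationError(RuntimeError):
    pass


def fit_variance_model(effects: pd.DataFrame) -> VarianceModel:
    """Fit the log-variance regression on rows with observed variance.

    Requires at least 5 complete rows and a predictor with nonzero spread;
    otherwise a hot-deck fallback model (resampling observed variances) is
    returned so sparse tables never abort a run.
    """
    complete = effects.dropna(subset=["variance"])
    obs = complete["variance"].to_numpy(dtype=float)
    total_n = (complete["n_t"] + complete["n_c"]).to_numpy(dtype=float) \
        if {"n_t", "n_c"} <= set(complete.columns) else None

    if len(complete) < 5 or total_n is None or \
            (np.ptp(np.log(total_n)) == 0 and np.ptp(np.abs(complete["estimate"])) == 0):
        if len(complete) == 0:
            raise ImputationError("no complete rows: variances cannot be imputed")
        return VarianceModel(params=np.zeros(3), resid_sd=0.0,
                             n_complete=len(complete), fallback=True,
                             observed_variances=obs)

    y = np.log(obs)
    X = sm.add_constant(np.column_stack([np.log(total_n),
                                         np.abs(complete["estimate"].to_numpy())]))
    fit = sm.OLS(y, X).fit()
    dof = max(len(y) - X.shape[1], 1)
    resid_sd = float(np.sqrt(np.sum(fit.resid**2) / dof))
    return VarianceModel(params=np.asarray(fit.params), resid_sd=resid_sd,
                         n_complete=len(complete), observed_variances=obs)


def _row_rng(master_seed: int, imputation: int, row_key: str) -> np.random.Generator:
    key_hash = zlib.crc32(row_key.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(imputation), key_hash])
    )


def impute_missing_variances(effects: pd.DataFrame, m: int = 10,
                             master_seed: int = 0,
                             model: VarianceModel | None = None,
                             ) -> list[pd.DataFrame]:
    """Produce m completed copies of the effect table.

    Observed variances are never altered; each missing variance is drawn
    independently per imputation. With no missing variances the m copies
    are identical to the input.
    """
    if m < 1:
        raise ImputationError("m must be >= 1")
    missing = effects["variance"].isna()
    if not missing.any():
        return [effects.copy() for _ in range(m)]

    if model is None:
        model = fit_variance_model(effects)

    tables: list[pd.DataFrame] = []
    miss_idx = effects.index[missing]
    for j in range(1, m + 1):
        tab = effects.copy()
        for idx in miss_idx:
            row = effects.loc[idx]
            key = f"{row['study_id']}|{row['comparison_id']}"
            rng = _row_rng(master_seed, j, key)
            if model.fallback:
                val = float(rng.choice(model.observed_variances))
            else:
                total_n = np.asarray([row.get("n_t", np.nan) + row.get("n_c", np.nan)])
                if np.isnan(total_n[0]):
                    total_n = np.asarray([4.0])  # minimal two-per-arm design
                mu = model.predict_log_variance(
                    total_n, np.asarray([abs(row["estimate"])]))[0]
                val = float(np.exp(mu + rng.normal(0.0, model.resid_sd)))
            tab.loc[idx, "variance"] = val
            tab.loc[idx, "variance_was_imputed"] = True
        tab.attrs["imputation_index"] = j
        tab.attrs["master_seed"] = master_seed
        tables.append(tab)
    return tables
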