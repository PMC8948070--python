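"""Weighted mixed-effects meta-regression (the core model).

The model for effect size :math:`y_i` of study :math:`s(i)` is

.. math::

    y_i = x_i^\\top \\beta + u_{s(i)} + e_i, \\qquad
    u_s \\sim N(0, \\tau^2), \\quad e_i \\sim N(0, \\sigma^2 v_i),

with known inverse-variance weights :math:`1/v_i` from the effect-size
sampling variances, a random intercept per study to absorb the
non-independence of multiple effects within a study, and the residual
scale :math:`\\sigma^2` estimated freely (an lme4-style weighted LMM
rather than a classical rma model with :math:`\\sigma^2` fixed at 1).

Estimation is REML. The criterion is profiled analytically over
:math:`\\sigma^2` so only the variance ratio
:math:`\\lambda = \\tau^2/\\sigma^2` is optimized, by deterministic
bounded scalar search. Per-coefficient denominator degrees of freedom use
the Satterthwaite approximation, with the variance of the variance
components taken from a finite-difference Hessian of the restricted
log-likelihood.

Usage follows statsmodels conventions::

    model = MetaRegression.from_dataframe(effects, fixed_effects=["quality"])
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MetaRegression", "MetaRegressionResults", "FIXED_EFFECT_SETS",
           "build_design"]

#: Named covariate sets for the published model objectives. "obj1" is the
#: magnitude model (applies to both the growth and the biomass arm);
#: "obj2.1" is the growth driver model; "obj2.2a/b/c" are the biomass
#: driver models.
FIXED_EFFECT_SETS: dict[str, list[str]] = {
    "obj1": ["months_since_removal", "n_species", "quality"],
    "obj2.1": ["months_since_removal", "repeated_removal", "removal_method",
               "disturbance", "dry_season_months", "precip_mm_yr", "temp_c",
               "elevation_m"],
    "obj2.2a": ["months_since_removal", "n_repeats"],
    "obj2.2b": ["months_since_removal", "repeated_removal"],
    "obj2.2c": ["months_since_removal", "n_repeats", "months_since_disturbance"],
}

# Reference levels for treatment coding of categorical covariates.
_REFERENCE_LEVELS = {
    "quality": "high",
    "disturbance": "logged",
    "removal_method": "whole_plot",
    "repeated_removal": False,
}


class RankDeficiencyError(ValueError):
    pass


def build_design(df: pd.DataFrame, fixed_effects: Sequence[str],
                 center: bool = True) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, treatment-coded categoricals and
    (optionally) mean-centred continuous covariates.

    Centring makes the intercept the summary effect at covariate means and
    at the categorical reference levels (e.g. quality = "high").
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for name in fixed_effects:
        if name not in df.columns:
            raise KeyError(f"fixed effect {name!r} not in table")
        col = df[name]
        if col.dtype == object or col.dtype == bool or str(col.dtype) == "category":
            levels = list(pd.unique(col.dropna()))
            ref = _REFERENCE_LEVELS.get(name)
            if ref not in levels:
                ref = levels[0]
            for lev in [l for l in levels if l != ref]:
                cols.append((col == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
        else:
            x = col.to_numpy(dtype=float)
            if np.isnan(x).any():
                raise ValueError(f"fixed effect {name!r} has missing values")
            if center:
                x = x - x.mean()
            cols.append(x)
            names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style scan
        bad = []
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                keep.append(j)
        raise RankDeficiencyError(f"design matrix rank deficient; collinear: {bad}")
    return X, names


class MetaRegression:
    """Inverse-variance-weighted mixed model for an effect-size table.

    Parameters
    ----------
    estimates, variances : array-like
        Effect sizes and their sampling variances (all variances > 0).
    groups : array-like
        Study identifier per effect (random-intercept grouping).
    exog : ndarray, optional
        Design matrix including intercept; defaults to intercept-only.
    exog_names : list of str, optional
    """

    def __init__(self, estimates, variances, groups, exog=None, exog_names=None):
        y = np.asarray(estimates, dtype=float)
        v = np.asarray(variances, dtype=float)
        g = np.asarray(groups)
        if y.ndim != 1 or y.shape != v.shape or y.shape[0] != g.shape[0]:
            raise ValueError("estimates, variances, groups must be equal-length 1-d")
        if np.isnan(v).any() or (v <= 0).any():
            raise ValueError("all sampling variances must be present and > 0")
        if np.isnan(y).any():
            raise ValueError("estimates contain missing values")
        if exog is None:
            exog = np.ones((len(y), 1))
            exog_names = ["intercept"]
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(X.shape[1])]

        # sort by group for contiguous-block Woodbury algebra
        order = np.argsort(g, kind="stable")
        self._order = order
        self.endog = y[order]
        self.variances = v[order]
        self.groups = g[order]
        self.exog = X[order]
        self.exog_names = list(exog_names)
        self.nobs = len(y)
        self.k_exog = X.shape[1]

        uniq, starts = np.unique(self.groups, return_index=True)
        starts = np.sort(starts)
        self._starts = starts
        self._group_sizes = np.diff(np.append(starts, self.nobs))
        self.n_groups = len(uniq)
        self._ainv = 1.0 / self.variances
        self._t_g = np.add.reduceat(self._ainv, starts)
        self._group_of = np.repeat(np.arange(self.n_groups), self._group_sizes)
        if self.n_groups < 2:
            raise ValueError("need at least 2 studies")
        if self.nobs <= self.k_exog:
            raise ValueError("fewer effects than fixed-effect parameters")

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       fixed_effects: Sequence[str] = (),
                       center: bool = True) -> "MetaRegression":
        """Build from an effect table with columns estimate, variance, study_id."""
        X, names = build_design(df, fixed_effects, center=center)
        return cls(df["estimate"].to_numpy(), df["variance"].to_numpy(),
                   df["study_id"].to_numpy(), exog=X, exog_names=names)

    # -- likelihood machinery ---------------------------------------------
    def _winv_apply(self, lam: float, M: np.ndarray) -> np.ndarray:
        """W(lam)^-1 M with W = diag(v) + lam * block-of-ones per study."""
        AM = self._ainv[:, None] * M
        colsum = np.add.reduceat(AM, self._starts, axis=0)
        shrink = (lam / (1.0 + lam * self._t_g))[:, None] * colsum
        return AM - self._ainv[:, None] * shrink[self._group_of]

    def _core(self, lam: float) -> dict:
        X, y = self.exog, self.endog
        WiX = self._winv_apply(lam, X)
        Wiy = self._winv_apply(lam, y[:, None])[:, 0]
        XtWX = X.T @ WiX
        XtWy = X.T @ Wiy
        ytWy = float(y @ Wiy)
        beta = np.linalg.solve(XtWX, XtWy)
        rss = ytWy - float(beta @ XtWy)
        rss = max(rss, 1e-300)
        logdetW = float(np.sum(np.log(self.variances))
                        + np.sum(np.log1p(lam * self._t_g)))
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        return dict(beta=beta, XtWX=XtWX, rss=rss, logdetW=logdetW,
                    logdetXtWX=logdetXtWX)

    def _profiled_neg2_reml(self, lam: float) -> float:
        c = self._core(lam)
        km = self.nobs - self.k_exog
        sigma2 = c["rss"] / km
        return km * math.log(sigma2) + c["logdetW"] + c["logdetXtWX"]

    def _restricted_loglike(self, tau2: float, sigma2: float) -> float:
        """Unprofiled restricted log-likelihood at (tau2, sigma2)."""
        lam = tau2 / sigma2
        c = self._core(lam)
        km = self.nobs - self.k_exog
        return -0.5 * (km * math.log(sigma2) + c["logdetW"] + c["logdetXtWX"]
                       + c["rss"] / sigma2 + km * math.log(2.0 * math.pi))

    # -- fitting -----------------------------------------------------------
    def fit(self, tau2: float | None = None, xtol: float = 1e-10
            ) -> "MetaRegressionResults":
        """REML fit; pass ``tau2=0`` (or any fixed value-ratio start) to fix
        the between-study variance instead of estimating it."""
        if tau2 is not None:
            # fixed tau2: profile sigma2 only if tau2 == 0; else optimize
            if tau2 == 0.0:
                lam = 0.0
                c = self._core(lam)
                sigma2 = c["rss"] / (self.nobs - self.k_exog)
                return self._results(lam, sigma2, c, converged=True,
                                     tau2_fixed=True)
            # general fixed tau2: 1-d REML in sigma2
            def nll(log_s2):
                return -self._restricted_loglike(tau2, math.exp(log_s2))
            r = optimize.minimize_scalar(nll, bounds=(-40, 40), method="bounded",
                                         options={"xatol": 1e-10})
            sigma2 = math.exp(r.x)
            lam = tau2 / sigma2
            return self._results(lam, sigma2, self._core(lam),
                                 converged=bool(r.success), tau2_fixed=True)

        # free tau2: optimize log-lambda, compare against the lam=0 boundary
        def obj(t: float) -> float:
            return self._profiled_neg2_reml(math.exp(t))

        r = optimize.minimize_scalar(obj, bounds=(-30.0, 30.0), method="bounded",
                                     options={"xatol": 1e-9})
        lam_opt = math.exp(r.x)
        val_opt = r.fun
        val_zero = self._profiled_neg2_reml(0.0)
        if val_zero <= val_opt or lam_opt < 1e-12:
            lam_opt = 0.0
        c = self._core(lam_opt)
        sigma2 = c["rss"] / (self.nobs - self.k_exog)
        return self._results(lam_opt, sigma2, c, converged=bool(r.success))

    def _results(self, lam: float, sigma2: float, core: dict,
                 converged: bool, tau2_fixed: bool = False
                 ) -> "MetaRegressionResults":
        tau2 = lam * sigma2
        cov = sigma2 * np.linalg.inv(core["XtWX"])
        dfs = self._satterthwaite(tau2, sigma2, cov, boundary=(lam == 0.0),
                                  skip=tau2_fixed)
        llf = self._restricted_loglike(tau2, sigma2) if sigma2 > 0 else np.nan
        fitted = self.exog @ core["beta"]
        return MetaRegressionResults(
            model=self, params=core["beta"], cov_params=cov, dfs=dfs,
            tau2=tau2, sigma2=sigma2, llf=llf, converged=converged,
            fittedvalues=fitted)

    def _cov_at(self, tau2: float, sigma2: float) -> np.ndarray:
        lam = tau2 / sigma2
        c = self._core(lam)
        return sigma2 * np.linalg.inv(c["XtWX"])

    def _satterthwaite(self, tau2: float, sigma2: float, cov: np.ndarray,
                       boundary: bool, skip: bool = False) -> np.ndarray:
        """Per-coefficient Satterthwaite df: 2*C_jj^2 / Var(C_jj), with
        Var(theta_hat) from the inverse FD Hessian of the restricted
        log-likelihood in theta = (tau2, sigma2)."""
        p = self.k_exog
        resid_df = float(max(self.nobs - p, 1))
        if skip:
            return np.full(p, resid_df)
        h_t = max(tau2, sigma2) * 1e-4 + 1e-12
        h_s = sigma2 * 1e-4 + 1e-12

        def ll(t2, s2):
            return self._restricted_loglike(max(t2, 0.0), max(s2, 1e-300))

        try:
            # FD Hessian; forward-shifted in tau2 at the boundary
            t0 = tau2 if not boundary else h_t
            H = np.empty((2, 2))
            f0 = ll(t0, sigma2)
            H[0, 0] = (ll(t0 + h_t, sigma2) - 2 * f0 + ll(t0 - h_t, sigma2)) / h_t**2
            H[1, 1] = (ll(t0, sigma2 + h_s) - 2 * f0 + ll(t0, sigma2 - h_s)) / h_s**2
            H[0, 1] = H[1, 0] = (
                ll(t0 + h_t, sigma2 + h_s) - ll(t0 + h_t, sigma2 - h_s)
                - ll(t0 - h_t, sigma2 + h_s) + ll(t0 - h_t, sigma2 - h_s)
            ) / (4 * h_t * h_s)
            A = np.linalg.inv(-H)  # approximate Var(tau2_hat, sigma2_hat)

            # gradient of each C_jj wrt theta
            c_tp = np.diag(self._cov_at(max(t0 + h_t, 0.0), sigma2))
            c_tm = np.diag(self._cov_at(max(t0 - h_t, 0.0), sigma2))
            c_sp = np.diag(self._cov_at(max(t0, 0.0), sigma2 + h_s))
            c_sm = np.diag(self._cov_at(max(t0, 0.0), sigma2 - h_s))
            g = np.stack([(c_tp - c_tm) / (2 * h_t),
                          (c_sp - c_sm) / (2 * h_s)])  # (2, p)
            var_c = np.einsum("ij,ik,kj->j", g, A, g)
            cjj = np.diag(cov)
            with np.errstate(divide="ignore", invalid="ignore"):
                df = 2.0 * cjj**2 / var_c
            df = np.where(np.isfinite(df) & (df > 0), df, resid_df)
            return np.minimum(np.maximum(df, 1.0), 10 * resid_df)
        except np.linalg.LinAlgError:
            return np.full(p, resid_df)


class MetaRegressionResults:
    """REML estimates with Satterthwaite t-based inference.

    Attributes mirror statsmodels results: ``params``, ``bse``,
    ``tvalues``, ``pvalues``, ``df`` (per-coefficient denominator df),
    ``tau2`` (between-study variance), ``sigma2`` (residual scale),
    ``conf_int()``, ``summary_frame()`` and ``summary()``.
    """

    def __init__(self, model: MetaRegression, params: np.ndarray,
                 cov_params: np.ndarray, dfs: np.ndarray, tau2: float,
                 sigma2: float, llf: float, converged: bool,
                 fittedvalues: np.ndarray):
        self.model = model
        self.exog_names = model.exog_names
        self.params = pd.Series(params, index=model.exog_names)
        self._cov = cov_params
        self.bse = pd.Series(np.sqrt(np.diag(cov_params)), index=model.exog_names)
        self.df = pd.Series(dfs, index=model.exog_names)
        self.tau2 = float(tau2)
        self.sigma2 = float(sigma2)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.fittedvalues = fittedvalues
        self.nobs = model.nobs
        self.n_groups = model.n_groups

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.params.index,
                            columns=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1 - alpha / 2.0, self.df)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def summary_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse, "df": self.df,
            "ci_low": ci["ci_low"], "ci_high": ci["ci_high"],
            "p": self.pvalues,
        })

    def summary(self, alpha: float = 0.05) -> str:
        head = (
            f"Weighted mixed-effects meta-regression (REML)\n"
            f"  effects: {self.nobs}   studies: {self.n_groups}\n"
            f"  tau2 (between-study): {self.tau2:.6g}   "
            f"sigma2 (residual scale): {self.sigma2:.6g}\n"
            f"  restricted log-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged}\n"
        )
        frame = self.summary_frame(alpha).round(4)
        return head + frame.to_string()

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MetaRegressionResults n={self.nobs} groups={self.n_groups} "
                f"tau2={self.tau2:.4g}>")
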