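"""Publication-bias diagnostics: Egger regression, year trend, fail-safe N.

Small-study (funnel-plot) asymmetry is tested by the Egger regression of
effect size on its standard error, weighted by inverse variance; a
nonzero SE coefficient indicates that small studies report systematically
different effects. Fail-safe numbers estimate how many unpublished null
studies would be needed to overturn the pooled result (Rosenthal:
unweighted z's; Rosenberg: inverse-variance weighted; Orwin: how many to
halve the mean effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EggerResult:
    slope: float        # coefficient on the standard error
    intercept: float
    se: float           # SE of the slope
    t: float
    df: int
    p: float


@dataclass
class TrendResult:
    slope: float        # change in effect per publication year
    se: float
    t: float
    df: int
    p: float


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ (w * resid)) / df if df > 0 else float("nan")
    cov = s2 * np.linalg.inv(XtWX)
    return beta, cov, df, s2


def egger_test(estimates, variances) -> EggerResult:
    """Weighted regression of y_i on se_i (weights 1/v_i); the two-sided
    t-test on the se coefficient is the asymmetry test."""
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) < 3 and len(y) != 2:
        raise ValueError("need at least 3 effects (2 gives an exact line)")
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        raise ValueError("all standard errors equal: asymmetry untestable "
                         "(se column collinear with intercept)")
    X = np.column_stack([np.ones_like(se), se])
    beta, cov, df, s2 = _wls(y, X, 1.0 / v)
    slope, intercept = float(beta[1]), float(beta[0])
    if df <= 0:
        return EggerResult(slope, intercept, float("nan"), float("nan"), 0,
                           float("nan"))
    slope_se = math.sqrt(max(cov[1, 1], 0.0))
    scale = max(1.0, float(np.mean(y**2)))
    if s2 <= 1e-12 * scale:
        # numerically exact fit; a flat line means no asymmetry
        flat = abs(slope) <= 1e-8 * math.sqrt(scale)
        return EggerResult(0.0 if flat else slope, intercept, 0.0,
                           0.0 if flat else math.inf, df,
                           1.0 if flat else 0.0)
    t = slope / slope_se
    return EggerResult(slope, intercept, slope_se, t, df,
                       float(2.0 * stats.t.sf(abs(t), df)))


def year_trend(estimates, variances, publication_years) -> TrendResult:
    """Inverse-variance weighted regression of effect size on publication
    year, probing whether later (presumably harder-to-publish) results
    drift from the first published finding."""
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    yr = np.asarray(publication_years, dtype=float)
    if len(np.unique(yr)) < 2:
        raise ValueError("need at least 2 distinct publication years")
    X = np.column_stack([np.ones_like(yr), yr - yr.mean()])
    beta, cov, df, _ = _wls(y, X, 1.0 / v)
    slope = float(beta[1])
    if df <= 0:
        return TrendResult(slope, float("nan"), float("nan"), 0, float("nan"))
    se = math.sqrt(max(cov[1, 1], 0.0))
    if se == 0.0:
        return TrendResult(slope, 0.0, math.inf if slope else 0.0, df,
                           0.0 if slope else 1.0)
    t = slope / se
    return TrendResult(slope, se, t, df, float(2.0 * stats.t.sf(abs(t), df)))


def fail_safe_n(estimates, variances, method: str = "rosenthal",
                alpha: float = 0.05, orwin_target: float | None = None) -> int:
    """Number of hypothetical null studies needed to overturn the result.

    rosenthal
        Classic file-drawer count from the summed z-scores, one-tailed
        alpha; floored (so N=10.3 reports 10).
    rosenberg
        Weighted analogue: smallest count of zero-effect studies of
        average weight whose addition makes the one-tailed p of the
        inverse-variance pooled estimate >= alpha.
    orwin
        ceil(k * (|mean effect| - target)/target); default target is half
        the observed unweighted mean effect.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = len(y)
    if k < 2:
        raise ValueError("need at least 2 effects")

    if method == "rosenthal":
        z = y / np.sqrt(v)
        z_alpha = stats.norm.ppf(1.0 - alpha)
        sum_z = float(np.sum(z))
        if sum_z / math.sqrt(k) <= z_alpha:
            return 0  # not significant to begin with
        return max(int(math.floor(sum_z**2 / z_alpha**2 - k)), 0)

    if method == "rosenberg":
        w = 1.0 / v
        sum_w, sum_wy = float(np.sum(w)), float(np.sum(w * y))
        z_alpha = stats.norm.ppf(1.0 - alpha)
        z0 = abs(sum_wy) / math.sqrt(sum_w)
        if z0 <= z_alpha:
            return 0
        w_bar = sum_w / k
        # smallest N with |sum_wy| / sqrt(sum_w + N*w_bar) <= z_alpha
        x = (sum_wy**2 / z_alpha**2 - sum_w) / w_bar
        n = int(math.ceil(x - 1e-12))
        return max(n, 0)

    if method == "orwin":
        d_bar = abs(float(np.mean(y)))
        target = orwin_target if orwin_target is not None else d_bar / 2.0
        if target <= 0 or d_bar <= target:
            return 0
        return int(math.ceil(k * (d_bar - target) / target - 1e-12))

    raise ValueError(f"unknown fail-safe method {method!r}")


def bias_diagnostics(table, alpha: float = 0.05,
                     year_column: str = "publication_year") -> dict:
    """All bias diagnostics for one completed effect table, as a flat dict
    suitable for the ``bias.csv`` export."""
    y = table["estimate"].to_numpy(dtype=float)
    v = table["variance"].to_numpy(dtype=float)
    out: dict = {"alpha": alpha}
    try:
        e = egger_test(y, v)
        out["egger"] = e
    except ValueError as exc:
        out["egger_error"] = str(exc)
    if year_column in table.columns and table[year_column].notna().all():
        try:
            out["year_trend"] = year_trend(y, v, table[year_column].to_numpy())
        except ValueError as exc:
            out["year_trend_error"] = str(exc)
    out["failsafe"] = {m: fail_safe_n(y, v, method=m, alpha=alpha)
                       for m in ("rosenthal", "rosenberg", "orwin")}
    return out


def forest_table(table) -> "pd.DataFrame":  # noqa: F821
    """(study, estimate, CI, weight) rows for forest/funnel rendering."""
    import pandas as pd
    se = np.sqrt(table["variance"].to_numpy(dtype=float))
    z = stats.norm.ppf(0.975)
    out = pd.DataFrame({
        "study_id": table["study_id"].to_numpy(),
        "comparison_id": table["comparison_id"].to_numpy(),
        "estimate": table["estimate"].to_numpy(dtype=float),
        "ci_low": table["estimate"].to_numpy(dtype=float) - z * se,
        "ci_high": table["estimate"].to_numpy(dtype=float) + z * se,
        "weight": 1.0 / table["variance"].to_numpy(dtype=float),
    })
    return out
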