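"""Per-comparison effect sizes: Hedges g (SMD) and raw mean difference.

The standardized mean difference d = (mean_t - mean_c)/s_pooled is
corrected for small-sample bias by J = 1 - 3/(4(n_t+n_c-2) - 1), giving
g = J*d with sampling variance var_g = J^2 * [ (n_t+n_c)/(n_t*n_c)
+ d^2 / (2(n_t+n_c)) ].  Positive g means faster growth / biomass
accumulation in the climber-removal plots than in the controls.

Rows whose reported group SDs are missing cannot supply a sampling
variance; they still receive an estimate (see :func:`build_effect_table`)
and the variance is filled in later by the imputation stage.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: covariates copied from the study table onto each effect size
COVARIATE_COLUMNS = (
    "months_since_removal", "n_species", "quality", "size_class", "region",
    "latitude", "elevation_m", "precip_mm_yr", "temp_c", "dry_season_months",
    "disturbance", "months_since_disturbance", "removal_method",
    "repeated_removal", "n_repeats", "months_disturbance_to_removal",
)


class DegenerateInputError(ValueError):
    """Zero pooled SD or too-small sample: no standardized effect exists."""


class Effect(NamedTuple):
    estimate: float
    variance: float  # NaN when not computable (missing SDs)


def _bias_correction(df_pooled: int) -> float:
    return 1.0 - 3.0 / (4.0 * df_pooled - 1.0)


def hedges_g(mean_t: float, sd_t: float, n_t: int,
             mean_c: float, sd_c: float, n_c: int) -> Effect:
    """Small-sample-corrected standardized mean difference and its variance."""
    n_t, n_c = int(n_t), int(n_c)
    if n_t + n_c < 3:
        raise DegenerateInputError(f"n_t + n_c = {n_t + n_c} < 3")
    df_pooled = n_t + n_c - 2
    s2 = ((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / df_pooled
    if not s2 > 0:
        raise DegenerateInputError("pooled SD is zero")
    d = (mean_t - mean_c) / math.sqrt(s2)
    J = _bias_correction(df_pooled)
    var_d = (n_t + n_c) / (n_t * n_c) + d**2 / (2.0 * (n_t + n_c))
    return Effect(J * d, J**2 * var_d)


def mean_difference(mean_t: float, sd_t: float, n_t: int,
                    mean_c: float, sd_c: float, n_c: int) -> Effect:
    """Raw mean difference; variance is NaN when either SD is missing."""
    md = mean_t - mean_c
    if pd.isna(sd_t) or pd.isna(sd_c):
        return Effect(md, float("nan"))
    var = sd_t**2 / n_t + sd_c**2 / n_c
    if var == 0.0:
        raise DegenerateInputError("both group SDs are zero: variance would be 0")
    return Effect(md, var)


def _fallback_pooled_sd(rows: pd.DataFrame) -> float:
    """Median pooled SD over rows with both SDs observed (salvage standardizer).

    Studies occasionally report group means without any dispersion; to keep
    such comparisons in the SMD analysis their estimate is standardized by a
    typical pooled SD of the same response metric, and the sampling variance
    is left missing for the imputation stage.
    """
    ok = rows.dropna(subset=["sd_t", "sd_c"])
    if ok.empty:
        raise DegenerateInputError(
            "no complete rows available to standardize SD-less comparisons"
        )
    nt, nc = ok["n_t"], ok["n_c"]
    s2 = ((nt - 1) * ok["sd_t"] ** 2 + (nc - 1) * ok["sd_c"] ** 2) / (nt + nc - 2)
    return float(np.median(np.sqrt(s2)))


def build_effect_table(rows: pd.DataFrame, response_metric: str = "growth",
                       measure: str = "smd") -> pd.DataFrame:
    """One effect size per comparison of the requested response metric.

    Returns a DataFrame with columns study_id, comparison_id, measure,
    estimate, variance, variance_was_imputed, plus all covariates and any
    extra columns of the input. Rows with degenerate inputs (zero pooled
    SD, n_t+n_c<3) are excluded with a logged warning; rows with missing
    SDs get a NaN variance for downstream imputation.
    """
    sub = rows[rows["response_metric"] == response_metric].copy()
    extra = [c for c in rows.columns if c not in
             ("response_metric", "growth_is_relative",
              "mean_t", "sd_t", "n_t", "mean_c", "sd_c", "n_c")]

    fallback_sd: float | None = None
    records, excluded = [], []
    for idx, r in sub.iterrows():
        try:
            missing_sd = pd.isna(r["sd_t"]) or pd.isna(r["sd_c"])
            if measure == "smd":
                if missing_sd:
                    if fallback_sd is None:
                        fallback_sd = _fallback_pooled_sd(sub)
                    sd = r["sd_t"] if pd.isna(r["sd_c"]) else r["sd_c"]
                    if pd.isna(sd):
                        sd = fallback_sd
                    d = (r["mean_t"] - r["mean_c"]) / sd
                    J = _bias_correction(int(r["n_t"] + r["n_c"] - 2))
                    eff = Effect(J * d, float("nan"))
                else:
                    eff = hedges_g(r["mean_t"], r["sd_t"], r["n_t"],
                                   r["mean_c"], r["sd_c"], r["n_c"])
            elif measure == "md":
                eff = mean_difference(r["mean_t"], r["sd_t"], r["n_t"],
                                      r["mean_c"], r["sd_c"], r["n_c"])
            else:
                raise ValueError(f"unknown measure {measure!r}")
        except DegenerateInputError as exc:
            logger.warning("excluding %s/%s: %s", r["study_id"], r["comparison_id"], exc)
            excluded.append((r["study_id"], r["comparison_id"], str(exc)))
            continue
        rec = {c: r[c] for c in extra}
        rec.update(measure=measure, estimate=eff.estimate, variance=eff.variance,
                   variance_was_imputed=False)
        records.append(rec)

    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(columns=["study_id", "comparison_id", "measure",
                                    "estimate", "variance", "variance_was_imputed"])
    lead = ["study_id", "comparison_id", "measure", "estimate", "variance",
            "variance_was_imputed"]
    out = out[[c for c in lead if c in out.columns]
              + [c for c in out.columns if c not in lead]]
    out.attrs["excluded_rows"] = excluded
    return out.reset_index(drop=True)
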