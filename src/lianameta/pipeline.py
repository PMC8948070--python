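"""End-to-end orchestration: effects -> impute -> fit -> pool -> Q/I2 ->
bias (-> extrapolation), honoring the sensitivity toggles (exclude
imputed rows, exclude studies, MD instead of SMD, alternative driver
formulas)."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import bias as bias_mod
from . import effects as eff_mod
from . import extrapolate as extrap_mod
from . import heterogeneity as het_mod
from . import impute as impute_mod
from .model import MetaRegression, build_design
from .pooling import pool_fits
from .study_io import AnalysisConfig, read_study_table, write_results

logger = logging.getLogger(__name__)


def run_pipeline(studies, config: AnalysisConfig, out_dir: str | Path | None = None,
                 scenarios_path: str | Path | None = None,
                 n_boot: int = 2000, save_imputations: bool = False,
                 model_label: str | None = None) -> dict:
    """Run one analysis arm; returns a dict of result objects/tables and,
    if ``out_dir`` is given, writes the CSV exports plus a run manifest.
    """
    if not isinstance(studies, pd.DataFrame):
        studies = read_study_table(studies)
    label = model_label or f"{config.response_metric}/{config.effect_measure}"

    if config.exclude_study_ids:
        studies = studies[~studies["study_id"].isin(config.exclude_study_ids)]
        studies = studies.reset_index(drop=True)

    effects = eff_mod.build_effect_table(
        studies, config.response_metric, config.effect_measure)
    if effects.empty:
        raise ValueError(f"no rows for response metric "
                         f"{config.response_metric!r}")
    excluded = effects.attrs.get("excluded_rows", [])

    if config.exclude_imputed_rows:
        effects = effects.dropna(subset=["variance"]).reset_index(drop=True)

    completed = impute_mod.impute_missing_variances(
        effects, m=config.m_imputations, master_seed=config.master_seed)

    fits, het_results = [], []
    design_cache = None
    for j, tab in enumerate(completed):
        model = MetaRegression.from_dataframe(tab, config.fixed_effects)
        fits.append(model.fit())
        X, _ = build_design(tab, config.fixed_effects)
        het_results.append(het_mod.assess_heterogeneity(
            tab, design=X, n_boot=n_boot,
            seed=config.master_seed + 7919 * (j + 1)))
    pooled = pool_fits(fits, rule=config.pooling_rule)
    het = het_mod.average_heterogeneity(het_results)

    # bias diagnostics on the first completed table (pre-pooling convention)
    diag = bias_mod.bias_diagnostics(completed[0], alpha=config.alpha)
    forest = bias_mod.forest_table(completed[0])

    results = {
        "label": label,
        "config": config,
        "effects": effects,
        "completed": completed,
        "fits": fits,
        "pooled": pooled,
        "heterogeneity": het,
        "bias": diag,
        "forest": forest,
        "excluded_rows": excluded,
        "summary_effect": pooled.summary_effect(config.alpha),
    }

    extrap = None
    if scenarios_path is not None:
        scenarios = extrap_mod.load_scenarios(scenarios_path)
        extrap = extrap_mod.extrapolation_table(scenarios)
        results["extrapolation"] = extrap

    if out_dir is not None:
        _export(results, Path(out_dir), save_imputations)
    return results


def _bias_rows(diag: dict, label: str) -> pd.DataFrame:
    rows = []
    if "egger" in diag:
        e = diag["egger"]
        rows.append({"model_label": label, "test": "egger", "statistic": e.slope,
                     "se": e.se, "df": e.df, "p": e.p,
                     "failsafe_method": None, "failsafe_n": None})
    if "year_trend" in diag:
        t = diag["year_trend"]
        rows.append({"model_label": label, "test": "year_trend",
                     "statistic": t.slope, "se": t.se, "df": t.df, "p": t.p,
                     "failsafe_method": None, "failsafe_n": None})
    for method, n in diag.get("failsafe", {}).items():
        rows.append({"model_label": label, "test": "fail_safe_n",
                     "statistic": None, "se": None, "df": None, "p": None,
                     "failsafe_method": method, "failsafe_n": n})
    return pd.DataFrame(rows)


def _export(results: dict, out_dir: Path, save_imputations: bool) -> None:
    label = results["label"]
    pooled = results["pooled"]
    model_summary = pooled.summary_frame().reset_index(names="coefficient")
    model_summary.insert(0, "model_label", label)
    model_summary["pooling_rule"] = pooled.pooling_rule

    het_df = pd.DataFrame([results["heterogeneity"].as_row(label)])
    tables = {
        "effects": results["effects"],
        "model_summary": model_summary,
        "heterogeneity": het_df,
        "bias": _bias_rows(results["bias"], label),
        "forest_plot": results["forest"],
    }
    if results.get("extrapolation") is not None:
        tables["extrapolation"] = results["extrapolation"]

    extra = {
        "master_seed": results["config"].master_seed,
        "excluded_rows": results["excluded_rows"],
        "summary_effect": {k: v for k, v in results["summary_effect"].items()},
    }
    write_results(tables, out_dir, config=results["config"],
                  extra_manifest=extra)
    if save_imputations:
        imp_dir = out_dir / "imputations"
        imp_dir.mkdir(exist_ok=True)
        for j, tab in enumerate(results["completed"], start=1):
            tab.to_csv(imp_dir / f"imputation_{j:02d}.csv", index=False,
                       float_format="%.12g")
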