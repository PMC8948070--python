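"""Synthetic study-level tables with the structure the analysis assumes.

The generator emulates an extracted climber-removal literature table:
studies contributing several treatment-vs-control comparisons (multiple
timepoints / tree size classes), a Normal between-study effect, covariate
gradients matching the reported study-context ranges (elevation 13-776 m,
precipitation 1144-2964 mm/yr, temperature 21.2-27.7 C, dry season 0-7
months, monitoring 12-228 months), and a fraction of rows whose group SDs
are unreported (missing variances).

True effects live on the SMD scale and are *back-converted* to group
summaries -- observed group means and SDs are then drawn from their
sampling distributions (Normal means, chi-scaled SDs) -- so the effects
module is genuinely exercised and the computed Hedges g carries realistic
sampling error with the variance its formula claims.

Covariate contributions (per-month slope, quality offsets) are applied as
deviations from the realized table mean of each continuous covariate, so
the generator's ``true_intercept`` is exactly the estimand of the fitted
model's (mean-centred, reference-level) intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import effects as eff_mod
from . import impute as impute_mod
from .model import MetaRegression, build_design
from .pooling import pool_fits

SIZE_CLASSES = ("all", ">=5cm_dbh", ">=10cm_dbh")


@dataclass
class SimConfig:
    """Generator settings; the defaults mirror the dimensions and context
    ranges of the synthesized literature (growth arm: 26 studies, 103
    comparisons)."""

    n_studies: int = 26
    total_comparisons: int = 103
    response_metric: str = "growth"
    true_intercept: float = 1.56
    tau_study: float = 0.5
    covariate_effects: dict = field(default_factory=lambda: {
        "months_since_removal": 0.01,
        "quality[medium]": -1.18,
        "quality[low]": -1.22,
        "n_species": 0.0,
    })
    group_n_range: tuple[int, int] = (3, 10)     # plots per arm
    sd_within: float = 1.0                       # within-arm response SD
    mean_control: float = 2.0                    # baseline control mean
    months_range: tuple[float, float] = (12.0, 228.0)
    elevation_range: tuple[float, float] = (13.0, 776.0)
    precip_range: tuple[float, float] = (1144.0, 2964.0)
    temp_range: tuple[float, float] = (21.2, 27.7)
    dry_season_range: tuple[int, int] = (0, 7)
    missing_variance_fraction: float = 0.2
    missing_mechanism: str = "mcar"              # or "mar" (small studies)
    publication_bias_strength: float = 0.0       # P(drop | one-sided p > .05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_variance_fraction <= 1.0:
            raise ValueError("missing_variance_fraction must lie in [0, 1]")
        if self.tau_study < 0 or self.sd_within < 0:
            raise ValueError("SDs must be >= 0")
        if self.total_comparisons < self.n_studies:
            raise ValueError("need at least one comparison per study")


def agb_config(**overrides) -> SimConfig:
    """The biomass-arm preset: 12 studies, 69 comparisons, intercept 2.09."""
    base = SimConfig(n_studies=12, total_comparisons=69,
                     response_metric="agb", true_intercept=2.09)
    return replace(base, **overrides)


def _study_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_studies
    region = rng.choice(["neotropics", "africa", "asia"], size=n,
                        p=[22 / 26, 2 / 26, 2 / 26])
    disturbance = rng.choice(
        ["none", "logged", "secondary", "logged+secondary"], size=n,
        p=[3 / 26, 13 / 26, 7 / 26, 3 / 26])
    quality = rng.choice(["high", "medium", "low"], size=n, p=[0.4, 0.4, 0.2])
    repeated = rng.random(n) < 0.4
    return pd.DataFrame({
        "study_id": [f"S{i+1:02d}" for i in range(n)],
        "region": region,
        "latitude": np.round(rng.uniform(-26.0, 23.0, n), 2),
        "elevation_m": np.round(rng.uniform(*cfg.elevation_range, n), 0),
        "precip_mm_yr": np.round(rng.uniform(*cfg.precip_range, n), 0),
        "temp_c": np.round(rng.uniform(*cfg.temp_range, n), 1),
        "dry_season_months": rng.integers(cfg.dry_season_range[0],
                                          cfg.dry_season_range[1] + 1, n),
        "disturbance": disturbance,
        "quality": quality,
        "removal_method": rng.choice(["whole_plot", "focal_tree"], size=n,
                                     p=[0.7, 0.3]),
        "repeated_removal": repeated,
        "n_repeats": np.where(repeated, rng.integers(1, 28, n), 0),
        "n_species": rng.integers(1, 51, n),
        "publication_year": rng.integers(1985, 2022, n),
    })


def generate_meta_dataset(config: SimConfig) -> pd.DataFrame:
    """A validated study table (one row per comparison) under the config.

    Deterministic for a fixed seed. ``months_since_disturbance`` is
    missing for undisturbed sites; ``sd_t``/``sd_c`` are blanked jointly
    for the missing-variance rows.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    studies = _study_frame(cfg, rng)

    sizes = rng.multinomial(cfg.total_comparisons - cfg.n_studies,
                            np.full(cfg.n_studies, 1.0 / cfg.n_studies)) + 1
    u_study = rng.normal(0.0, cfg.tau_study, cfg.n_studies)

    rows: list[dict] = []
    for s_idx, (_, st) in enumerate(studies.iterrows()):
        disturbed = st["disturbance"] != "none"
        msd = float(rng.uniform(1, 720)) if disturbed else np.nan
        mdr = float(rng.uniform(-12, 720))
        for c_idx in range(sizes[s_idx]):
            rows.append({
                **st.to_dict(),
                "comparison_id": f"C{c_idx+1:02d}",
                "response_metric": cfg.response_metric,
                "growth_is_relative": cfg.response_metric == "growth",
                "months_since_removal": float(rng.uniform(*cfg.months_range)),
                "size_class": SIZE_CLASSES[c_idx % len(SIZE_CLASSES)],
                "months_since_disturbance": msd,
                "months_disturbance_to_removal": mdr,
                "_u": u_study[s_idx],
            })
    df = pd.DataFrame(rows)

    # true SMD: intercept + covariate deviations from table means + u_study
    delta = np.full(len(df), cfg.true_intercept) + df["_u"].to_numpy()
    for name, beta in cfg.covariate_effects.items():
        if beta == 0.0:
            continue
        if name.startswith("quality["):
            level = name[len("quality["):-1]
            delta += beta * (df["quality"] == level).to_numpy(dtype=float)
        else:
            x = df[name].to_numpy(dtype=float)
            delta += beta * (x - x.mean())

    # back-convert to observed group summaries with sampling noise
    n_t = rng.integers(cfg.group_n_range[0], cfg.group_n_range[1] + 1, len(df))
    n_c = rng.integers(cfg.group_n_range[0], cfg.group_n_range[1] + 1, len(df))
    sd = cfg.sd_within
    mu_c = cfg.mean_control
    mu_t = mu_c + delta * sd
    mean_c = rng.normal(mu_c, sd / np.sqrt(n_c))
    mean_t = rng.normal(mu_t, sd / np.sqrt(n_t))
    sd_t = sd * np.sqrt(rng.chisquare(n_t - 1) / (n_t - 1))
    sd_c = sd * np.sqrt(rng.chisquare(n_c - 1) / (n_c - 1))

    df["mean_t"], df["sd_t"], df["n_t"] = mean_t, sd_t, n_t
    df["mean_c"], df["sd_c"], df["n_c"] = mean_c, sd_c, n_c
    df = df.drop(columns="_u")

    # optional publication censoring: drop "nonsignificant" comparisons
    if cfg.publication_bias_strength > 0:
        zish = (mean_t - mean_c) / (sd * np.sqrt(1 / n_t + 1 / n_c))
        nonsig = zish < 1.645
        drop = nonsig & (rng.random(len(df)) < cfg.publication_bias_strength)
        df = df[~drop].reset_index(drop=True)

    # blank SDs for the missing-variance rows
    frac = cfg.missing_variance_fraction
    if frac > 0:
        if cfg.missing_mechanism == "mar":
            total_n = (df["n_t"] + df["n_c"]).to_numpy(dtype=float)
            p = frac * (total_n.max() + 1 - total_n) / \
                np.mean(total_n.max() + 1 - total_n)
            p = np.clip(p, 0, 1)
        else:
            p = np.full(len(df), frac)
        miss = rng.random(len(df)) < p
        df.loc[miss, ["sd_t", "sd_c"]] = np.nan

    from .study_io import STUDY_COLUMNS
    ordered = [c for c in STUDY_COLUMNS] + \
        [c for c in df.columns if c not in STUDY_COLUMNS]
    return df[ordered]


def fit_pooled(study_table: pd.DataFrame, fixed_effects=("months_since_removal",
               "n_species", "quality"), m: int = 10, master_seed: int = 0,
               response_metric: str | None = None, measure: str = "smd",
               pooling_rule: str = "average"):
    """Convenience: effects -> imputation -> m weighted fits -> pooled."""
    metric = response_metric or study_table["response_metric"].iloc[0]
    table = eff_mod.build_effect_table(study_table, metric, measure)
    completed = impute_mod.impute_missing_variances(table, m=m,
                                                    master_seed=master_seed)
    fits = [MetaRegression.from_dataframe(t, fixed_effects).fit()
            for t in completed]
    return pool_fits(fits, rule=pooling_rule), completed


def end_to_end_recovery(config: SimConfig, n_replicates: int = 200,
                        m: int = 10,
                        fixed_effects=("months_since_removal", "n_species",
                                       "quality"),
                        alpha: float = 0.05) -> pd.DataFrame:
    """Generate -> effects -> impute -> fit -> pool, replicated; reports
    bias, RMSE and CI coverage per recovered parameter.

    Truth per parameter comes from the generator: the intercept is
    ``true_intercept``; covariate rows use the configured effects.
    """
    truths = {"intercept": config.true_intercept}
    for name, beta in config.covariate_effects.items():
        truths[name] = beta

    records: dict[str, list] = {}
    base = np.random.SeedSequence(config.seed)
    child_seeds = base.generate_state(n_replicates)
    for r in range(n_replicates):
        cfg = replace(config, seed=int(child_seeds[r] % (2**31 - 1)))
        table = generate_meta_dataset(cfg)
        pooled, _ = fit_pooled(table, fixed_effects=fixed_effects, m=m,
                               master_seed=cfg.seed)
        ci = pooled.conf_int(alpha)
        for name in pooled.params.index:
            if name not in truths:
                continue
            rec = records.setdefault(name, [])
            rec.append((float(pooled.params[name]),
                        float(ci.loc[name, "ci_low"]),
                        float(ci.loc[name, "ci_high"])))

    rows = []
    for name, rec in records.items():
        est = np.array([x[0] for x in rec])
        lo = np.array([x[1] for x in rec])
        hi = np.array([x[2] for x in rec])
        truth = truths[name]
        rows.append({
            "parameter": name, "truth": truth,
            "mean_estimate": est.mean(),
            "bias": est.mean() - truth,
            "rmse": float(np.sqrt(np.mean((est - truth) ** 2))),
            "coverage": float(np.mean((lo <= truth) & (truth <= hi))),
            "n_replicates": len(est),
        })
    return pd.DataFrame(rows)
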