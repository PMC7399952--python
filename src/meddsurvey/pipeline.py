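"""End-to-end study orchestration.

Stages, in fixed order: ingest recalls -> exclusion cascade (incomplete
recall pair, then no cognitive test at all, then the modified-z energy
screen) -> two-day averaging -> FPED-to-component mapping -> MedD scoring and
equal-size adherence tertiles -> education-stratified cognitive z-scores ->
design-based estimation. Outputs are tidy analogues of the study's result
tables:

* descriptives by adherence tertile (weighted means/proportions +/- SD),
* MedD component score means by tertile,
* survey-weighted OLS of each cognitive z-score on the continuous MedD score,
  unadjusted (Model 1) and adjusted for the 11 covariates (Model 2),
* survey-weighted logistic odds ratios of low cognitive performance across
  adherence tertiles (lowest = reference),
* the same logistic models refit in the no-memory-complaint subset with
  freshly computed tertiles (sensitivity),
* demographic mean-score comparisons with Tukey-adjusted pairwise p-values.

Education acts only through z-score standardization; it is not entered as a
model covariate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ingest
from .cognition import COGNITIVE_MEASURES, standardize_cognition
from .errors import ConfigurationError, ValidationError
from .scoring import (
    COMPONENT_NAMES,
    ScoreCutoffs,
    assign_tertiles,
    score_components,
)
from .simulate import CohortConfig, generate_cohort
from .survey import (
    SurveyDesign,
    SvyLogit,
    SvyOLS,
    four_year_weights,
    pairwise_contrasts_tukey,
    rao_scott_chisq,
    svy_mean,
    svy_proportion,
    svy_sd,
)

log = logging.getLogger("meddsurvey")

#: The 11 adjustment covariates (Model 2 / logistic models).
DEFAULT_COVARIATES = [
    "AGE",
    "SEX",
    "BMI",
    "RACE_ETH",
    "INC_POV_RATIO",
    "MARITAL",
    "SMOKER",
    "DIABETES",
    "CVD",
    "HYPERTENSION",
    "STROKE",
]

CONTINUOUS_COVARIATES = {"AGE", "BMI", "INC_POV_RATIO"}


@dataclass
class AnalysisConfig:
    """Configuration for a full analysis run."""

    recalls_csv: str | None = None
    participants_csv: str | None = None
    simulate: CohortConfig | None = None
    cutoffs: ScoreCutoffs = field(default_factory=ScoreCutoffs)
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    alpha: float = 0.05
    energy_cutoff: float = 3.5
    lonely_psu: str = "error"
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.simulate is None and (self.recalls_csv is None or self.participants_csv is None):
            raise ConfigurationError(
                "either a simulate block or both recalls_csv and participants_csv are required"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cutoffs = raw.pop("cutoffs", None)
        cfg = cls(
            simulate=CohortConfig(**sim) if sim is not None else None,
            cutoffs=ScoreCutoffs.from_dict(cutoffs) if cutoffs else ScoreCutoffs(),
            **raw,
        )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ResultTables:
    """Tidy result tables plus bookkeeping (per-model n, exclusions)."""

    descriptives: pd.DataFrame
    component_scores: pd.DataFrame
    ols_models: pd.DataFrame
    logistic_or: pd.DataFrame
    sensitivity_or: pd.DataFrame
    demographic_means: pd.DataFrame
    analysis_frame: pd.DataFrame = field(repr=False, default=None)
    model_n: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "descriptives": self.descriptives,
            "component_scores": self.component_scores,
            "ols_models": self.ols_models,
            "logistic_or": self.logistic_or,
            "sensitivity_or": self.sensitivity_or,
            "demographic_means": self.demographic_means,
        }


# ---------------------------------------------------------------------------
# stage helpers


def build_analysis_frame(
    recalls: pd.DataFrame,
    participants: pd.DataFrame,
    cutoffs: ScoreCutoffs,
    energy_cutoff: float = 3.5,
) -> tuple[pd.DataFrame, dict]:
    """Run ingest -> exclusions -> scoring -> z-scores; return one wide frame.

    The exclusion cascade drops, in order: participants without a complete
    two-day recall pair, participants with no cognitive test at all, and
    participants failing the modified-z energy screen. The returned frame has
    one row per retained participant with component intakes, component and
    total scores, tertile labels, z-scores and low flags, covariates and the
    4-year analysis weight (``WT4YR``).
    """
    exclusions = {}
    recalls = ingest.validate_recall_table(recalls.copy())
    intake, no_pair = ingest.average_recall_table(recalls)
    exclusions["incomplete_recalls"] = len(no_pair)

    df = intake.merge(participants, on="SEQN", how="inner", validate="1:1")
    cog_cols = ["CERAD_T1", "CERAD_T2", "CERAD_T3", "DSST", "AFT", "CERAD_DR"]
    no_cog = df[cog_cols].isna().all(axis=1)
    exclusions["no_cognition"] = int(no_cog.sum())
    df = df[~no_cog]

    kept, flagged = ingest.screen_energy_outliers(df, cutoff=energy_cutoff)
    exclusions["energy_outliers"] = len(flagged)
    df = kept.reset_index(drop=True)

    components = ingest.map_fped_to_components(df)
    scores = score_components(components, cutoffs)
    df = pd.concat(
        [df, components.drop(columns=["SEQN"]), scores.drop(columns=["SEQN"])], axis=1
    )
    tert = assign_tertiles(df.set_index("SEQN")["SCORE_TOTAL"])
    df["TERTILE"] = pd.Categorical(
        tert.to_numpy(), categories=["lowest", "middle", "highest"], ordered=True
    )
    df = standardize_cognition(df)
    df["WT4YR"] = four_year_weights(df["WTDRD_2DAY"].to_numpy())
    log.info("analysis frame: %d participants (exclusions: %s)", len(df), exclusions)
    return df, exclusions


def _design(df: pd.DataFrame, lonely_psu: str = "error") -> SurveyDesign:
    return SurveyDesign(df["SDMVSTRA"], df["SDMVPSU"], df["WT4YR"], lonely_psu=lonely_psu)


def _covariate_formula_terms(df: pd.DataFrame, covariates: list[str]) -> str:
    terms = []
    for cov in covariates:
        if cov not in df.columns:
            raise ConfigurationError(f"covariate column not found: {cov}")
        if cov in CONTINUOUS_COVARIATES or (
            pd.api.types.is_numeric_dtype(df[cov]) and df[cov].nunique() > 6
        ):
            terms.append(cov)
        else:
            terms.append(f"C({cov})")
    return " + ".join(terms)


def _masked(values: pd.Series, mask: pd.Series) -> np.ndarray:
    out = values.astype(float).to_numpy().copy()
    out[~mask.to_numpy(dtype=bool)] = np.nan
    return out


def _fmt_est(res) -> dict:
    return {"estimate": res.estimate, "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high}


# ---------------------------------------------------------------------------
# result tables


def descriptives_table(df: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Weighted descriptives (mean +/- SD or %) overall and by tertile."""
    rows = []
    tert = df["TERTILE"]
    groups = {"All": pd.Series(True, index=df.index)}
    groups.update({t: tert == t for t in ("lowest", "middle", "highest")})

    def add_continuous(label, col):
        row = {"variable": label, "kind": "mean_sd"}
        for gname, gmask in groups.items():
            vals = _masked(df[col], gmask & df[col].notna())
            m, s = svy_mean(vals, design), svy_sd(vals, design)
            row[f"{gname}_mean"], row[f"{gname}_sd"] = m.estimate, s.estimate
        contrasts = pairwise_contrasts_tukey(tert, df[col].astype(float), design)
        lh = contrasts[
            (contrasts["group_a"] == "highest") & (contrasts["group_b"] == "lowest")
        ]
        row["p"] = float(lh["p_adjusted"].iloc[0]) if len(lh) else np.nan
        rows.append(row)

    def add_categorical(label, col):
        chi = rao_scott_chisq(df[col], tert, design)
        for level in sorted(df[col].dropna().unique(), key=str):
            row = {"variable": f"{label}: {level}", "kind": "percent", "p": chi.p}
            ind = (df[col] == level).astype(float)
            ind[df[col].isna()] = np.nan
            for gname, gmask in groups.items():
                vals = _masked(pd.Series(ind), gmask & df[col].notna())
                row[f"{gname}_mean"] = 100 * svy_proportion(vals, design).estimate
                row[f"{gname}_sd"] = np.nan
            rows.append(row)

    add_continuous("Age, y", "AGE")
    add_categorical("Sex", "SEX")
    add_continuous("BMI, kg/m2", "BMI")
    add_categorical("Race/Ethnicity", "RACE_ETH")
    add_categorical("Education", "EDU_LEVEL")
    add_categorical("Marital Status", "MARITAL")
    add_continuous("Family Income/Poverty Ratio", "INC_POV_RATIO")
    for label, col in (
        ("Diabetes, % Yes", "DIABETES"),
        ("Hypertension, % Yes", "HYPERTENSION"),
        ("Cardiovascular Disease, % Yes", "CVD"),
        ("Stroke, % Yes", "STROKE"),
        ("Smoking Status, % Yes", "SMOKER"),
    ):
        chi = rao_scott_chisq(df[col], tert, design)
        row = {"variable": label, "kind": "percent", "p": chi.p}
        for gname, gmask in groups.items():
            vals = _masked(df[col].astype(float), gmask & df[col].notna())
            row[f"{gname}_mean"] = 100 * svy_proportion(vals, design).estimate
            row[f"{gname}_sd"] = np.nan
        rows.append(row)
    add_continuous("Mediterranean Diet Score", "SCORE_TOTAL")
    for label, col in [
        ("CERAD Immediate Learning", "CERAD_IMM"),
        ("Digit Symbol Substitution Test", "DSST"),
        ("Animal Fluency Test", "AFT"),
        ("CERAD Delayed Recall", "CERAD_DR"),
        ("Global Cognition", "Z_GLOBAL"),
    ]:
        add_continuous(label, col)
    return pd.DataFrame(rows)


def component_scores_table(df: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Weighted mean component scores, overall and by adherence tertile."""
    rows = []
    tert = df["TERTILE"]
    groups = {"All": pd.Series(True, index=df.index)}
    groups.update({t: tert == t for t in ("lowest", "middle", "highest")})
    for name in COMPONENT_NAMES:
        col = f"SCORE_{name.upper()}"
        row = {"component": name}
        for gname, gmask in groups.items():
            vals = _masked(df[col], gmask)
            row[f"{gname}_mean"] = svy_mean(vals, design).estimate
            row[f"{gname}_sd"] = svy_sd(vals, design).estimate
        contrasts = pairwise_contrasts_tukey(tert, df[col].astype(float), design)
        lh = contrasts[
            (contrasts["group_a"] == "highest") & (contrasts["group_b"] == "lowest")
        ]
        row["p"] = float(lh["p_adjusted"].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)


def ols_models_table(
    df: pd.DataFrame, design: SurveyDesign, covariates: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Model 1 (score only) and Model 2 (score + covariates) per cognitive measure."""
    rows, model_n = [], {}
    cov_terms = _covariate_formula_terms(df, covariates)
    data = df.copy()
    for measure, (zcol, _) in COGNITIVE_MEASURES.items():
        for model, formula in (
            ("Model 1", f"{zcol} ~ SCORE_TOTAL"),
            ("Model 2", f"{zcol} ~ SCORE_TOTAL + {cov_terms}"),
        ):
            res = SvyOLS.from_formula(formula, data, design).fit()
            ci = res.conf_int()
            rows.append(
                {
                    "measure": measure,
                    "model": model,
                    "beta": res.params["SCORE_TOTAL"],
                    "se": res.bse["SCORE_TOTAL"],
                    "ci_low": ci.loc["SCORE_TOTAL", "ci_low"],
                    "ci_high": ci.loc["SCORE_TOTAL", "ci_high"],
                    "p": res.pvalues["SCORE_TOTAL"],
                    "n": res.nobs,
                }
            )
            model_n[f"ols/{measure}/{model}"] = res.nobs
    return pd.DataFrame(rows), model_n


def logistic_or_table(
    df: pd.DataFrame,
    design: SurveyDesign,
    covariates: list[str],
    tertile_column: str = "TERTILE",
) -> tuple[pd.DataFrame, dict]:
    """Odds ratios of low cognitive performance for middle/highest vs lowest."""
    rows, model_n = [], {}
    cov_terms = _covariate_formula_terms(df, covariates)
    data = df.copy()
    data["_TERT"] = pd.Categorical(
        data[tertile_column].astype(str), categories=["lowest", "middle", "highest"], ordered=False
    )
    for measure, (_, lowcol) in COGNITIVE_MEASURES.items():
        formula = f"{lowcol} ~ C(_TERT) + {cov_terms}" if cov_terms else f"{lowcol} ~ C(_TERT)"
        res = SvyLogit.from_formula(formula, data, design).fit()
        ors = res.odds_ratios()
        model_n[f"logistic/{measure}"] = res.nobs
        for tert in ("middle", "highest"):
            term = f"C(_TERT)[T.{tert}]"
            rows.append(
                {
                    "measure": measure,
                    "tertile": tert,
                    "or": ors.loc[term, "or"],
                    "ci_low": ors.loc[term, "ci_low"],
                    "ci_high": ors.loc[term, "ci_high"],
                    "p": ors.loc[term, "p"],
                    "n": res.nobs,
                }
            )
    return pd.DataFrame(rows), model_n


AGE_BINS = [(60, 65, "60-64.9"), (65, 70, "65-69.9"), (70, 75, "70-74.9"),
            (75, 80, "75-79.9"), (80, 200, "80+")]


def demographic_means_table(df: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Mean MedD score by demographic group with Tukey-adjusted pairwise p."""
    data = df.copy()
    age = data["AGE"].astype(float)
    data["AGE_GROUP"] = pd.cut(
        age, bins=[b[0] for b in AGE_BINS] + [200],
        labels=[b[2] for b in AGE_BINS], right=False,
    ).astype(object)
    inc = data["INC_POV_RATIO"].astype(float)
    data["INCOME_GROUP"] = pd.cut(
        inc, bins=[-np.inf, 1, 2, np.inf], labels=["<1", "1-2", ">2"]
    ).astype(object)
    data["DIABETES_GROUP"] = np.where(data["DIABETES"].astype(float) == 1, "Yes", "No")
    characteristics = {
        "Sex": "SEX",
        "Age": "AGE_GROUP",
        "Race/Ethnicity": "RACE_ETH",
        "Education": "EDU_LEVEL",
        "Income to Poverty Ratio": "INCOME_GROUP",
        "Marital Status": "MARITAL",
        "Diabetes Status": "DIABETES_GROUP",
    }
    rows = []
    score = data["SCORE_TOTAL"].astype(float)
    for char, col in characteristics.items():
        contrasts = pairwise_contrasts_tukey(data[col], score, design)
        for level in sorted(data[col].dropna().unique(), key=str):
            mask = (data[col] == level) & data[col].notna()
            est = svy_mean(_masked(score, mask), design)
            sd = svy_sd(_masked(score, mask), design)
            pair = contrasts[
                ((contrasts["group_a"] == level) | (contrasts["group_b"] == level))
            ]
            rows.append(
                {
                    "characteristic": char,
                    "group": level,
                    "n": int(mask.sum()),
                    "mean": est.estimate,
                    "sd": sd.estimate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "min_pairwise_p": float(pair["p_adjusted"].min()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level operations


def run_full_analysis(config: AnalysisConfig) -> ResultTables:
    """Execute the whole study on real CSV inputs or a simulated cohort."""
    t0 = time.monotonic()
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        recalls, participants = cohort.recalls, cohort.participants
    else:
        recalls = ingest.read_recall_table(config.recalls_csv)
        participants = pd.read_csv(config.participants_csv)
    df, exclusions = build_analysis_frame(
        recalls, participants, config.cutoffs, config.energy_cutoff
    )
    design = _design(df, config.lonely_psu)
    log.info("design: %d strata, %d PSUs, df=%d", design.n_strata, design.n_psus, design.df)

    descr = descriptives_table(df, design)
    comp = component_scores_table(df, design)
    ols, n_ols = ols_models_table(df, design, config.covariates)
    logi, n_logi = logistic_or_table(df, design, config.covariates)
    sens, n_sens = run_sensitivity(config, df)
    demo = demographic_means_table(df, design)
    model_n = {**n_ols, **n_logi, **{f"sensitivity/{k}": v for k, v in n_sens.items()}}
    log.info("analysis complete in %.1fs", time.monotonic() - t0)
    return ResultTables(
        descriptives=descr,
        component_scores=comp,
        ols_models=ols,
        logistic_or=logi,
        sensitivity_or=sens,
        demographic_means=demo,
        analysis_frame=df,
        model_n=model_n,
        exclusions=exclusions,
    )


def run_sensitivity(
    config: AnalysisConfig, analysis_frame: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Refit the logistic models among participants without memory complaints.

    Adherence tertiles are recomputed within the subset (fresh cut points,
    not the full-cohort boundaries) before refitting.
    """
    if "MEMORY_COMPLAINT" not in analysis_frame.columns:
        raise ValidationError("MEMORY_COMPLAINT column required for the sensitivity analysis")
    sub = analysis_frame[analysis_frame["MEMORY_COMPLAINT"].astype(float) == 0].copy()
    if len(sub) < 3:
        raise ValidationError(f"sensitivity subset has {len(sub)} participants (<3)")
    sub = sub.reset_index(drop=True)
    sub["TERTILE_SENS"] = assign_tertiles(sub.set_index("SEQN")["SCORE_TOTAL"]).to_numpy()
    design = _design(sub, config.lonely_psu)
    table, model_n = logistic_or_table(
        sub, design, config.covariates, tertile_column="TERTILE_SENS"
    )
    table.insert(0, "analysis", "no_memory_complaints")
    return table, model_n


def write_outputs(tables: ResultTables, directory, config: AnalysisConfig | None = None) -> dict:
    """Write one CSV per result table plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, tbl in tables.tables().items():
        path = directory / f"{name}.csv"
        tbl.to_csv(path, index=False, float_format="%.10g")
        paths[name] = str(path)
    manifest = {
        "software": f"meddsurvey {__version__}",
        "n_participants": int(len(tables.analysis_frame)) if tables.analysis_frame is not None else None,
        "exclusions": tables.exclusions,
        "model_n": tables.model_n,
        "tables": paths,
    }
    if config is not None:
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        manifest["seed"] = config.seed
        manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    paths["manifest"] = str(directory / "manifest.json")
    return paths
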