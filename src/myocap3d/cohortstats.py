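"""Cohort-level aggregation and statistical models.

The study design is hierarchical: repeated fields of view nest within
subject × muscle, four muscles nest within subject, and subjects belong to a
CTRL or T2DM group. Capillary outcomes are modelled per muscle with linear
mixed-effects models (random intercept per subject; fixed effects group, age,
BMI; optional sensitivity terms age², group×age, mean fibre diameter),
fibre-level outcomes with two-way ANOVA (group × fibre type) plus Tukey post
hoc tests, the within-subject muscle hierarchy with paired t-tests and a
repeated-measures model ``outcome ~ group × muscle + age + BMI + (1|subject)``,
and HbA1c associations within the T2DM subgroup with age/BMI-adjusted linear
models. A cohort simulator with the same hierarchy supports type-I-error and
effect-recovery calibration.

Mixed models are fitted by restricted maximum likelihood. Statsmodels
reports Wald z inference for mixed models; p-values and confidence intervals
here instead use a between-within t approximation with
``df = n_subjects − n_fixed_effects`` (normal approximation retained as the
fallback when a fit does not converge).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import SingularFitWarning

__all__ = [
    "MUSCLES",
    "CohortDesign",
    "ModelResult",
    "simulate_cohort",
    "subject_level_means",
    "fit_group_model",
    "twoway_anova_tukey",
    "within_subject_hierarchy",
    "hba1c_association",
]

MUSCLES = ("DIA", "SC", "EXT", "VL")


@dataclass
class ModelResult:
    """Adjusted effect estimate with CI and two-sided p-value."""

    term: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    df: float
    covariates: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    singular: bool = False

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "df": self.df,
            "converged": self.converged,
            "singular": self.singular,
            "covariates": self.covariates,
        }


# ----------------------------------------------------------------- simulator
@dataclass
class CohortDesign:
    """Generative design of a synthetic autopsy cohort.

    Defaults follow the study conditions: 24 male subjects per group, four
    muscles each, five fields of view per muscle; age ≈ N(70, 10) in both
    groups; BMI ≈ N(24.8, 2.7) in CTRL versus N(31.9, 4.7) in T2DM; HbA1c
    below 5.7% in CTRL and ≈ N(6.9, 1.1) in T2DM. ``muscle_means`` sets the
    CTRL outcome level per muscle; ``group_effects`` the additive T2DM offset
    (scalar or per muscle); variance components split subject-level
    heterogeneity from field-to-field noise.
    """

    n_per_group: int = 24
    n_fields: int = 5
    muscles: tuple[str, ...] = MUSCLES
    outcome: str = "LVf"
    muscle_means: dict[str, float] = field(
        default_factory=lambda: {"DIA": 20.09, "SC": 13.64, "EXT": 12.57, "VL": 10.13}
    )
    group_effects: dict[str, float] | float = 0.0
    sd_subject: float = 2.0
    sd_field: float = 1.0
    age_mean: float = 70.0
    age_sd: float = 10.0
    bmi_ctrl: tuple[float, float] = (24.8, 2.7)
    bmi_t2dm: tuple[float, float] = (31.9, 4.7)
    hba1c_ctrl: tuple[float, float] = (5.3, 0.2)
    hba1c_t2dm: tuple[float, float] = (6.9, 1.1)
    age_slope: float = 0.0
    bmi_slope: float = 0.0
    hba1c_slope: float = 0.0  # applies within T2DM only

    def __post_init__(self):
        if self.sd_subject < 0 or self.sd_field < 0:
            raise ValueError("variance components must be non-negative")

    def effect_for(self, muscle: str) -> float:
        if isinstance(self.group_effects, dict):
            return float(self.group_effects.get(muscle, 0.0))
        return float(self.group_effects)


def simulate_cohort(design: CohortDesign, seed: int = 0) -> pd.DataFrame:
    """Draw one synthetic cohort table (one row per field of view).

    Columns: subject, group, age, BMI, HbA1c, muscle, field, outcome, value.
    Deterministic for a fixed seed; with both variance components zero the
    values equal the design means plus covariate terms exactly.
    """
    rng = np.random.default_rng([int(seed), 23])
    rows = []
    sid = 0
    for group in ("CTRL", "T2DM"):
        bmi_mu, bmi_sd = design.bmi_ctrl if group == "CTRL" else design.bmi_t2dm
        h_mu, h_sd = design.hba1c_ctrl if group == "CTRL" else design.hba1c_t2dm
        for _ in range(design.n_per_group):
            sid += 1
            age = rng.normal(design.age_mean, design.age_sd)
            bmi = rng.normal(bmi_mu, bmi_sd)
            hba1c = rng.normal(h_mu, h_sd)
            u = rng.normal(0.0, design.sd_subject) if design.sd_subject > 0 else 0.0
            for muscle in design.muscles:
                base = design.muscle_means[muscle]
                if group == "T2DM":
                    base += design.effect_for(muscle)
                    base += design.hba1c_slope * (hba1c - design.hba1c_t2dm[0])
                base += design.age_slope * (age - design.age_mean)
                base += design.bmi_slope * (bmi - design.bmi_ctrl[0])
                for fov in range(design.n_fields):
                    eps = rng.normal(0.0, design.sd_field) if design.sd_field > 0 else 0.0
                    rows.append(
                        {
                            "subject": f"S{sid:03d}",
                            "group": group,
                            "age": age,
                            "BMI": bmi,
                            "HbA1c": hba1c,
                            "muscle": muscle,
                            "field": fov,
                            "outcome": design.outcome,
                            "value": base + u + eps,
                        }
                    )
    return pd.DataFrame(rows)


def subject_level_means(table: pd.DataFrame, outcome: str | None = None) -> pd.DataFrame:
    """Average the field-level values to one row per subject × muscle.

    Invariant to the ordering of fields; carries the subject covariates along.
    """
    df = table if outcome is None else table[table["outcome"] == outcome]
    keys = ["subject", "group", "age", "BMI", "HbA1c", "muscle"]
    return df.groupby(keys, as_index=False)["value"].mean()


# ------------------------------------------------------------- mixed models
def _mixed_fit(df: pd.DataFrame, formula: str, term: str) -> ModelResult:
    """REML mixed model with subject random intercept; between-within t inference."""
    singular = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        try:
            fit = model.fit(reml=True)
        except Exception:
            converged = False
            fit = None
        if fit is not None:
            for w in caught:
                if issubclass(w.category, ConvergenceWarning) or "singular" in str(w.message).lower():
                    singular = True
    if fit is None or not np.isfinite(fit.params.get(term, np.nan)):
        # degenerate data (e.g. zero noise): fall back to OLS on the same formula
        ols = smf.ols(formula, df).fit()
        beta = float(ols.params[term])
        se = float(ols.bse[term])
        singular = True
        params = ols.params
        bse = ols.bse
    else:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        params = fit.params
        bse = fit.bse
    if singular:
        warnings.warn(
            "singular or non-converged mixed-model fit; estimates returned with caution",
            SingularFitWarning,
            stacklevel=3,
        )
    n_subjects = df["subject"].nunique()
    n_fixed = len([k for k in params.index if k != "Group Var"])
    dof = max(n_subjects - n_fixed, 1)
    if se > 0 and np.isfinite(se):
        tval = beta / se
        p = float(2 * stats.t.sf(abs(tval), dof))
        crit = stats.t.ppf(0.975, dof)
        ci = (beta - crit * se, beta + crit * se)
    else:
        p, ci = (1.0, (beta, beta)) if beta == 0 else (0.0, (beta, beta))
    covs = {
        k: float(params[k]) for k in params.index if k not in (term, "Group Var", "Intercept")
    }
    return ModelResult(
        term=term, beta=beta, ci_low=ci[0], ci_high=ci[1], p=max(p, np.finfo(float).tiny),
        df=dof, covariates=covs, converged=converged, singular=singular,
    )


def fit_group_model(
    table: pd.DataFrame,
    outcome: str,
    muscle: str,
    extras: tuple[str, ...] = (),
) -> ModelResult:
    """Adjusted T2DM-vs-CTRL effect on one outcome in one muscle.

    Linear mixed model on the field-level values with a subject random
    intercept and fixed effects group, age and BMI. ``extras`` may include
    ``"age2"`` (quadratic age), ``"group_by_age"`` (group × age interaction)
    and ``"fibre_diameter_covariate"`` (requires a ``fibre_diameter`` column).
    Returns the group effect β with 95% CI and two-sided p.
    """
    df = table[(table["outcome"] == outcome) & (table["muscle"] == muscle)].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r} in muscle {muscle!r}")
    if df.groupby("group")["subject"].nunique().min() < 2 or df["group"].nunique() < 2:
        raise ValueError("need at least two subjects per group")
    df["group_t2dm"] = (df["group"] == "T2DM").astype(float)
    rhs = ["group_t2dm", "age", "BMI"]
    if "age2" in extras:
        df["age_sq"] = df["age"] ** 2
        rhs.append("age_sq")
    if "group_by_age" in extras:
        rhs.append("group_t2dm:age")
    if "fibre_diameter_covariate" in extras:
        if "fibre_diameter" not in df.columns:
            raise ValueError("fibre_diameter column required for that covariate")
        rhs.append("fibre_diameter")
    unknown = set(extras) - {"age2", "group_by_age", "fibre_diameter_covariate"}
    if unknown:
        raise ValueError(f"unknown extras: {sorted(unknown)}")
    return _mixed_fit(df, "value ~ " + " + ".join(rhs), "group_t2dm")


def twoway_anova_tukey(subject_means: pd.DataFrame, value: str = "value") -> dict:
    """Two-way ANOVA (group × fibre type) with Tukey post hoc comparisons.

    Input is one row per subject × fibre type with columns ``group``,
    ``fibre_type`` and the value column. Returns the ANOVA table (type II)
    and the Tukey HSD table over all group/fibre-type cells.
    """
    df = subject_means.copy()
    for fac in ("group", "fibre_type"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac!r} needs at least two levels")
    cells = df.groupby(["group", "fibre_type"]).size()
    full = pd.MultiIndex.from_product([df["group"].unique(), df["fibre_type"].unique()])
    empty = [c for c in full if c not in cells.index or cells.get(c, 0) == 0]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    ols = smf.ols(f"{value} ~ C(group) * C(fibre_type)", df).fit()
    table = anova_lm(ols, typ=2)
    labels = df["group"].astype(str) + "/" + df["fibre_type"].astype(str)
    tukey = pairwise_tukeyhsd(df[value].to_numpy(), labels.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"anova": table, "tukey": tukey_df}


def within_subject_hierarchy(table: pd.DataFrame, outcome: str) -> dict:
    """Intermuscular ordering of an outcome within subjects.

    Subjects missing any muscle are excluded listwise (and reported). Every
    muscle pair is compared with a paired t-test on subject means; a
    repeated-measures mixed model ``value ~ group × muscle + age + BMI`` with
    a subject random intercept estimates group-by-muscle interactions. The
    returned ``order`` ranks muscles by mean, with ``p < 0.01`` pairs marked
    as strict inequalities and others as ``≈``.
    """
    means = subject_level_means(table, outcome)
    muscles = [m for m in MUSCLES if m in set(means["muscle"])]
    wide = means.pivot_table(index="subject", columns="muscle", values="value")
    complete = wide.dropna(subset=muscles)
    excluded = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise ValueError(f"only {len(complete)} complete subjects (need ≥ 3)")
    pairs = []
    for i, a in enumerate(muscles):
        for b in muscles[i + 1 :]:
            diffs = (complete[a] - complete[b]).to_numpy()
            if np.allclose(diffs, 0.0):
                t, p = 0.0, 1.0  # identical values: no evidence either way
            elif np.isclose(diffs.std(ddof=1), 0.0):
                t, p = np.sign(diffs.mean()) * np.inf, 0.0  # constant offset
            else:
                t, p = stats.ttest_rel(complete[a], complete[b])
            pairs.append(
                {"muscle_a": a, "muscle_b": b, "mean_diff": float((complete[a] - complete[b]).mean()),
                 "t": float(t), "p": float(p)}
            )
    pair_df = pd.DataFrame(pairs)
    ranked = complete[muscles].mean().sort_values(ascending=False)

    def pair_p(a, b):
        row = pair_df[((pair_df.muscle_a == a) & (pair_df.muscle_b == b))
                      | ((pair_df.muscle_a == b) & (pair_df.muscle_b == a))]
        return float(row["p"].iloc[0])

    marks = []
    names = list(ranked.index)
    for a, b in zip(names[:-1], names[1:]):
        marks.append(" > " if pair_p(a, b) < 0.01 else " ≈ ")
    order = "".join(n + m for n, m in zip(names, marks + [""]))

    df = means.copy()
    df["group_t2dm"] = (df["group"] == "T2DM").astype(float)
    df["value"] = df["value"].astype(float)
    rm = _mixed_fit(df, "value ~ group_t2dm * C(muscle) + age + BMI", "group_t2dm")
    return {
        "order": order,
        "ranking": ranked.to_dict(),
        "paired_tests": pair_df,
        "excluded_subjects": excluded,
        "repeated_measures_model": rm,
    }


def hba1c_association(table: pd.DataFrame, outcome: str, muscle: str | None = None) -> ModelResult:
    """HbA1c slope on a structural outcome within the T2DM subgroup.

    Ordinary linear model on subject-level means adjusted for age and BMI.
    """
    df = table[(table["group"] == "T2DM") & (table["outcome"] == outcome)]
    if muscle is not None:
        df = df[df["muscle"] == muscle]
    means = subject_level_means(df)
    if means.empty:
        raise ValueError("no T2DM rows for that outcome/muscle")
    if means["HbA1c"].isna().any():
        raise ValueError("HbA1c missing for retained rows")
    if np.ptp(means["HbA1c"].to_numpy()) < 1e-12:
        raise ValueError("HbA1c is constant; association model is unidentifiable")
    fit = smf.ols("value ~ HbA1c + age + BMI", means).fit()
    beta = float(fit.params["HbA1c"])
    ci = fit.conf_int().loc["HbA1c"]
    return ModelResult(
        term="HbA1c",
        beta=beta,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues["HbA1c"]),
        df=float(fit.df_resid),
        covariates={"age": float(fit.params["age"]), "BMI": float(fit.params["BMI"]),
                    "r_squared": float(fit.rsquared)},
        converged=True,
    )
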