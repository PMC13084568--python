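"""The two growth SEMs (weight- and BMI-based), the analysis frame that
feeds them, residual/assumption diagnostics, and the descriptive group
comparisons.

The analysis frame pools the 12- and 18-mo plasma rows (age entering as a
two-level covariate) and attaches the cumulative protein AUC ending at the
row's age.  Only listwise-complete rows are analyzed; infants missing any
of the four dietary records are excluded by the AUC completeness rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EmptyFrame
from .intake import cumulative_auc, zscore
from .panel import metabolite_column
from .sem import (
    SEMFit,
    SEMSpec,
    fit_indices,
    fit_ml,
    modification_indices,
    parse_model,
    robust_adjust,
)

__all__ = [
    "MODEL_VARIABLES",
    "build_frame",
    "weight_model_spec",
    "bmi_model_spec",
    "run_sem_pipeline",
    "residual_diagnostics",
    "group_compare",
    "proxy_validation",
    "significance_stars",
    "diagram_dot",
]

#: shared covariates of both growth models, in frame-column names
MODEL_VARIABLES = [
    "z_prot_auc",
    "ln_bcaa",
    "ln_igf1",
    "ln_ins_glu",
    "sex_male",
    "age18",
    "birth_weight_g",
    "ebf_months",
    "any_formula",
    "prepreg_bmi",
    "gwg_kg",
]


def build_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Analysis frame: one row per infant x plasma timepoint with all model
    variables transformed (ln total BCAA, ln IGF-1, ln insulin/glucose,
    z-scored protein AUC ending at the row's age)."""
    plasma = cohort[cohort["visit_age"].isin([12.0, 18.0])].copy()
    if plasma.empty:
        raise EmptyFrame("cohort has no 12/18-mo rows")

    auc12 = cumulative_auc(cohort, "protein", 12)
    auc18 = cumulative_auc(cohort, "protein", 18)
    plasma["prot_auc"] = np.where(
        plasma["visit_age"] == 12.0,
        plasma["infant_id"].map(auc12),
        plasma["infant_id"].map(auc18),
    )

    leu = plasma[metabolite_column("leucine")]
    ile = plasma[metabolite_column("isoleucine")]
    val = plasma[metabolite_column("valine")]
    frame = pd.DataFrame(
        {
            "infant_id": plasma["infant_id"],
            "group": plasma["group"],
            "age18": (plasma["visit_age"] == 18.0).astype(float),
            "sex_male": plasma["sex_male"].astype(float),
            "prot_auc": plasma["prot_auc"],
            "ln_bcaa": np.log(leu + ile + val),
            "ln_igf1": np.log(plasma["igf1_ngml"]),
            "ln_ins_glu": np.log(plasma["insulin_miul"] / plasma["glucose_mmol"]),
            "weight_kg": plasma["weight_kg"],
            "bmi": plasma["bmi"],
            "birth_weight_g": plasma["birth_weight_g"],
            "ebf_months": plasma["ebf_months"],
            "any_formula": plasma["any_formula"].astype(float),
            "prepreg_bmi": plasma["prepreg_bmi"],
            "gwg_kg": plasma["gwg_kg"],
        }
    )
    frame = frame.dropna().reset_index(drop=True)
    if frame.empty:
        raise EmptyFrame("no listwise-complete analysis rows")
    frame["z_prot_auc"] = zscore(frame["prot_auc"])
    return frame


def _model_text(outcome: str, include_igf1_path: bool = True) -> str:
    growth_terms = ["z_prot_auc", "ln_ins_glu"]
    if include_igf1_path:
        growth_terms.append("ln_igf1")
    growth_terms += [
        "birth_weight_g", "gwg_kg", "prepreg_bmi", "ebf_months",
        "any_formula", "sex_male", "age18",
    ]
    lines = [
        f"{outcome} ~ " + " + ".join(growth_terms),
        "ln_igf1 ~ z_prot_auc + ln_bcaa + sex_male + age18",
        "ln_ins_glu ~ ln_bcaa + sex_male + age18",
    ]
    return "\n".join(lines)


def weight_model_spec(include_igf1_path: bool = True) -> SEMSpec:
    """Growth SEM with body weight (kg) as the outcome."""
    return parse_model(_model_text("weight_kg", include_igf1_path))


def bmi_model_spec(include_igf1_path: bool = True) -> SEMSpec:
    """Growth SEM with BMI (kg/m^2) as the outcome."""
    return parse_model(_model_text("bmi", include_igf1_path))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "†"  # dagger: marginal
    return ""


def run_sem_pipeline(
    cohort: pd.DataFrame,
    model: str = "weight",
    include_igf1_path: bool = True,
    frame: pd.DataFrame | None = None,
) -> dict:
    """Full SEM stage: frame -> robust ML fit -> indices -> modification
    indices -> standardized path table with star bands -> DOT diagram.
    Deterministic given the cohort."""
    if model not in ("weight", "bmi"):
        raise ValueError("model must be 'weight' or 'bmi'")
    if frame is None:
        frame = build_frame(cohort)
    spec = (weight_model_spec if model == "weight" else bmi_model_spec)(include_igf1_path)
    fit = robust_adjust(fit_ml(spec, frame), frame)
    idx = fit_indices(fit)
    mi = modification_indices(fit)
    table = fit.standardized_table()
    table["stars"] = [significance_stars(p) for p in table["p"]]
    return {
        "model": model,
        "n_obs": fit.n_obs,
        "estimates": table,
        "indices": idx,
        "mod_indices": mi,
        "dot": diagram_dot(fit, table, title=f"{model} model"),
        "fit": fit,
    }


def report_to_json(report: dict) -> str:
    """Serializable bundle (drops the live fit object)."""
    payload = {
        "model": report["model"],
        "n_obs": int(report["n_obs"]),
        "estimates": report["estimates"].to_dict(orient="records"),
        "indices": report["indices"].as_dict(),
        "mod_indices": report["mod_indices"].to_dict(orient="records"),
        "dot": report["dot"],
    }
    return json.dumps(payload, indent=1, default=str)


def diagram_dot(fit: SEMFit, table: pd.DataFrame | None = None, title: str = "") -> str:
    """Path diagram in DOT: directed edges labeled with standardized
    coefficients and significance stars; exogenous covariances omitted for
    legibility."""
    if table is None:
        table = fit.standardized_table()
        table["stars"] = [significance_stars(p) for p in table["p"]]
    lines = [
        "digraph sem {",
        "  rankdir=LR;",
        f'  label="{title}";',
        "  node [shape=box];",
    ]
    for _, row in table.iterrows():
        if row["op"] != "~":
            continue
        lab = f'{row["std"]:.2f}{row["stars"]}'
        lines.append(f'  "{row["rhs"]}" -> "{row["lhs"]}" [label="{lab}"];')
    lines.append("}")
    return "\n".join(lines)


# ----------------------------------------------------------------------
# simulation-based residual diagnostics
# ----------------------------------------------------------------------

def residual_diagnostics(
    frame: pd.DataFrame,
    model: str = "weight",
    n_sim: int = 250,
    seed: int = 0,
    include_igf1_path: bool = True,
) -> dict:
    """Per-equation assumption checks via simulated quantile residuals.

    Each structural equation is refit by Gaussian least squares; ``n_sim``
    response vectors are simulated from the fitted equation and every
    observation's quantile residual is its (randomized) rank among its own
    simulations, uniform on (0,1) under a correct model.  Reports a KS
    uniformity test, a dispersion test (observed residual variance against
    the simulated distribution), and a boundary-outlier binomial test.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be >= 50")
    spec = (weight_model_spec if model == "weight" else bmi_model_spec)(include_igf1_path)
    rng = np.random.default_rng(seed)
    out = {}
    for endo in spec.endogenous():
        parents = spec.parents(endo)
        X = sm.add_constant(frame[parents].to_numpy())
        y = frame[endo].to_numpy()
        res = sm.OLS(y, X).fit()
        mu = res.fittedvalues
        sd = np.sqrt(res.scale)
        n = len(y)
        sims = mu[:, None] + sd * rng.standard_normal((n, n_sim))
        below = (sims < y[:, None]).sum(axis=1)
        ties = (sims == y[:, None]).sum(axis=1)
        u = (below + rng.random(n) * (ties + 1)) / (n_sim + 1)

        ks_stat, ks_p = stats.kstest(u, "uniform")
        v_obs = res.resid.var(ddof=X.shape[1])
        v_sim = ((sims - mu[:, None]).var(axis=0, ddof=X.shape[1]))
        tail = (np.sum(v_sim >= v_obs) + 1) / (n_sim + 1)
        disp_p = min(1.0, 2 * min(tail, 1 - tail + 1 / (n_sim + 1)))
        k_out = int(np.sum((u < 1 / (n_sim + 1)) | (u > n_sim / (n_sim + 1))))
        outlier = stats.binomtest(k_out, n, 2 / (n_sim + 1))
        out[endo] = {
            "ks_stat": float(ks_stat),
            "ks_p": float(ks_p),
            "dispersion_ratio": float(v_obs / v_sim.mean()),
            "dispersion_p": float(disp_p),
            "outliers": k_out,
            "outlier_p": float(outlier.pvalue),
            "quantile_residuals": u,
        }
    return out


# ----------------------------------------------------------------------
# descriptive group comparisons
# ----------------------------------------------------------------------

def chi2_yates(table) -> dict:
    """Continuity-corrected chi-square on a 2x2 count table."""
    table = np.asarray(table)
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=True)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof),
            "min_expected": float(expected.min())}


def welch_t(x, y) -> dict:
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(t), "p": float(p)}


def exact_binary(table, mode: str = "conditional") -> dict:
    """Exact test for a 2x2 binary outcome: conditional (hypergeometric,
    Fisher) by default, or a one-sample binomial comparing the first row's
    rate to the pooled rate (``mode='binomial'``)."""
    table = np.asarray(table)
    if mode == "conditional":
        odds, p = stats.fisher_exact(table)
        return {"statistic": float(odds), "p": float(p), "mode": mode}
    k, n = int(table[0, 0]), int(table[0].sum())
    pooled = table[:, 0].sum() / table.sum()
    res = stats.binomtest(k, n, pooled)
    return {"statistic": float(k / n), "p": float(res.pvalue), "mode": mode}


def group_compare(
    df: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Welch t-tests for continuous variables and (Yates) chi-square tests
    for 2-level categoricals between the two groups; the exact conditional
    test replaces chi-square when any expected count is < 5."""
    uniq = df[group_col].dropna().unique()
    if len(uniq) != 2:
        raise ValueError("need exactly two groups")
    a, b = sorted(uniq)
    rows = []
    for col in continuous or []:
        x = df.loc[df[group_col] == a, col].dropna()
        y = df.loc[df[group_col] == b, col].dropna()
        res = welch_t(x, y)
        rows.append({"variable": col, "test": "welch", "statistic": res["t"],
                     "p": res["p"], "mean_a": x.mean(), "mean_b": y.mean()})
    for col in categorical or []:
        tab = pd.crosstab(df[group_col], df[col]).to_numpy()
        res = chi2_yates(tab)
        if res["min_expected"] < 5:
            ex = exact_binary(tab)
            rows.append({"variable": col, "test": "exact", "statistic": ex["statistic"],
                         "p": ex["p"], "mean_a": np.nan, "mean_b": np.nan})
        else:
            rows.append({"variable": col, "test": "chi2_yates", "statistic": res["chi2"],
                         "p": res["p"], "mean_a": np.nan, "mean_b": np.nan})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# proxy-validation correlations
# ----------------------------------------------------------------------

def proxy_validation(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations supporting the modeling proxies: recent protein
    vs total BCAA, the inter-BCAA block, weight vs length, BMI vs fat-mass
    index, cumulative protein vs fat-free/fat mass, plus a sex-adjusted
    regression of fat-free mass on cumulative protein with interaction."""
    sub = cohort[cohort["visit_age"].isin([12.0, 18.0])].copy()
    auc12 = cumulative_auc(cohort, "protein", 12)
    auc18 = cumulative_auc(cohort, "protein", 18)
    sub["prot_auc"] = np.where(
        sub["visit_age"] == 12.0,
        sub["infant_id"].map(auc12),
        sub["infant_id"].map(auc18),
    )
    leu = sub[metabolite_column("leucine")]
    ile = sub[metabolite_column("isoleucine")]
    val = sub[metabolite_column("valine")]
    sub["total_bcaa"] = leu + ile + val
    sub["fat_mass"] = sub["weight_kg"] - sub["ffm_kg"]

    pairs = [
        ("protein_gd", "total_bcaa", "recent protein vs total BCAA"),
        (metabolite_column("leucine"), metabolite_column("isoleucine"), "leucine vs isoleucine"),
        (metabolite_column("leucine"), metabolite_column("valine"), "leucine vs valine"),
        (metabolite_column("isoleucine"), metabolite_column("valine"), "isoleucine vs valine"),
        ("weight_kg", "length_cm", "weight vs length"),
        ("bmi", "fmi", "BMI vs fat-mass index"),
        ("prot_auc", "ffm_kg", "cumulative protein vs fat-free mass"),
        ("prot_auc", "fat_mass", "cumulative protein vs fat mass"),
    ]
    rows = []
    for x, y, label in pairs:
        d = sub[[x, y]].dropna()
        if len(d) < 3:
            raise ValueError(f"insufficient pairs for {label}")
        r, p = stats.pearsonr(d[x], d[y])
        rows.append({"pair": label, "r": float(r), "p": float(p), "n": len(d)})

    d = sub[["ffm_kg", "prot_auc", "sex_male"]].dropna()
    X = d[["prot_auc", "sex_male"]].copy()
    X["interaction"] = X["prot_auc"] * X["sex_male"]
    res = sm.OLS(d["ffm_kg"], sm.add_constant(X)).fit()
    rows.append({
        "pair": "ffm ~ protein AUC (sex-adjusted, with interaction)",
        "r": float(res.params["prot_auc"]),
        "p": float(res.pvalues["prot_auc"]),
        "n": int(res.nobs),
    })
    return pd.DataFrame(rows)
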