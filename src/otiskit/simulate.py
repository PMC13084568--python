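"""Synthetic cohort generation.

The generator emulates a two-arm complementary-feeding trial: per-visit
5-day-record dietary means at 6/9/12/18 mo, a 52-analyte plasma NMR panel at
12 and 18 mo, growth-axis biomarkers (IGF-1, insulin, glucose, folate),
anthropometry, maternal/neonatal covariates, breastfeeding history, and
informative dropout.

Simulation order (all vectorized, one named RNG substream per stage):

1. exogenous covariates and randomized group;
2. per-visit dietary trajectories (Nordic protein shifted down, most
   strongly at 12 mo, mimicking waning adherence);
3. ln total BCAA from recent (same-visit) protein, split into leucine /
   isoleucine / valine via a shared lognormal factor;
4. ln IGF-1 and ln insulin-to-glucose from the standardized structural
   coefficients; then weight and BMI from theirs;
5. the remaining panel analytes as lognormals with class-targeted group
   shifts.

Structural variables are generated standardized (variance 1 in-sample: the
residual variance of each endogenous variable is set from the realized
variance of its linear predictor), then mapped to natural units by affine
rescaling, so the preset's standardized coefficients are the generating
truth a standardized SEM fit recovers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InfeasiblePreset
from .intake import trapezoid_auc
from .panel import BASE_CONCENTRATION, BCAAS, LOG_SD, METABOLITES, metabolite_column
from .presets import (
    EFFECT_CLASS_TARGET_R,
    GenerativePreset,
    VISITS,
    PLASMA_VISITS,
    wilcoxon_r_to_shift,
)

__all__ = ["generate_cohort", "apply_dropout", "write_cohort", "read_cohort"]

ENROLLMENT_AGE = 4.5

_MEAL_RATE = {6: 3.0, 9: 2.0, 12: 1.0, 18: 0.5}
_SNACK_RATE = {6: 2.0, 9: 1.5, 12: 1.0, 18: 0.5}


def _std(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise InfeasiblePreset("degenerate (constant) structural variable")
    return (x - x.mean()) / s


def _truncnorm(rng, mean, sd, size, lo=-np.inf, hi=np.inf):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_cohort(preset: GenerativePreset, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full cohort table (one row per infant x visit).

    Visits are enrollment (4.5 mo) plus 6, 9, 12, 18 mo; dietary columns are
    populated at the four record visits, the plasma panel at 12 and 18 mo.
    Deterministic given ``(preset, seed)``.
    """
    preset.validate()
    if seed is None:
        seed = preset.seed
    n = preset.n_per_group
    n_inf = 2 * n
    group = np.array(["nordic"] * n + ["conventional"] * n)
    nordic = group == "nordic"
    mom = preset.exogenous_moments

    rng_ex = substream(seed, "exogenous")
    sex_male = (rng_ex.random(n_inf) < mom["sex_male"]["p"]).astype(float)
    bw = _truncnorm(rng_ex, mom["birth_weight"]["mean"], mom["birth_weight"]["sd"],
                    n_inf, lo=mom["birth_weight"]["min"])
    prepreg = _truncnorm(rng_ex, mom["prepreg_bmi"]["mean"], mom["prepreg_bmi"]["sd"],
                         n_inf, lo=mom["prepreg_bmi"]["min"])
    gwg = _truncnorm(rng_ex, mom["gwg"]["mean"], mom["gwg"]["sd"], n_inf,
                     lo=mom["gwg"]["min"])
    mat_age = _truncnorm(rng_ex, mom["maternal_age"]["mean"], mom["maternal_age"]["sd"],
                         n_inf, lo=mom["maternal_age"]["min"])
    ebf = _truncnorm(rng_ex, mom["ebf_months"]["mean"], mom["ebf_months"]["sd"],
                     n_inf, lo=mom["ebf_months"]["min"], hi=mom["ebf_months"]["max"])
    p_formula = np.clip(
        mom["any_formula"]["base"] + mom["any_formula"]["per_ebf_month"] * ebf,
        0.05, 0.95,
    )
    any_formula = (rng_ex.random(n_inf) < p_formula).astype(float)

    # breastfeeding: one latent per infant against a declining per-visit
    # probability curve, so cessation is monotone
    u_bf = rng_ex.random(n_inf)
    bf_curve = preset.breastfeeding_curve
    bf_enroll = np.where(
        nordic, u_bf < bf_curve["nordic"][0], u_bf < bf_curve["conventional"][0]
    ).astype(float)
    bf_at = {
        v: np.where(
            nordic, u_bf < bf_curve["nordic"][v], u_bf < bf_curve["conventional"][v]
        ).astype(float)
        for v in VISITS
    }

    # ------------------------------------------------------------------
    # dietary trajectories
    rng_diet = substream(seed, "diet")
    a = np.sqrt(preset.visit_tracking)
    c = np.sqrt(1.0 - preset.visit_tracking)

    def trajectory(means_by_group: dict[str, dict[int, float]], sds: dict[int, float]):
        u = rng_diet.normal(size=n_inf)
        out = {}
        for v in VISITS:
            m = np.where(nordic, means_by_group["nordic"][v], means_by_group["conventional"][v])
            out[v] = np.clip(m + sds[v] * (a * u + c * rng_diet.normal(size=n_inf)), 0.5, None)
        return out

    protein = trajectory(preset.protein_trajectory, preset.trajectory_sd["protein"])
    carb = trajectory(preset.diet_trajectory["carbohydrate"], preset.trajectory_sd["carbohydrate"])
    fat = trajectory(preset.diet_trajectory["fat"], preset.trajectory_sd["fat"])
    fveg = trajectory(preset.diet_trajectory["fruit_veg"], preset.trajectory_sd["fruit_veg"])
    energy = {
        v: np.clip(
            4.0 * (protein[v] + carb[v]) + 9.0 * fat[v]
            + rng_diet.normal(0.0, preset.trajectory_sd["energy"][v], n_inf),
            50.0, None,
        )
        for v in VISITS
    }

    meals, snacks = {}, {}
    for v in VISITS:
        meals[v] = np.where(bf_at[v] > 0, rng_diet.poisson(_MEAL_RATE[v], n_inf), 0)
        snacks[v] = np.where(bf_at[v] > 0, rng_diet.poisson(_SNACK_RATE[v], n_inf), 0)

    # ------------------------------------------------------------------
    # analysis rows: one per infant per plasma visit (12, 18)
    months = np.array(VISITS, dtype=float)
    prot_mat = np.column_stack([protein[v] for v in VISITS])
    auc12 = trapezoid_auc(prot_mat[:, :3], months[:3])
    auc18 = trapezoid_auc(prot_mat, months)

    def rows(x12, x18):
        return np.concatenate([x12, x18])

    def tile(x):
        return np.concatenate([x, x])

    age18 = rows(np.zeros(n_inf), np.ones(n_inf))
    row_visit = rows(np.full(n_inf, 12.0), np.full(n_inf, 18.0))
    z_auc = _std(rows(auc12, auc18))
    z_recent = _std(rows(protein[12], protein[18]))
    row_nordic = tile(nordic)
    n_rows = 2 * n_inf

    # ------------------------------------------------------------------
    # total BCAA from recent protein, plus a direct group shift topping the
    # mediated one up to the preset's 12-mo effect-size class
    rng_b = substream(seed, "bcaa")
    r_pb = preset.bcaa_protein_r
    z_lat = r_pb * z_recent + np.sqrt(1.0 - r_pb**2) * rng_b.normal(size=n_rows)

    direction, cls = preset.metabolite_effects["leucine"][12]
    if cls != "none":
        at12 = row_visit == 12.0
        target = wilcoxon_r_to_shift(EFFECT_CLASS_TARGET_R[cls])
        sel_n, sel_c = at12 & row_nordic, at12 & ~row_nordic
        s_within = np.sqrt(0.5 * (z_lat[sel_n].var() + z_lat[sel_c].var()))
        gap = z_lat[sel_c].mean() - z_lat[sel_n].mean()
        topup = max(0.0, target * s_within - gap)
        z_lat = z_lat - np.where(sel_n, topup, 0.0)

    lam = preset.bcaa_component_load
    bcaa_conc = {}
    for name in BCAAS:
        s = LOG_SD[name]
        ln_x = np.log(BASE_CONCENTRATION[name]) + s * (
            np.sqrt(lam) * z_lat + np.sqrt(1.0 - lam) * rng_b.normal(size=n_rows)
        )
        bcaa_conc[name] = np.exp(ln_x)
    total_bcaa = sum(bcaa_conc.values())
    z_bcaa = _std(np.log(total_bcaa))

    # ------------------------------------------------------------------
    # structural endogenous variables
    rng_s = substream(seed, "structural")
    parent_values = {
        "z_prot_auc": z_auc,
        "ln_bcaa": z_bcaa,
        "sex_male": _std(tile(sex_male)),
        "age18": _std(age18),
        "birth_weight": _std(tile(bw)),
        "gwg": _std(tile(gwg)),
        "prepreg_bmi": _std(tile(prepreg)),
        "ebf_months": _std(tile(ebf)),
        "any_formula": _std(tile(any_formula)),
    }
    children = preset.structural_children()
    z_endo = {}
    for y in ("ln_igf1", "ln_ins_glu", "weight", "bmi"):
        linpred = np.zeros(n_rows)
        for parent, coef in children.get(y, []):
            if coef != 0.0:
                linpred = linpred + coef * (z_endo.get(parent, parent_values.get(parent)))
        v = linpred.var()
        if v >= 1.0:
            raise InfeasiblePreset(f"realized explained variance of {y} is {v:.3f} >= 1")
        z_endo[y] = linpred + np.sqrt(1.0 - v) * rng_s.normal(size=n_rows)

    # ------------------------------------------------------------------
    # natural units
    rng_a = substream(seed, "anthro")
    igf1 = np.exp(mom["ln_igf1"]["mean"] + mom["ln_igf1"]["sd"] * z_endo["ln_igf1"])
    glucose = np.exp(rng_a.normal(mom["glucose_mmol"]["mean"], mom["glucose_mmol"]["sd"], n_rows))
    insulin = glucose * np.exp(
        mom["ln_ins_glu"]["mean"] + mom["ln_ins_glu"]["sd"] * z_endo["ln_ins_glu"]
    )
    weight = mom["weight"]["mean"] + mom["weight"]["sd"] * z_endo["weight"]
    bmi = mom["bmi"]["mean"] + mom["bmi"]["sd"] * z_endo["bmi"]
    weight = np.clip(weight, 5.0, None)
    bmi = np.clip(bmi, 10.0, None)
    length = 100.0 * np.sqrt(weight / bmi)
    ffm_frac = np.clip(
        rng_a.normal(mom["ffm_fraction"]["mean"], mom["ffm_fraction"]["sd"], n_rows),
        0.55, 0.88,
    )
    ffm = weight * ffm_frac
    fmi = (weight - ffm) / (length / 100.0) ** 2
    fol = mom["folate_nmol"]
    fol_shift = np.where(
        row_nordic, np.where(row_visit == 12.0, fol["nordic_shift_12"], fol["nordic_shift_18"]), 0.0
    )
    folate = np.exp(rng_a.normal(fol["mean"], fol["sd"], n_rows) + fol_shift)

    # ------------------------------------------------------------------
    # remaining panel analytes
    rng_m = substream(seed, "metabolites")
    conc = dict(bcaa_conc)
    for name in METABOLITES:
        if name in BCAAS:
            continue
        s = LOG_SD[name]
        shift = np.zeros(n_rows)
        for t in PLASMA_VISITS:
            direction, cls = preset.metabolite_effects[name][t]
            if cls == "none":
                continue
            delta = wilcoxon_r_to_shift(EFFECT_CLASS_TARGET_R[cls]) * s
            sign = -1.0 if direction == "lower_in_nordic" else 1.0
            shift += np.where(row_nordic & (row_visit == t), sign * delta, 0.0)
        conc[name] = np.exp(np.log(BASE_CONCENTRATION[name]) + s * rng_m.normal(size=n_rows) + shift)

    # ------------------------------------------------------------------
    # early anthropometry (enrollment, 6, 9 mo) - descriptive only
    z_bw_inf = (bw - bw.mean()) / bw.std()
    w_enr = mom["enroll_weight"]["mean"] + mom["enroll_weight"]["sd"] * (
        0.5 * z_bw_inf + np.sqrt(0.75) * rng_a.normal(size=n_inf)
    )
    bmi_enr = mom["enroll_bmi"]["mean"] + mom["enroll_bmi"]["sd"] * rng_a.normal(size=n_inf)
    early = {}
    for v, (mw, mb) in {6: (7.9, 17.3), 9: (9.0, 17.5)}.items():
        wv = mw + 0.9 * (0.5 * z_bw_inf + np.sqrt(0.75) * rng_a.normal(size=n_inf))
        bv = mb + 1.4 * rng_a.normal(size=n_inf)
        early[v] = (np.clip(wv, 4.0, None), np.clip(bv, 11.0, None))

    # ------------------------------------------------------------------
    # assemble the long table
    ids = np.array([f"otis{idx:05d}" for idx in range(n_inf)])
    frames = []

    def infant_block(visit_age: float) -> dict:
        return {
            "infant_id": ids,
            "visit_age": visit_age,
            "group": group,
            "sex_male": sex_male.astype(int),
            "birth_weight_g": bw,
            "prepreg_bmi": prepreg,
            "gwg_kg": gwg,
            "maternal_age": mat_age,
            "ebf_months": ebf,
            "any_formula": any_formula.astype(int),
            "bf_enroll": bf_enroll.astype(int),
        }

    blk = infant_block(ENROLLMENT_AGE)
    blk.update(weight_kg=np.clip(w_enr, 4.0, None), bmi=np.clip(bmi_enr, 11.0, None),
               breastfeeding=bf_enroll.astype(int))
    frames.append(pd.DataFrame(blk))

    for v in VISITS:
        blk = infant_block(float(v))
        blk.update(
            breastfeeding=bf_at[v].astype(int),
            protein_gd=protein[v],
            carb_gd=carb[v],
            fat_gd=fat[v],
            energy_kcal=energy[v],
            fruit_veg_gd=fveg[v],
            bm_meals=meals[v],
            bm_snacks=snacks[v],
        )
        if v in PLASMA_VISITS:
            sel = row_visit == float(v)
            blk.update(
                weight_kg=weight[sel],
                bmi=bmi[sel],
                ffm_kg=ffm[sel],
                fmi=fmi[sel],
                igf1_ngml=igf1[sel],
                insulin_miul=insulin[sel],
                glucose_mmol=glucose[sel],
                folate_nmol=folate[sel],
            )
            for name in METABOLITES:
                blk[metabolite_column(name)] = conc[name][sel]
        else:
            wv, bv = early[v]
            blk.update(weight_kg=wv, bmi=bv)
        frames.append(pd.DataFrame(blk))

    cohort = pd.concat(frames, ignore_index=True)
    cohort["length_cm"] = 100.0 * np.sqrt(cohort["weight_kg"] / cohort["bmi"])
    cohort["dropped_out"] = 0
    cohort["dropout_visit"] = np.nan
    cohort = cohort.sort_values(["infant_id", "visit_age"], kind="stable").reset_index(drop=True)
    return cohort


def apply_dropout(cohort: pd.DataFrame, preset: GenerativePreset,
                  seed: int | None = None) -> pd.DataFrame:
    """Mark infants lost to follow-up and delete their post-dropout rows.

    Dropout probability follows a logistic model on standardized maternal
    prepregnancy BMI (+), maternal age (-), breastfeeding at enrollment (-)
    and randomized group (Nordic +), with intercept/group coefficient
    calibrated in the preset. The dropout visit (last attended) is drawn
    from {9, 12, 18}.
    """
    if seed is None:
        seed = preset.seed
    rng = substream(seed, "dropout")
    lg = preset.dropout_logit
    inf = cohort.drop_duplicates("infant_id").set_index("infant_id")
    z_bmi = (inf["prepreg_bmi"] - inf["prepreg_bmi"].mean()) / inf["prepreg_bmi"].std(ddof=0)
    z_age = (inf["maternal_age"] - inf["maternal_age"].mean()) / inf["maternal_age"].std(ddof=0)
    eta = (
        lg.get("intercept", 0.0)
        + lg.get("prepreg_bmi", 0.0) * z_bmi
        + lg.get("maternal_age", 0.0) * z_age
        + lg.get("bf_enroll", 0.0) * inf["bf_enroll"]
        + lg.get("nordic", 0.0) * (inf["group"] == "nordic").astype(float)
    )
    p = 1.0 / (1.0 + np.exp(-eta.to_numpy()))
    if not ((p >= 0) & (p <= 1)).all():  # pragma: no cover - sigmoid guarantees
        raise InfeasiblePreset("dropout probability outside [0, 1]")
    dropped = rng.random(len(inf)) < p
    last_visit = rng.choice([9.0, 12.0, 18.0], size=len(inf), p=[0.4, 0.3, 0.3])

    status = pd.DataFrame(
        {"dropped_out": dropped.astype(int),
         "dropout_visit": np.where(dropped, last_visit, np.nan)},
        index=inf.index,
    )
    out = cohort.drop(columns=["dropped_out", "dropout_visit"]).merge(
        status, left_on="infant_id", right_index=True, how="left"
    )
    keep = out["dropout_visit"].isna() | (out["visit_age"] <= out["dropout_visit"])
    return out.loc[keep].reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
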