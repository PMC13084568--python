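"""Dietary-intake derivations: breastmilk grams, cumulative-intake AUC, and
protein-threshold flags.

Cumulative intake is the trapezoid-rule integral of mean daily intake over
the scheduled visit ages (6, 9, 12, 18 mo), in (g/d)*month or
(kcal/d)*month.  It is defined only for infants with records at all four
visits; anyone else is excluded (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingVisit

__all__ = [
    "BREASTMILK_MEAL_G",
    "BREASTMILK_SNACK_G",
    "PROTEIN_GKG_THRESHOLD",
    "PROTEIN_ENERGY_THRESHOLD",
    "PROTEIN_KCAL_PER_G",
    "breastmilk_grams",
    "trapezoid_auc",
    "cumulative_auc",
    "cumulative_auc_table",
    "protein_flags",
    "zscore",
]

VISITS = (6, 9, 12, 18)

#: grams of breastmilk assigned to one qualitative feed code
BREASTMILK_MEAL_G = 102.0
BREASTMILK_SNACK_G = 25.0

#: protein adequacy threshold, g per day per kg body weight
PROTEIN_GKG_THRESHOLD = 1.05
#: protein share of total energy above which intake is flagged (strict >)
PROTEIN_ENERGY_THRESHOLD = 0.15
#: Atwater factor used to convert protein grams to energy
PROTEIN_KCAL_PER_G = 4.0

_NUTRIENT_COLUMNS = {
    "protein": "protein_gd",
    "carbohydrate": "carb_gd",
    "fat": "fat_gd",
    "energy": "energy_kcal",
    "fruit_veg": "fruit_veg_gd",
}


def breastmilk_grams(meal_count, snack_count) -> float:
    """Estimated breastmilk intake (g/d) from qualitative feed codes:
    102 g per "meal", 25 g per "snack"."""
    meal = np.asarray(meal_count, dtype=float)
    snack = np.asarray(snack_count, dtype=float)
    if (meal < 0).any() or (snack < 0).any():
        raise ValueError("feed counts must be nonnegative")
    out = BREASTMILK_MEAL_G * meal + BREASTMILK_SNACK_G * snack
    return float(out) if out.ndim == 0 else out


def trapezoid_auc(values: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Row-wise trapezoid integral of ``values`` (n x v) over ``months``."""
    return np.trapezoid(np.atleast_2d(values), x=np.asarray(months, float), axis=1)


@dataclass
class CumulativeIntake:
    infant_id: str
    nutrient: str
    end_month: int
    auc: float


def cumulative_auc(records: pd.DataFrame, nutrient: str, end_month: int) -> pd.Series:
    """Per-infant cumulative intake from month 6 to ``end_month`` (12 or 18).

    ``records`` is a long table with ``infant_id``, ``visit_age`` and the
    nutrient column.  Infants missing any of the four scheduled records are
    excluded (the four-visit completeness rule applies to both intervals).
    Raises :class:`MissingVisit` if *no* infant is complete.
    """
    if end_month not in (12, 18):
        raise ValueError("end_month must be 12 or 18")
    col = _NUTRIENT_COLUMNS.get(nutrient, nutrient)
    if col not in records.columns:
        raise KeyError(f"no column {col!r} for nutrient {nutrient!r}")
    sub = records[records["visit_age"].isin(VISITS)]
    wide = sub.pivot_table(index="infant_id", columns="visit_age", values=col)
    wide = wide.reindex(columns=[float(v) for v in VISITS])
    complete = wide.dropna()
    if complete.empty:
        raise MissingVisit("no infant has records at all four visits")
    if (complete.to_numpy() < 0).any():
        raise ValueError("negative intake")
    use = [float(v) for v in VISITS if v <= end_month]
    auc = trapezoid_auc(complete[use].to_numpy(), np.array(use))
    return pd.Series(auc, index=complete.index, name=f"auc_{nutrient}_{end_month}")


def cumulative_auc_table(records: pd.DataFrame, nutrient: str = "protein") -> pd.DataFrame:
    """Both intervals (6-12 and 6-18) for every complete-record infant."""
    a12 = cumulative_auc(records, nutrient, 12)
    a18 = cumulative_auc(records, nutrient, 18)
    return pd.DataFrame({a12.name: a12, a18.name: a18})


def zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (population SD) over the given sample."""
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std()


def protein_flags(protein_gd, energy_kcal, weight_kg,
                  kcal_per_g: float = PROTEIN_KCAL_PER_G) -> pd.DataFrame:
    """Threshold flags: ``meets_gkg`` (protein/weight >= 1.05 g/d/kg) and
    ``exceeds_e15`` (protein energy share strictly > 15 E%)."""
    protein = np.atleast_1d(np.asarray(protein_gd, dtype=float))
    energy = np.atleast_1d(np.asarray(energy_kcal, dtype=float))
    weight = np.atleast_1d(np.asarray(weight_kg, dtype=float))
    if (energy <= 0).any() or (weight <= 0).any() or (protein < 0).any():
        raise ValueError("inputs must be positive")
    e_frac = kcal_per_g * protein / energy
    return pd.DataFrame(
        {
            "meets_gkg": protein / weight >= PROTEIN_GKG_THRESHOLD,
            "exceeds_e15": e_frac > PROTEIN_ENERGY_THRESHOLD,
            "protein_e_pct": 100.0 * e_frac,
        }
    )
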