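"""Schema of the 52-analyte plasma NMR panel.

Concentrations are in µmol/L (µM).  ``BASE_CONCENTRATION`` holds typical
infant plasma medians used as lognormal location parameters by the cohort
generator; ``LOG_SD`` the corresponding log-scale spread.  The branched-chain
amino acids (leucine, isoleucine, valine) are generated from a shared latent
factor tied to recent dietary protein, everything else is an independent
lognormal with optional group shifts.
"""

from __future__ import annotations

METABOLITES: tuple[str, ...] = (
    "alanine",
    "arginine",
    "asparagine",
    "aspartate",
    "citrulline",
    "glutamate",
    "glutamine",
    "glycine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "ornithine",
    "phenylalanine",
    "proline",
    "serine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
    "2-hydroxybutyrate",
    "3-hydroxybutyrate",
    "3-hydroxyisobutyrate",
    "2-ketoisocaproate",
    "2-ketoisovalerate",
    "3-methyl-2-oxovalerate",
    "acetate",
    "acetone",
    "pyruvate",
    "lactate",
    "citrate",
    "succinate",
    "fumarate",
    "formate",
    "glucose",
    "myo-inositol",
    "glycerol",
    "betaine",
    "choline",
    "carnitine",
    "acetylcarnitine",
    "creatine",
    "creatinine",
    "dimethylamine",
    "dimethylglycine",
    "dimethyl sulfone",
    "trimethylamine N-oxide",
    "urea",
    "taurine",
    "sarcosine",
    "methanol",
)

BCAAS: tuple[str, str, str] = ("leucine", "isoleucine", "valine")

BASE_CONCENTRATION: dict[str, float] = {
    "alanine": 350.0,
    "arginine": 80.0,
    "asparagine": 45.0,
    "aspartate": 15.0,
    "citrulline": 30.0,
    "glutamate": 60.0,
    "glutamine": 550.0,
    "glycine": 230.0,
    "histidine": 80.0,
    "isoleucine": 60.0,
    "leucine": 110.0,
    "lysine": 160.0,
    "methionine": 25.0,
    "ornithine": 60.0,
    "phenylalanine": 60.0,
    "proline": 180.0,
    "serine": 120.0,
    "threonine": 130.0,
    "tryptophan": 55.0,
    "tyrosine": 70.0,
    "valine": 220.0,
    "2-hydroxybutyrate": 40.0,
    "3-hydroxybutyrate": 80.0,
    "3-hydroxyisobutyrate": 20.0,
    "2-ketoisocaproate": 30.0,
    "2-ketoisovalerate": 15.0,
    "3-methyl-2-oxovalerate": 20.0,
    "acetate": 40.0,
    "acetone": 20.0,
    "pyruvate": 60.0,
    "lactate": 1800.0,
    "citrate": 110.0,
    "succinate": 8.0,
    "fumarate": 3.0,
    "formate": 25.0,
    "glucose": 4800.0,
    "myo-inositol": 30.0,
    "glycerol": 100.0,
    "betaine": 40.0,
    "choline": 10.0,
    "carnitine": 35.0,
    "acetylcarnitine": 8.0,
    "creatine": 60.0,
    "creatinine": 35.0,
    "dimethylamine": 3.0,
    "dimethylglycine": 3.0,
    "dimethyl sulfone": 4.0,
    "trimethylamine N-oxide": 4.0,
    "urea": 4500.0,
    "taurine": 60.0,
    "sarcosine": 3.0,
    "methanol": 30.0,
}

# log-scale SD; amino acids are fairly tight, microbial/diet-driven analytes
# (TMAO, DMA, acetone, 3-HB) wider.
LOG_SD: dict[str, float] = {name: 0.28 for name in METABOLITES}
LOG_SD.update(
    {
        "lactate": 0.35,
        "acetone": 0.45,
        "3-hydroxybutyrate": 0.50,
        "trimethylamine N-oxide": 0.55,
        "dimethylamine": 0.40,
        "acetate": 0.35,
        "formate": 0.35,
        "glucose": 0.10,
        "urea": 0.30,
        "glycerol": 0.40,
    }
)

PANEL_COLUMNS: tuple[str, ...] = tuple(f"met_{name}" for name in METABOLITES)


def metabolite_column(name: str) -> str:
    """Cohort-table column holding the concentration of ``name``."""
    if name not in METABOLITES:
        raise KeyError(f"unknown panel analyte: {name!r}")
    return f"met_{name}"
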