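"""Published reference values from a hatch-to-adult G. sigillatus feeding trial.

These are printed summary statistics — per-diet means with standard errors,
and global-maximum coordinates of fitted nutrient landscapes — usable as
inputs to the yield and ratio arithmetic when raw records are unavailable.
"""

from __future__ import annotations

import pandas as pd

from .yields import DietSummary

#: Per-P:C summaries (mass mg, proportion surviving, days to adulthood,
#: each +/- s.e.), pooled over the 14/45/76% cellulose dilutions, together
#: with the published yield +/- s.e. and its 95% CI as printed.
DIET_SUMMARY_TABLE = pd.DataFrame(
    [
        ("1P:8C", 100.00, 9.47, 11, 0.15, 0.034, 96, 92.27, 2.07, 0.16, 0.039, 0.083, 0.24),
        ("1P:5C", 112.72, 6.32, 16, 0.17, 0.036, 89, 92.88, 2.02, 0.20, 0.044, 0.11, 0.29),
        ("1P:3C", 112.39, 8.26, 17, 0.18, 0.037, 88, 90.67, 1.94, 0.22, 0.048, 0.13, 0.31),
        ("1P:1C", 127.90, 5.92, 30, 0.23, 0.037, 99, 88.97, 1.70, 0.33, 0.056, 0.22, 0.44),
        ("3P:1C", 132.94, 6.89, 37, 0.31, 0.043, 81, 72.43, 1.50, 0.58, 0.086, 0.41, 0.75),
        ("5P:1C", 131.50, 7.31, 29, 0.22, 0.036, 102, 73.38, 1.51, 0.40, 0.070, 0.26, 0.54),
        ("8P:1C", 143.00, 8.72, 20, 0.16, 0.032, 109, 73.80, 1.49, 0.30, 0.063, 0.18, 0.42),
    ],
    columns=[
        "pc_label", "mass_mg", "mass_se", "n_adults", "prop_surviving", "prop_se",
        "n_deaths", "days_to_adult", "days_se", "yield", "yield_se",
        "ci_low", "ci_high",
    ],
)

#: Global-maximum coordinates (cumulative protein, carbohydrate in mg) of the
#: published nutrient landscapes, with the ratio each implies as printed.
LANDSCAPE_OPTIMA = pd.DataFrame(
    [
        ("size_pc1", "pooled", 0.546, 0.174, "3.14P:1C"),
        ("size_pc1", "female", 0.489, 0.174, "2.81P:1C"),
        ("size_pc1", "male", 0.209, 0.387, "1P:1.85C"),
        ("mass_mg", "pooled", 0.532, 0.165, "3.22P:1C"),
        ("mass_mg", "female", 0.523, 0.159, "3.29P:1C"),
        ("mass_mg", "male", 0.310, 0.141, "2.20P:1C"),
        ("dev_days", "pooled", 0.081, 0.544, "1P:6.72C"),
        ("dev_days", "female", 0.202, 0.400, "1P:1.98C"),
        ("dev_days", "male", 0.093, 0.648, "1P:6.97C"),
    ],
    columns=["trait", "group", "protein_mg", "carb_mg", "printed_ratio"],
)

#: Hazard ratios quoted in the published development/survival analysis.
QUOTED_HAZARD_RATIOS = {
    "development 1P:8C vs 3P:1C": 0.07,   # "93% less likely"
    "development 1P:5C vs 3P:1C": 0.14,   # "86% less likely"
    "development 1P:3C vs 3P:1C": 0.22,   # "78% less likely"
    "development 1P:1C vs 3P:1C": 0.36,   # "64% less likely"
    "development high vs low cellulose": 0.37,  # "63% less likely"
    "survival 8P:1C vs 3P:1C": 1.45,      # "45% higher risk"
    "survival high cellulose days 0-7": 2.74,   # "174% higher risk"
    "survival medium cellulose days 0-7": 1.89, # "89% higher risk"
    "survival high cellulose days 7-14": 6.05,  # "505% higher risk"
}


def published_diet_summaries() -> list[DietSummary]:
    """The printed per-diet table as :class:`DietSummary` objects."""
    return [
        DietSummary(
            pc_label=r.pc_label, mass_mg=r.mass_mg, mass_se=r.mass_se,
            prop_surviving=r.prop_surviving, prop_se=r.prop_se,
            days_to_adult=r.days_to_adult, days_se=r.days_se,
            n_adults=int(r.n_adults), n_deaths=int(r.n_deaths),
        )
        for r in DIET_SUMMARY_TABLE.itertuples()
    ]
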