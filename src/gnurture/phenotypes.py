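"""Substance-use measure derivations from questionnaire-style fields.

Implements the standard epidemiological recodes: smoking initiation (ever
smoked a full year), pack-years (20 cigarettes/day for one year = 1
pack-year, with cross-product tobacco equivalence), average daily alcohol
intake in grams/day from per-beverage frequency and quantity categories, and
the two-gate lifetime-cannabis recode.  All conversion tables (tobacco
equivalence weights, category midpoints, ethanol grams per glass) are
explicit configuration with declared defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlcoholConfig",
    "smoking_initiation",
    "pack_years",
    "daily_alcohol_grams",
    "lifetime_cannabis",
    "DEFAULT_EQUIVALENCE",
    "DEFAULT_FREQ_MIDPOINTS",
    "DEFAULT_GLASS_MIDPOINTS",
]

# cigarette-equivalence weights per tobacco product unit (units/day -> cigarettes/day)
DEFAULT_EQUIVALENCE = {
    "cigarettes": 1.0,
    "cigarillos": 1.0,
    "cigars": 1.0,
    "pipe_grams": 1.0,
}

# frequency category -> midpoint days per week
DEFAULT_FREQ_MIDPOINTS = {
    "not this month": 0.0,
    "1 day per month": 0.23,
    "2-3 days per month": 0.58,
    "1 day per week": 1.0,
    "2-3 days per week": 2.5,
    "4-5 days per week": 4.5,
    "6-7 days per week": 6.5,
}

# glasses category -> midpoint glasses per drinking day
DEFAULT_GLASS_MIDPOINTS = {str(k): float(k) for k in range(1, 12)} | {"12 or more": 12.0}

BEVERAGES = (
    "beer",
    "alcohol_free_beer",
    "red_wine",
    "white_wine",
    "sherry",
    "distilled",
    "other",
)

# grams of ethanol per standard glass (Dutch standard glass ~ 10 g)
DEFAULT_ETHANOL_PER_GLASS = {b: 10.0 for b in BEVERAGES} | {"alcohol_free_beer": 0.0}


@dataclass
class AlcoholConfig:
    freq_midpoints: dict = field(default_factory=lambda: dict(DEFAULT_FREQ_MIDPOINTS))
    glass_midpoints: dict = field(default_factory=lambda: dict(DEFAULT_GLASS_MIDPOINTS))
    ethanol_per_glass: dict = field(
        default_factory=lambda: dict(DEFAULT_ETHANOL_PER_GLASS)
    )


def smoking_initiation(ever_smoked_full_year):
    """1 if the respondent ever smoked for a full year, 0 otherwise.

    Smoking for less than a year does not count as initiation.  Missing
    answers propagate as missing (None/NaN).
    """
    if ever_smoked_full_year is None:
        return None
    if isinstance(ever_smoked_full_year, float) and np.isnan(ever_smoked_full_year):
        return float("nan")
    return 1 if bool(ever_smoked_full_year) else 0


def pack_years(
    units_per_day_by_type: dict,
    years: float,
    equivalence_weights: dict | None = None,
) -> float:
    """Cumulative smoking exposure in pack-years.

    pack_years = (sum over products of units/day x cigarette-equivalence) / 20
    x years smoked.  One pack-year equals 20 cigarettes per day for one year.
    """
    weights = equivalence_weights or DEFAULT_EQUIVALENCE
    if years < 0:
        raise ValueError("years smoked must be non-negative")
    total_cig_equiv = 0.0
    for product, units in units_per_day_by_type.items():
        if units < 0:
            raise ValueError(f"negative units/day for {product!r}")
        total_cig_equiv += units * weights.get(product, 1.0)
    return total_cig_equiv / 20.0 * years


def daily_alcohol_grams(record: dict, config: AlcoholConfig | None = None) -> float:
    """Average daily alcohol intake in grams of ethanol per day.

    ``record`` maps beverage -> (frequency category, glasses category); a
    beverage may be omitted or carry frequency 'not this month', contributing
    zero.  Intake = sum over beverages of (days/week midpoint / 7) x glasses
    midpoint x grams ethanol per glass of that beverage.
    """
    cfg = config or AlcoholConfig()
    grams = 0.0
    for beverage, (freq_cat, glass_cat) in record.items():
        if freq_cat not in cfg.freq_midpoints:
            raise ValueError(f"unknown frequency category {freq_cat!r}")
        days_per_week = cfg.freq_midpoints[freq_cat]
        if days_per_week == 0.0:
            continue
        if str(glass_cat) not in cfg.glass_midpoints:
            raise ValueError(f"unknown glasses category {glass_cat!r}")
        glasses = cfg.glass_midpoints[str(glass_cat)]
        grams += days_per_week / 7.0 * glasses * cfg.ethanol_per_glass.get(beverage, 10.0)
    return grams


def lifetime_cannabis(ever_drugs, ever_cannabis):
    """Two-gate recode: ever used cannabis (1) vs never (0).

    The cannabis question is asked only of respondents who ever used drugs; a
    'no' on the drugs gate therefore recodes to 0 without consulting the
    second answer.  A missing drugs gate propagates as missing.
    """
    if ever_drugs is None:
        return None
    if isinstance(ever_drugs, float) and np.isnan(ever_drugs):
        return float("nan")
    if not bool(ever_drugs):
        return 0
    if ever_cannabis is None:
        return None
    if isinstance(ever_cannabis, float) and np.isnan(ever_cannabis):
        return float("nan")
    return 1 if bool(ever_cannabis) else 0
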