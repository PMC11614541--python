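"""Per-diet farm-yield index with propagated error.

Yield condenses three life-history traits into one number per diet,

    yield = (mean adult mass x proportion surviving) / mean days to adulthood,

an index of harvestable output per rearing day.  Its standard error follows
the product/quotient error-propagation formula on relative errors, and the
95% confidence interval is yield +/- 1.96 se.  Mass and days average over
adults within a P:C ratio (pooling cellulose dilutions); the proportion
surviving counts both adults and still-alive juveniles over all enrolled
subjects, replacements included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_95 = 1.96  # critical value for the 95% interval


@dataclass(frozen=True)
class DietSummary:
    """Per-diet summary statistics (means +/- standard errors)."""

    pc_label: str
    mass_mg: float
    mass_se: float
    prop_surviving: float
    prop_se: float
    days_to_adult: float
    days_se: float
    n_adults: int = 0
    n_deaths: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prop_surviving <= 1.0:
            raise ValueError("proportion surviving must lie in [0, 1]")
        if min(self.mass_se, self.prop_se, self.days_se) < 0:
            raise ValueError("standard errors must be nonnegative")
        if self.days_to_adult <= 0 and not np.isnan(self.days_to_adult):
            raise ValueError("days to adulthood must be positive")


@dataclass(frozen=True)
class YieldResult:
    pc_label: str
    value: float
    se: float
    ci_low: float
    ci_high: float


def compute_yield(s: DietSummary) -> float:
    """Point value (mass x proportion surviving) / days to adulthood."""
    if not s.days_to_adult > 0:
        raise ValueError("days to adulthood must be positive")
    return s.mass_mg * s.prop_surviving / s.days_to_adult


def propagate_yield_se(s: DietSummary, y: float) -> float:
    """se = y * sqrt((se_m/m)^2 + (se_s/s)^2 + (se_d/d)^2)."""
    rel = []
    for mean, se in ((s.mass_mg, s.mass_se), (s.prop_surviving, s.prop_se),
                     (s.days_to_adult, s.days_se)):
        if se == 0:
            rel.append(0.0)
        elif mean == 0:
            raise ValueError("relative error undefined: zero mean with nonzero se")
        else:
            rel.append((se / mean) ** 2)
    return float(y * np.sqrt(sum(rel)))


def yield_ci(y: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """y +/- 1.96 se (the critical value is fixed at 1.96 for level 0.95)."""
    if se < 0:
        raise ValueError("se must be nonnegative")
    if level != 0.95:
        from scipy.stats import norm
        z = float(norm.ppf(0.5 + level / 2.0))
    else:
        z = Z_95
    return y - z * se, y + z * se


def display_round(x: float) -> float:
    """Presentation rounding: 2 decimals, 3 when the magnitude is below 0.1."""
    return round(x, 3) if abs(x) < 0.1 else round(x, 2)


def yield_result(s: DietSummary) -> YieldResult:
    y = compute_yield(s)
    se = propagate_yield_se(s, y)
    lo, hi = yield_ci(y, se)
    return YieldResult(pc_label=s.pc_label, value=y, se=se, ci_low=lo, ci_high=hi)


def summarize_by_diet(records) -> list[DietSummary]:
    """Collapse a cohort to per-P:C summaries, pooling cellulose dilutions.

    Mass and days average over adults only; proportion surviving =
    (enrolled - deaths) / enrolled, so survivors count adults, still-alive
    juveniles and other non-death outcomes, with a binomial standard error.
    A diet with zero adults yields NaN mass/days (flagged by n_adults = 0).
    """
    by_pc: dict[str, dict] = {}
    for r in records:
        d = by_pc.setdefault(r.pc_label, {"mass": [], "days": [], "deaths": 0, "n": 0})
        d["n"] += 1
        if r.fate == "died":
            d["deaths"] += 1
        elif r.fate == "adult":
            d["mass"].append(r.adult_mass)
            d["days"].append(r.dev_days)
    out = []
    for pc, d in by_pc.items():
        n, deaths = d["n"], d["deaths"]
        prop = (n - deaths) / n
        prop_se = float(np.sqrt(prop * (1 - prop) / n))
        mass = np.asarray(d["mass"], float)
        days = np.asarray(d["days"], float)
        def _mean_se(x: np.ndarray) -> tuple[float, float]:
            if x.size == 0:
                return float("nan"), 0.0
            se = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
            return float(x.mean()), se
        m, m_se = _mean_se(mass)
        dy, dy_se = _mean_se(days)
        out.append(DietSummary(
            pc_label=pc, mass_mg=m, mass_se=m_se,
            prop_surviving=prop, prop_se=prop_se,
            days_to_adult=dy, days_se=dy_se,
            n_adults=len(d["mass"]), n_deaths=deaths,
        ))
    return out


def yield_table(summaries: list[DietSummary]) -> pd.DataFrame:
    """Full yield table (one row per P:C), raw and display-rounded columns."""
    rows = []
    for s in summaries:
        if s.n_adults == 0 or not s.days_to_adult > 0:
            rows.append({"pc_label": s.pc_label, "yield": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "flag": "no adults"})
            continue
        r = yield_result(s)
        rows.append({
            "pc_label": s.pc_label, "yield": r.value, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high,
            "yield_display": display_round(r.value),
            "ci_low_display": display_round(r.ci_low),
            "ci_high_display": display_round(r.ci_high),
            "flag": "",
        })
    return pd.DataFrame(rows)
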