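"""Two-dish choice experiment: intake targets and the consumption model.

Offered a pure-protein dish (1P:0C) and a pure-carbohydrate dish (0P:1C),
both at 45% cellulose, an animal's cumulative protein:carbohydrate ratio
reveals its self-selected intake target.  Per-group ratios are tested
against the random-feeding expectation of 1:1 with one-sample t-tests on
normalizing transforms (log10 pooled, square root for males, inverse for
females), reported back-transformed.  Weekly amounts eaten are modelled by a
Gamma log-link regression with a per-cricket random intercept, and the
fixed-effect structure (week, food type, sex, week-1 body size and their
interactions) is chosen by the AIC confidence-set procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diets import MICRONUTRIENT_FRACTION
from .glmm import GammaGLMM
from .survival import aic_confidence_set

#: nutrient mass fraction of each single-nutrient dish (45% cellulose dilution)
DISH_NUTRIENT_FRACTION = 1.0 - 0.45 - MICRONUTRIENT_FRACTION

TRANSFORMS = {
    "log10": (np.log10, lambda m: 10.0**m),
    "sqrt": (np.sqrt, lambda m: m**2),
    "inverse": (lambda x: 1.0 / x, lambda m: 1.0 / m),
}


def cumulative_ratio(records: pd.DataFrame) -> float:
    """Cumulative P:C ratio for one cricket's weekly dish records.

    Nutrient intake per dish is dry mass eaten times the dish's nutrient
    fraction; since both dishes share the 45% dilution, the ratio equals the
    ratio of dry-mass totals.
    """
    if len(records) == 0:
        raise ValueError("need at least one week of records")
    p = records["protein_dish_mg"].sum() * DISH_NUTRIENT_FRACTION
    c = records["carb_dish_mg"].sum() * DISH_NUTRIENT_FRACTION
    if c == 0:
        raise ValueError("cumulative ratio undefined: zero carbohydrate total")
    return float(p / c)


def cumulative_ratios(choice: pd.DataFrame) -> pd.DataFrame:
    """Per-cricket cumulative P:C ratios (adults only if an ``adult`` column exists)."""
    df = choice[choice["adult"]] if "adult" in choice.columns else choice
    rows = []
    for cid, grp in df.groupby("cricket_id", sort=False):
        rows.append({"cricket_id": cid, "sex": grp["sex"].iloc[0],
                     "ratio": cumulative_ratio(grp)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntakeTargetResult:
    """One-sample test of a group's intake target against 1:1."""

    group: str
    n: int
    df: int
    mean_ratio: float  # back-transformed
    transform: str
    t: float
    p: float
    shapiro_p: float
    degenerate: bool = False


def intake_target_test(
    ratios: np.ndarray, expected: float = 1.0, transform: str = "log10",
    group: str = "pooled",
) -> IntakeTargetResult:
    """One-sample t-test of transformed P:C ratios against the 1:1 expectation.

    The mean is reported back-transformed; a Shapiro-Wilk normality check on
    the transformed ratios is reported alongside.  Zero within-group variance
    is flagged as degenerate rather than producing an infinite t.
    """
    r = np.asarray(ratios, float)
    if r.size < 3:
        raise ValueError("need at least 3 ratios")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    if np.any(r <= 0):
        bad = np.flatnonzero(r <= 0).tolist()
        raise ValueError(f"nonpositive ratios at positions {bad} "
                         f"cannot be {transform}-transformed")
    fwd, back = TRANSFORMS[transform]
    z = fwd(r)
    mean_back = float(back(z.mean()))
    n = int(r.size)
    if np.allclose(z, z[0]):
        if np.isclose(z[0], fwd(expected)):
            # constant exactly at the null: t = 0 is the natural limit
            return IntakeTargetResult(group=group, n=n, df=n - 1,
                                      mean_ratio=mean_back, transform=transform,
                                      t=0.0, p=1.0, shapiro_p=float("nan"))
        return IntakeTargetResult(group=group, n=n, df=n - 1, mean_ratio=mean_back,
                                  transform=transform, t=float("nan"), p=float("nan"),
                                  shapiro_p=float("nan"), degenerate=True)
    t, p = stats.ttest_1samp(z, fwd(expected))
    shapiro_p = float(stats.shapiro(z).pvalue)
    return IntakeTargetResult(group=group, n=n, df=n - 1, mean_ratio=mean_back,
                              transform=transform, t=float(t), p=float(p),
                              shapiro_p=shapiro_p)


def intake_target_report(choice: pd.DataFrame, expected: float = 1.0) -> list[IntakeTargetResult]:
    """Pooled / male / female intake-target tests with the conventional transforms."""
    ratios = cumulative_ratios(choice)
    out = [intake_target_test(ratios["ratio"].to_numpy(), expected, "log10", "pooled")]
    for sex, tr in (("M", "sqrt"), ("F", "inverse")):
        sub = ratios.loc[ratios["sex"] == sex, "ratio"].to_numpy()
        out.append(intake_target_test(sub, expected, tr, {"M": "male", "F": "female"}[sex]))
    return out


def percent_more(a: float, b: float) -> float:
    """(a - b)/b x 100: how much larger `a` is than `b`, in percent."""
    if b <= 0:
        raise ValueError("reference value must be positive")
    return (a - b) / b * 100.0


# ---------------------------------------------------------------------------
# consumption model


_INTERACTIONS = ("week:diet", "week:sex", "diet:sex")


def _long_format(choice: pd.DataFrame) -> pd.DataFrame:
    """One row per cricket-week-dish with the amount eaten from that dish."""
    base = choice.rename(columns={"size_pc1_week1": "size_week1"})
    rows = []
    for _, r in base.iterrows():
        for diet, col in (("protein", "protein_dish_mg"), ("carb", "carb_dish_mg")):
            rows.append({"cricket_id": r["cricket_id"], "sex": r["sex"],
                         "week": r["week"], "diet": diet, "amount": r[col],
                         "size_week1": r.get("size_week1", 0.0)})
    return pd.DataFrame(rows)


def _design(df: pd.DataFrame, interactions: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    week = df["week"].to_numpy(float)
    diet = (df["diet"] == "protein").to_numpy(float)
    sex = (df["sex"] == "M").to_numpy(float)
    size = df["size_week1"].to_numpy(float)
    cols = {"intercept": np.ones(len(df)), "week": week, "diet[protein]": diet,
            "sex[M]": sex, "size_week1": size}
    if "week:diet" in interactions:
        cols["week:diet[protein]"] = week * diet
    if "week:sex" in interactions:
        cols["week:sex[M]"] = week * sex
    if "diet:sex" in interactions:
        cols["diet[protein]:sex[M]"] = diet * sex
    if "week:diet:sex" in interactions:
        cols["week:diet[protein]:sex[M]"] = week * diet * sex
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def candidate_interaction_sets() -> list[tuple[str, ...]]:
    """Nine fixed-effect candidates: every subset of the two-way interactions
    (all four main effects always included), plus the full three-way model."""
    cands: list[tuple[str, ...]] = []
    for k in range(len(_INTERACTIONS) + 1):
        for combo in combinations(_INTERACTIONS, k):
            cands.append(combo)
    cands.append(_INTERACTIONS + ("week:diet:sex",))
    return cands


@dataclass
class ConsumptionModelReport:
    table: pd.DataFrame  # AIC confidence-set table over candidates
    selected: str
    selected_terms: tuple[str, ...]
    coef: pd.Series
    sigma: float
    shape: float
    zero_replacement: float | None


def consumption_model(
    choice: pd.DataFrame, backend: str = "glmm", n_quad: int = 21
) -> ConsumptionModelReport:
    """Fit the nine-candidate Gamma log-link model set and select by AIC.

    ``backend="glmm"`` fits the random-intercept Gamma GLMM; ``"glm"`` fits
    the zero-random-effect limit (an ordinary Gamma GLM), useful when the
    generator has no between-animal heterogeneity.  Zero amounts are replaced
    by half the smallest positive amount (flagged in the report) so the log
    link is defined.
    """
    long = _long_format(choice)
    y = long["amount"].to_numpy(float)
    zero_repl = None
    if np.any(y <= 0):
        zero_repl = float(y[y > 0].min() / 2.0)
        y = np.where(y <= 0, zero_repl, y)
    groups = long["cricket_id"].to_numpy()

    fits: dict[tuple[str, ...], object] = {}
    cands = []
    for inter in candidate_interaction_sets():
        X, names = _design(long, inter)
        if backend == "glmm":
            model = GammaGLMM(n_quad=n_quad).fit(X, y, groups)
            aic = model.aic_
            coef = pd.Series(model.coef_, index=names)
            extra = (model.sigma_, model.shape_)
        elif backend == "glm":
            import statsmodels.api as sm
            res = sm.GLM(y, X, family=sm.families.Gamma(
                link=sm.families.links.Log())).fit()
            aic = float(res.aic)
            coef = pd.Series(res.params, index=names)
            extra = (0.0, 1.0 / float(res.scale))
        else:
            raise ValueError(f"unknown backend {backend!r}")
        label = "+".join(inter) if inter else "mains-only"
        fits[inter] = (coef, extra)
        cands.append({"name": label, "aic": aic, "terms": set(inter), "k": len(names)})

    cs = aic_confidence_set(cands)
    # selected = lowest-AIC retained model
    sel_row = cs.table[cs.table["retained"]].iloc[0]
    sel_terms = tuple(t for t in (*_INTERACTIONS, "week:diet:sex")
                      if t in sel_row["terms"])
    coef, (sigma, shape) = fits[sel_terms]
    return ConsumptionModelReport(
        table=cs.table, selected=str(sel_row["name"]), selected_terms=sel_terms,
        coef=coef, sigma=sigma, shape=shape, zero_replacement=zero_repl,
    )


def group_phase_daily_intake(total_eaten_mg: float, n_crickets: int, n_days: float) -> float:
    """Descriptive group-phase feeding rate: eaten / crickets / days."""
    if n_crickets <= 0 or n_days <= 0:
        raise ValueError("crickets and days must be positive")
    return total_eaten_mg / n_crickets / n_days
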