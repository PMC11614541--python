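"""Synthetic cohorts with the statistical structure the analysis assumes.

The no-choice generator emulates a hatch-to-adult feeding trial: 7 P:C ratios
x 3 cellulose dilutions x ``n_per_diet`` crickets, weekly dry intake along
nutritional rails, adult traits generated from a known quadratic surface of
cumulative (protein, carbohydrate) intake, piecewise-exponential mortality
with strong early-life cellulose effects, light censoring, and replacement of
subjects that die within the first two weeks.  The choice generator emulates
a two-dish (pure protein vs pure carbohydrate) self-selection experiment with
per-sex intake targets.

Every random draw flows from a single seed through per-subject substreams, so
datasets are reproducible independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .diets import DietSpec, IntakeRecord, derive_fractions, parse_pc_label

STUDY_PC_LABELS: tuple[str, ...] = (
    "8P:1C", "5P:1C", "3P:1C", "1P:1C", "1P:3C", "1P:5C", "1P:8C",
)
CELLULOSE_LEVELS: dict[str, float] = {"low": 0.14, "medium": 0.45, "high": 0.76}
#: Hazard-stratification cutpoints (days): early nymphal, second week, remainder.
INTERVALS: tuple[tuple[float, float], ...] = ((0.0, 7.0), (7.0, 14.0), (14.0, 153.0))
STUDY_END_DAY = 153.0

Fate = Literal["adult", "died", "censored"]


def study_diets() -> dict[str, DietSpec]:
    """The 21 unique diets: 7 P:C ratios at 3 cellulose dilutions."""
    out: dict[str, DietSpec] = {}
    for pc in STUDY_PC_LABELS:
        for name, cell in CELLULOSE_LEVELS.items():
            spec = derive_fractions(parse_pc_label(pc), cell)
            out[f"{pc}|{name}"] = spec
    return out


def sextet_from_optimum(
    p_star: float, c_star: float, peak: float,
    curv_p: float, curv_c: float, curv_pc: float = 0.0,
) -> np.ndarray:
    """Build quadratic-surface coefficients (b0, bP, bC, bPP, bCC, bPC) with a
    prescribed interior maximum at ``(p_star, c_star)`` of height ``peak``.

    ``curv_p``/``curv_c`` are positive downward curvatures; the Hessian
    ``[[-2*curv_p, curv_pc], [curv_pc, -2*curv_c]]`` must be negative definite.
    """
    if curv_p <= 0 or curv_c <= 0 or 4 * curv_p * curv_c <= curv_pc**2:
        raise ValueError("curvatures do not give a negative-definite Hessian")
    b_pp, b_cc, b_pc = -curv_p, -curv_c, curv_pc
    b_p = 2 * curv_p * p_star - curv_pc * c_star
    b_c = 2 * curv_c * c_star - curv_pc * p_star
    b0 = peak - (b_p * p_star + b_c * c_star + b_pp * p_star**2
                 + b_cc * c_star**2 + b_pc * p_star * c_star)
    return np.array([b0, b_p, b_c, b_pp, b_cc, b_pc])


def eval_sextet(beta: np.ndarray, p, c):
    """Evaluate b0 + bP*P + bC*C + bPP*P^2 + bCC*C^2 + bPC*P*C."""
    p = np.asarray(p, float)
    c = np.asarray(c, float)
    return (beta[0] + beta[1] * p + beta[2] * c
            + beta[3] * p**2 + beta[4] * c**2 + beta[5] * p * c)


@dataclass
class SimConfig:
    """Generator parameters.  Defaults encode the emulated study design."""

    seed: int = 0
    n_per_diet: int = 20
    weeks: int = 22
    #: known quadratic trait surfaces over cumulative (P, C) intake (mg)
    true_surface: dict[str, np.ndarray] = field(default_factory=lambda: {
        "mass_mg": sextet_from_optimum(0.532, 0.165, 135.0, 250.0, 120.0, 50.0),
        "size": sextet_from_optimum(0.546, 0.174, 1.5, 4.0, 8.0, 2.0),
    })
    trait_noise_sd: dict[str, float] = field(default_factory=lambda: {
        "mass_mg": 15.0, "size": 0.4,
    })
    #: independent per-trait measurement noise (mm) on the three size traits;
    #: sized so the latent axis carries ~95% of standardized variance
    morpho_noise_sd: tuple[float, float, float] = (0.12, 0.11, 0.10)
    #: baseline per-day mortality rate
    hazard_base: float = 0.012
    #: cellulose-level multiplier per stratification interval (0-7, 7-14, 14-153 d)
    hazard_multipliers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "low": (1.0, 1.0, 1.0),
            "medium": (1.89, 1.0, 1.0),
            "high": (2.74, 6.05, 1.0),
        })
    #: P:C-label multiplier, constant over time.  Values are backed out of
    #: the emulated trial's per-diet survival proportions and development
    #: times, so the moderately protein-biased diet is the configured optimum
    diet_hazard: dict[str, float] = field(default_factory=lambda: {
        "8P:1C": 1.45, "5P:1C": 1.27, "3P:1C": 1.0, "1P:1C": 1.02,
        "1P:3C": 1.17, "1P:5C": 1.18, "1P:8C": 1.27,
    })
    #: per-diet (mean, sd) of days to adult eclosion for subjects that survive
    dev_time_model: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "8P:1C": (73.80, 12.0), "5P:1C": (73.38, 12.0), "3P:1C": (72.43, 12.0),
        "1P:1C": (88.97, 12.0), "1P:3C": (90.67, 12.0), "1P:5C": (92.88, 12.0),
        "1P:8C": (92.27, 12.0),
    })
    sex_ratio: float = 0.5
    censor_prob: float = 0.03
    replacement_window_days: float = 14.0
    #: weekly dry intake: lognormal, median grows geometrically until the
    #: plateau week (appetite saturates in late instars), then stays flat
    intake_median0: float = 0.02
    intake_growth: float = 1.2
    intake_plateau_week: int = 10
    intake_sigma: float = 0.30
    # -- choice experiment --
    n_choice: int = 60
    choice_weeks: int = 8
    choice_n_adults: int = 34
    #: per-sex cumulative P:C intake target (protein/carbohydrate)
    choice_target_ratio: dict[str, float] = field(default_factory=lambda: {
        "M": 1.38, "F": 1.0 / 1.15,
    })
    #: Beta concentration of the weekly protein-dish share around its target
    choice_concentration: float = 400.0
    #: linear drift of the protein share per week (0 = stable preference)
    choice_week_trend: float = 0.0
    choice_total_median0: float = 0.03
    choice_total_growth: float = 1.3
    choice_total_sigma: float = 0.25

    def validate(self) -> None:
        if self.hazard_base <= 0:
            raise ValueError("hazard_base must be positive")
        for k, v in self.diet_hazard.items():
            if v <= 0:
                raise ValueError(f"diet_hazard[{k!r}] must be positive")
        for k, mult in self.hazard_multipliers.items():
            if min(mult) <= 0:
                raise ValueError(f"hazard_multipliers[{k!r}] must be positive")
        for k, (m, s) in self.dev_time_model.items():
            if m <= 0 or s <= 0:
                raise ValueError(f"dev_time_model[{k!r}] must be positive")
        for k, r in self.choice_target_ratio.items():
            if r <= 0:
                raise ValueError(f"choice_target_ratio[{k!r}] must be positive")
        for sd in self.trait_noise_sd.values():
            if sd < 0:
                raise ValueError("trait noise sd must be nonnegative")


@dataclass
class CricketRecord:
    """One experimental subject of the no-choice trial."""

    cricket_id: str
    sex: str
    pc_label: str
    cellulose_level: str
    diet: DietSpec
    weekly: list[IntakeRecord]
    fate: Fate
    fate_day: float
    adult_mass: float | None = None
    head_width: float | None = None
    pronotum_width: float | None = None
    pronotum_length: float | None = None
    dev_days: float | None = None

    @property
    def cumulative(self) -> tuple[float, float]:
        return (sum(r.protein_mg for r in self.weekly),
                sum(r.carb_mg for r in self.weekly))


def _piecewise_exp_time(u: float, rates: Sequence[float]) -> float:
    """Invert the piecewise-exponential survivor function at ``u`` ~ U(0,1).

    Returns inf if the target cumulative hazard is not reached by day 153.
    """
    target = -np.log(u)
    acc = 0.0
    for (lo, hi), rate in zip(INTERVALS, rates):
        seg = rate * (hi - lo)
        if acc + seg >= target:
            return lo + (target - acc) / rate
        acc += seg
    return float("inf")


def piecewise_survival(t: float, rates: Sequence[float]) -> float:
    """Closed-form S(t) = exp(-sum rate x duration) for the interval hazards."""
    h = 0.0
    for (lo, hi), rate in zip(INTERVALS, rates):
        h += rate * (min(t, hi) - lo if t > lo else 0.0)
    return float(np.exp(-h))


def _subject_rng(seed: int, *ids: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, 977, *ids)))


def _simulate_subject(
    cfg: SimConfig, pc_label: str, cell_name: str, diet: DietSpec,
    slot: int, depth: int,
) -> CricketRecord:
    rng = _subject_rng(
        cfg.seed, STUDY_PC_LABELS.index(pc_label),
        list(CELLULOSE_LEVELS).index(cell_name), slot, depth,
    )
    cid = f"{pc_label}|{cell_name}|s{slot:03d}" + ("" if depth == 0 else f"r{depth}")
    sex = "M" if rng.random() < cfg.sex_ratio else "F"

    rates = [cfg.hazard_base * cfg.diet_hazard[pc_label] * m
             for m in cfg.hazard_multipliers[cell_name]]
    death_day = _piecewise_exp_time(rng.random(), rates)
    mean_dev, sd_dev = cfg.dev_time_model[pc_label]
    dev_day = float(np.clip(rng.normal(mean_dev, sd_dev), 21.0, 150.0))
    censor_day = (float(rng.uniform(7.0, STUDY_END_DAY))
                  if rng.random() < cfg.censor_prob else np.inf)

    fate_day = min(death_day, dev_day, censor_day, STUDY_END_DAY)
    if fate_day == censor_day or fate_day == STUDY_END_DAY and dev_day > STUDY_END_DAY:
        fate: Fate = "censored"
    elif fate_day == death_day:
        fate = "died"
    else:
        fate = "adult"

    n_weeks = min(int(np.ceil(fate_day / 7.0)), cfg.weeks)
    weekly: list[IntakeRecord] = []
    for w in range(1, n_weeks + 1):
        median = cfg.intake_median0 * cfg.intake_growth ** (min(w, cfg.intake_plateau_week) - 1)
        dry = float(rng.lognormal(np.log(median), cfg.intake_sigma))
        weekly.append(IntakeRecord(
            cricket_id=cid, week=w, dry_consumed=dry,
            protein_mg=dry * diet.protein_fraction,
            carb_mg=dry * diet.carb_fraction,
        ))

    rec = CricketRecord(
        cricket_id=cid, sex=sex, pc_label=pc_label, cellulose_level=cell_name,
        diet=diet, weekly=weekly, fate=fate, fate_day=fate_day,
    )
    if fate == "adult":
        p_cum, c_cum = rec.cumulative
        mass = eval_sextet(cfg.true_surface["mass_mg"], p_cum, c_cum)
        rec.adult_mass = float(mass + rng.normal(0.0, cfg.trait_noise_sd["mass_mg"]))
        size = eval_sextet(cfg.true_surface["size"], p_cum, c_cum)
        z = float(size + rng.normal(0.0, cfg.trait_noise_sd["size"]))
        m1, m2, m3 = cfg.morpho_noise_sd
        rec.head_width = 5.0 + 0.50 * z + float(rng.normal(0.0, m1))
        rec.pronotum_width = 4.0 + 0.45 * z + float(rng.normal(0.0, m2))
        rec.pronotum_length = 3.0 + 0.40 * z + float(rng.normal(0.0, m3))
        rec.dev_days = fate_day
    return rec


def simulate_no_choice(cfg: SimConfig) -> list[CricketRecord]:
    """Simulate the full no-choice cohort, including replacements.

    Deaths before ``replacement_window_days`` spawn a fresh hatchling on the
    same diet (recursively, as on the bench); both the dead subject and its
    replacement are retained, so total enrolment exceeds the number of slots.
    """
    cfg.validate()
    records: list[CricketRecord] = []
    for pc in STUDY_PC_LABELS:
        for cell in CELLULOSE_LEVELS:
            diet = derive_fractions(parse_pc_label(pc), CELLULOSE_LEVELS[cell])
            for slot in range(cfg.n_per_diet):
                depth = 0
                while True:
                    rec = _simulate_subject(cfg, pc, cell, diet, slot, depth)
                    records.append(rec)
                    if not (rec.fate == "died"
                            and rec.fate_day < cfg.replacement_window_days):
                        break
                    depth += 1
    return records


def apply_replacement(
    cfg: SimConfig, records: list[CricketRecord], window_days: float = 14.0,
) -> list[CricketRecord]:
    """Top up early deaths in an existing cohort with fresh subjects.

    Each death before ``window_days`` that has no replacement yet spawns one
    on the same diet; the dead subject is kept.  Replacements that die early
    are themselves replaced.
    """
    out = list(records)
    seen = {r.cricket_id for r in out}
    frontier = [r for r in out
                if r.fate == "died" and r.fate_day < window_days]
    for rec in frontier:
        slot = int(rec.cricket_id.split("|s")[1][:3])
        depth = rec.cricket_id.count("r") and int(rec.cricket_id.rsplit("r", 1)[1]) or 0
        diet = rec.diet
        d = depth + 1
        while True:
            new = _simulate_subject(cfg, rec.pc_label, rec.cellulose_level, diet, slot, d)
            if new.cricket_id in seen:
                break
            out.append(new)
            seen.add(new.cricket_id)
            if not (new.fate == "died" and new.fate_day < window_days):
                break
            d += 1
    return out


# ---------------------------------------------------------------------------
# tabular views consumed by the analysis stages


def records_to_subjects(records: list[CricketRecord]) -> pd.DataFrame:
    """Survival-analysis view: one row per subject with entry/exit/event."""
    rows = []
    for r in records:
        rows.append({
            "id": r.cricket_id, "sex": r.sex, "pc_label": r.pc_label,
            "cellulose_level": r.cellulose_level, "entry_day": 0.0,
            "exit_day": max(r.fate_day, 0.5), "fate": r.fate,
        })
    return pd.DataFrame(rows)


def records_to_adults(records: list[CricketRecord]) -> pd.DataFrame:
    """Landscape view: adults only, cumulative (P, C) plus traits."""
    rows = []
    for r in records:
        if r.fate != "adult":
            continue
        p, c = r.cumulative
        rows.append({
            "cricket_id": r.cricket_id, "sex": r.sex, "pc_label": r.pc_label,
            "cellulose_level": r.cellulose_level,
            "protein_mg": p, "carb_mg": c,
            "mass_mg": r.adult_mass, "dev_days": r.dev_days,
            "head_width_mm": r.head_width, "pronotum_width_mm": r.pronotum_width,
            "pronotum_length_mm": r.pronotum_length,
        })
    return pd.DataFrame(rows)


def records_to_intakes(records: list[CricketRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for ir in r.weekly:
            rows.append({
                "cricket_id": r.cricket_id, "diet_label": f"{r.pc_label}|{r.cellulose_level}",
                "week": ir.week, "dry_consumed": ir.dry_consumed,
                "protein_mg": ir.protein_mg, "carb_mg": ir.carb_mg,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# choice experiment


def simulate_choice(cfg: SimConfig) -> pd.DataFrame:
    """Simulate the two-dish choice experiment.

    Returns a long table with one row per cricket-week: dry mass eaten from
    the pure-protein (1P:0C) and pure-carbohydrate (0P:1C) dishes, both at
    45% cellulose, plus the dish-side assignment and a week-1 body-size score.
    The weekly protein-dish share is drawn around each sex's intake target so
    the expected cumulative P:C equals the target.
    """
    cfg.validate()
    rows = []
    n_adults = min(cfg.choice_n_adults, cfg.n_choice)
    for i in range(cfg.n_choice):
        rng = _subject_rng(cfg.seed, 7001, i)
        sex = "M" if i % 2 == 0 else "F"  # even split across containers
        target = cfg.choice_target_ratio[sex]
        is_adult = i < n_adults  # survival thinning to the configured adult count
        death_week = cfg.choice_weeks if is_adult else int(rng.integers(2, cfg.choice_weeks))
        size_week1 = float(rng.normal(0.0, 1.0))
        side = "L" if i % 2 == 0 else "R"  # balanced dish-side assignment
        for w in range(1, death_week + 1):
            median = cfg.choice_total_median0 * cfg.choice_total_growth ** (w - 1)
            total = float(rng.lognormal(np.log(median), cfg.choice_total_sigma))
            drift = cfg.choice_week_trend * (w - 1)
            mean_share = np.clip(target / (1.0 + target) + drift, 1e-6, 1 - 1e-6)
            if cfg.choice_concentration == np.inf:
                share = float(mean_share)
            else:
                k = cfg.choice_concentration
                share = float(rng.beta(mean_share * k, (1 - mean_share) * k))
            rows.append({
                "cricket_id": f"ch{i:03d}", "sex": sex, "week": w,
                "protein_dish_mg": total * share,
                "carb_dish_mg": total * (1.0 - share),
                "protein_side": side, "adult": is_adult,
                "size_pc1_week1": size_week1,
            })
    return pd.DataFrame(rows)


def perturb(cfg: SimConfig, **kwargs) -> SimConfig:
    """Copy the config with selected fields replaced (keeps defaults intact)."""
    return replace(cfg, **kwargs)
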