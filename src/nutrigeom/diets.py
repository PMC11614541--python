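"""Diet composition and intake accounting for nutritional-geometry experiments.

A holidic diet is described by its protein:carbohydrate (P:C) ratio and its
cellulose dilution.  Every diet additionally carries a fixed 4.055% block of
lipids and micronutrients, so the digestible-nutrient mass fraction closes as

    nutrient = 1 - cellulose - 0.04055

split between protein and carbohydrate in the P:C proportion.  An animal
confined to one diet moves along a "nutritional rail": the ray through the
origin of (protein, carbohydrate) intake space whose slope is the diet's C:P
composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

#: Fixed mass fraction of lipids + micronutrients in every diet.
MICRONUTRIENT_FRACTION = 0.04055

_LABEL_RE = re.compile(
    r"^\s*(?P<p>\d+(?:\.\d+)?)\s*_?P_?\s*:\s*(?P<c>\d+(?:\.\d+)?)\s*_?C_?\s*$",
    re.IGNORECASE,
)


class DietLabelError(ValueError):
    """Raised when a P:C label cannot be parsed or is degenerate."""


@dataclass(frozen=True)
class PCRatio:
    """A protein:carbohydrate ratio expressed as two nonnegative parts."""

    protein_parts: float
    carb_parts: float

    def __post_init__(self) -> None:
        if self.protein_parts < 0 or self.carb_parts < 0:
            raise DietLabelError("P:C parts must be nonnegative")
        if self.protein_parts == 0 and self.carb_parts == 0:
            raise DietLabelError("P:C parts cannot both be zero")

    @property
    def value(self) -> float:
        """protein/carbohydrate ratio; ``inf`` for a pure-protein diet."""
        if self.carb_parts == 0:
            return float("inf")
        return self.protein_parts / self.carb_parts

    @property
    def protein_share(self) -> float:
        """Fraction of the digestible nutrient mass that is protein."""
        return self.protein_parts / (self.protein_parts + self.carb_parts)

    @property
    def label(self) -> str:
        def _part(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else f"{x:g}"

        return f"{_part(self.protein_parts)}P:{_part(self.carb_parts)}C"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_pc_label(label: str) -> PCRatio:
    """Parse a ``"aP:bC"`` diet label (whitespace/underscore dialects allowed).

    >>> parse_pc_label("3P:1C")
    PCRatio(protein_parts=3.0, carb_parts=1.0)
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise DietLabelError(f"malformed P:C label: {label!r}")
    return PCRatio(float(m.group("p")), float(m.group("c")))


@dataclass(frozen=True)
class DietSpec:
    """A complete diet: P:C ratio, cellulose dilution and derived mass fractions.

    Invariant: ``protein_fraction + carb_fraction + cellulose_fraction +
    micronutrient_fraction == 1`` to within 1e-12.
    """

    pc: PCRatio
    cellulose_fraction: float
    micronutrient_fraction: float = MICRONUTRIENT_FRACTION
    protein_fraction: float = field(init=False)
    carb_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        nutrient = 1.0 - self.cellulose_fraction - self.micronutrient_fraction
        if not 0.0 <= self.cellulose_fraction < 1.0:
            raise ValueError("cellulose_fraction must lie in [0, 1)")
        if nutrient <= 0:
            raise ValueError(
                "cellulose so high that no mass remains for nutrients: "
                f"cellulose={self.cellulose_fraction}, "
                f"micronutrients={self.micronutrient_fraction}"
            )
        object.__setattr__(self, "protein_fraction", nutrient * self.pc.protein_share)
        object.__setattr__(self, "carb_fraction", nutrient * (1.0 - self.pc.protein_share))

    @property
    def label(self) -> str:
        return f"{self.pc.label}@{self.cellulose_fraction:.0%}"


def derive_fractions(pc: PCRatio, cellulose_fraction: float) -> DietSpec:
    """Split the non-cellulose, non-micronutrient mass into P and C fractions."""
    return DietSpec(pc=pc, cellulose_fraction=cellulose_fraction)


@dataclass(frozen=True)
class IntakeRecord:
    """One cricket-week of consumption, in mg dry mass."""

    cricket_id: str
    week: int
    dry_consumed: float
    protein_mg: float
    carb_mg: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.week < 1:
            raise ValueError("weeks are 1-based")
        if min(self.dry_consumed, self.protein_mg, self.carb_mg) < 0:
            raise ValueError("intake components must be nonnegative")


def intake_from_weights(
    before_mg: float, after_mg: float, diet: DietSpec, *, cricket_id: str = "", week: int = 1
) -> IntakeRecord:
    """Turn a dish weighing (before, after) into nutrient intake.

    Apparent negative consumption (dish gained weight, e.g. humidity uptake)
    is clipped to zero and flagged rather than dropped, preserving the week
    count.
    """
    if before_mg < 0 or after_mg < 0:
        raise ValueError("dish weights must be nonnegative")
    dry = before_mg - after_mg
    clipped = dry < 0
    if clipped:
        dry = 0.0
    return IntakeRecord(
        cricket_id=cricket_id,
        week=week,
        dry_consumed=dry,
        protein_mg=dry * diet.protein_fraction,
        carb_mg=dry * diet.carb_fraction,
        clipped=clipped,
    )


@dataclass(frozen=True)
class CumulativeIntake:
    """Total protein and carbohydrate eaten by one subject (mg)."""

    protein_mg: float
    carb_mg: float

    def __post_init__(self) -> None:
        if self.protein_mg < 0 or self.carb_mg < 0:
            raise ValueError("cumulative intake must be nonnegative")

    @classmethod
    def from_records(cls, records: Iterable[IntakeRecord]) -> "CumulativeIntake":
        p = c = 0.0
        for r in records:
            p += r.protein_mg
            c += r.carb_mg
        return cls(p, c)


def intake_ratio(ci: CumulativeIntake) -> float:
    """Protein/carbohydrate ratio of a cumulative intake point.

    Returns ``inf`` for a pure-protein intake; raises if both components are
    zero (the ratio is undefined at the origin).
    """
    if ci.protein_mg == 0 and ci.carb_mg == 0:
        raise ValueError("intake ratio undefined: no protein or carbohydrate consumed")
    if ci.carb_mg == 0:
        return float("inf")
    return ci.protein_mg / ci.carb_mg


def render_ratio(ratio: float) -> str:
    """Render a P/C ratio with the larger side first, 2 decimals.

    ``3.1379 -> "3.14P:1C"``, ``0.1489 -> "1P:6.72C"``.
    """
    if ratio == float("inf"):
        return "1P:0C"
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if ratio >= 1:
        return f"{ratio:.2f}P:1C"
    return f"1P:{1.0 / ratio:.2f}C"


def intake_table(
    weighings: pd.DataFrame, diets: dict[str, DietSpec]
) -> pd.DataFrame:
    """Vectorised intake accounting over a weighing table.

    `weighings` columns: ``cricket_id, diet_label, week, before_mg, after_mg``;
    `diets` maps each diet_label to its DietSpec.  Returns one row per
    cricket-week with dry/protein/carb intake and the clipping flag.
    """
    df = weighings.copy()
    dry = df["before_mg"].to_numpy(float) - df["after_mg"].to_numpy(float)
    clipped = dry < 0
    dry = np.where(clipped, 0.0, dry)
    pfrac = df["diet_label"].map(lambda l: diets[l].protein_fraction).to_numpy(float)
    cfrac = df["diet_label"].map(lambda l: diets[l].carb_fraction).to_numpy(float)
    out = df[["cricket_id", "diet_label", "week"]].copy()
    out["dry_consumed"] = dry
    out["protein_mg"] = dry * pfrac
    out["carb_mg"] = dry * cfrac
    out["clipped"] = clipped
    return out


def cumulative_intakes(intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cumulative (P, C) landscape coordinates from weekly rows."""
    g = intakes.groupby("cricket_id", sort=False)[["protein_mg", "carb_mg"]].sum()
    return g.reset_index()
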