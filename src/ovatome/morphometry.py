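"""Follicle-stage morphometry of ovary sections.

Ciona ovarian follicles grow through stages I (pre-vitellogenic, ~50 um
diameter), II (vitellogenic, ~70 um) and III (post-vitellogenic, ~100 um);
stage IV follicles are ovulated and absent from sections. Follicles are
classified by diameter with boundaries at the midpoints of the nominal stage
diameters (60 and 85 um, half-open upward), and each section is summarized as
counts, occupancy per mm^2 of section area and the stage-III proportion.
Two sections (e.g. mutant vs wildtype) are compared as fold ratios of these
densities. "Follicles/mm^2" and "oocytes/mm^2" are synonyms here; the
package standardizes on follicles/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidInputError

STAGES = ("I", "II", "III")
STAGE_DIAMETERS_UM = {"I": 50.0, "II": 70.0, "III": 100.0}
STAGE_BOUNDARIES_UM = (60.0, 85.0)


@dataclass
class Follicle:
    """One follicle record: a diameter in um, a stage label, or both."""

    follicle_id: str
    diameter_um: float | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.diameter_um is None and self.stage is None:
            raise InvalidInputError(
                f"follicle {self.follicle_id!r}: need diameter or stage"
            )
        if self.diameter_um is not None and self.diameter_um <= 0:
            raise InvalidInputError(
                f"follicle {self.follicle_id!r}: non-positive diameter"
            )
        if self.stage is not None and self.stage not in STAGES:
            raise InvalidInputError(
                f"follicle {self.follicle_id!r}: unknown stage {self.stage!r}"
            )


def classify_stage(
    diameter_um: float,
    boundaries: tuple[float, float] = STAGE_BOUNDARIES_UM,
) -> str:
    """Assign a growth stage from the follicle diameter.

    Stage I below the first boundary, II from the first up to (excluding)
    the second, III at or above the second.
    """
    if diameter_um <= 0:
        raise InvalidInputError(f"diameter must be positive, got {diameter_um}")
    b12, b23 = boundaries
    if not 0 < b12 < b23:
        raise InvalidInputError(f"boundaries must satisfy 0 < b12 < b23, got {boundaries}")
    if diameter_um < b12:
        return "I"
    if diameter_um < b23:
        return "II"
    return "III"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding, matching how report tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SectionSummary:
    """Counts and per-area occupancy of one histological section.

    Densities are follicles/mm^2; ``prop_stage3`` is a percentage and is
    None (undefined) for an empty section. Raw unrounded values are stored;
    ``rounded()`` renders them at report precision (two decimals for the
    stage-III density, one elsewhere).
    """

    area_mm2: float
    n_by_stage: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise InvalidInputError(f"section area must be positive, got {self.area_mm2}")
        for s in STAGES:
            self.n_by_stage.setdefault(s, 0)

    @property
    def n_total(self) -> int:
        return sum(self.n_by_stage.values())

    @property
    def density_total(self) -> float:
        return self.n_total / self.area_mm2

    @property
    def density_stage3(self) -> float:
        return self.n_by_stage["III"] / self.area_mm2

    @property
    def prop_stage3(self) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_by_stage["III"] / self.n_total

    def rounded(self) -> dict[str, float | None]:
        return {
            "area_mm2": self.area_mm2,
            "n_total": self.n_total,
            "n_stage3": self.n_by_stage["III"],
            "density_total": round_half_up(self.density_total, 1),
            "density_stage3": round_half_up(self.density_stage3, 2),
            "prop_stage3": (
                None if self.prop_stage3 is None else round_half_up(self.prop_stage3, 1)
            ),
        }


def summarize_section(
    follicles: Iterable[Follicle],
    area_mm2: float,
    boundaries: tuple[float, float] = STAGE_BOUNDARIES_UM,
) -> SectionSummary:
    """Count follicles per stage (classifying by diameter where no stage
    label is given) and derive the occupancy summary."""
    if area_mm2 <= 0:
        raise InvalidInputError(f"section area must be positive, got {area_mm2}")
    counts = {s: 0 for s in STAGES}
    for f in follicles:
        stage = f.stage if f.stage is not None else classify_stage(f.diameter_um, boundaries)
        counts[stage] += 1
    return SectionSummary(area_mm2=area_mm2, n_by_stage=counts)


def summary_from_counts(
    n_total: int, n_stage3: int, area_mm2: float, n_stage1: int | None = None
) -> SectionSummary:
    """Build a summary directly from printed totals (stage I/II split is
    arbitrary when only the total and the stage-III count are known)."""
    if n_stage3 > n_total:
        raise InvalidInputError("stage-III count exceeds total")
    rest = n_total - n_stage3
    n1 = rest if n_stage1 is None else n_stage1
    return SectionSummary(
        area_mm2=area_mm2,
        n_by_stage={"I": n1, "II": rest - n1, "III": n_stage3},
    )


def compare_sections(a: SectionSummary, b: SectionSummary) -> dict[str, float | None]:
    """Fold ratios a/b of the occupancy statistics.

    A zero denominator yields None (undefined), not an error. Ratios are
    reported raw plus half-up rounded to one decimal.
    """

    def ratio(x: float | None, y: float | None) -> float | None:
        if x is None or y is None or y == 0:
            return None
        return x / y

    out = {
        "density_total_ratio": ratio(a.density_total, b.density_total),
        "density_stage3_ratio": ratio(a.density_stage3, b.density_stage3),
        "prop_stage3_ratio": ratio(a.prop_stage3, b.prop_stage3),
    }
    out.update(
        {
            k + "_rounded": (None if v is None else round_half_up(v, 1))
            for k, v in list(out.items())
        }
    )
    return out


def read_follicles_csv(path) -> list[Follicle]:
    """CSV columns: follicle_id, diameter_um and/or stage."""
    df = pd.read_csv(path)
    if "follicle_id" not in df.columns:
        raise InvalidInputError("follicle CSV needs a follicle_id column")
    out = []
    for row in df.itertuples():
        d = getattr(row, "diameter_um", None)
        s = getattr(row, "stage", None)
        out.append(
            Follicle(
                follicle_id=str(row.follicle_id),
                diameter_um=None if d is None or pd.isna(d) else float(d),
                stage=None if s is None or (isinstance(s, float) and pd.isna(s)) else str(s),
            )
        )
    return out
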