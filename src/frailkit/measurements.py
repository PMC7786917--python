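"""Grading of raw anthropometric and biomarker measurements.

Converts raw clinical readings — height/weight, blood pressure, random
blood sugar (RBS) and the 15-item short Geriatric Depression Scale
(GDS-15) — into the ordinal deficit grades the instrument's graded items
expect.  Each grader is a monotone step function returning a
(label, weight) pair that is a legal level of the corresponding item's
coding scheme; the cut points are configurable because published
deficit-index instruments often state the grade labels without the exact
clinical thresholds.

Default thresholds:

* BMI — WHO adult bands, with underweight pooled into the 0.5 grade
  (underweight is itself a deficit in elderly cohorts): normal
  18.5–24.9 → 0; underweight or overweight 25–29.9 → 0.5; obese
  (>= 30) → 1.
* Blood pressure — WHO/ISH hypertension grades: < 140/90 → Normal (0);
  grade 1 (140–159 or 90–99) → Mild (0.33); grade 2 (160–179 or
  100–109) → Moderate (0.66); grade 3 (>= 180 or >= 110) → Severe (1).
  The worse of the systolic and diastolic grades governs.
* RBS (mmol/L) — < 7.9 → 0; [7.9, 15.0) → 0.5; >= 15.0 → 1.
* GDS-15 total — standard screening bands 0–4 / 5–9 / 10–15 mapped to
  normal / moderate / severe depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Sequence

from .errors import DomainError, ValidationError

__all__ = [
    "GradedLevel",
    "RawMeasurements",
    "compute_bmi",
    "grade_bmi",
    "grade_bp",
    "grade_gds",
    "grade_rbs",
    "grade_measurements",
    "BMI_CUTS",
    "BP_CUTS",
    "GDS_CUTS",
    "RBS_CUTS",
]


@dataclass(frozen=True)
class GradedLevel:
    """An ordinal grade: the scheme label and its deficit weight."""

    label: str
    weight: float


#: (normal_low, normal_high, severe_low): normal band and obesity threshold, kg/m².
BMI_CUTS: tuple[float, float, float] = (18.5, 25.0, 30.0)

#: Systolic and diastolic thresholds (mmHg) for hypertension grades 1/2/3.
BP_CUTS: dict[str, tuple[float, float, float]] = {
    "systolic": (140.0, 160.0, 180.0),
    "diastolic": (90.0, 100.0, 110.0),
}

#: RBS grade boundaries, mmol/L.
RBS_CUTS: tuple[float, float] = (7.9, 15.0)

#: GDS-15 totals at which moderate and severe depression begin.
GDS_CUTS: tuple[int, int] = (5, 10)


def compute_bmi(height_m: float, weight_kg: float) -> float:
    """Body-mass index weight/height², with a plausibility screen on inputs."""
    if not 0.5 < height_m < 2.5:
        raise ValidationError(f"height {height_m} m outside the plausible range (0.5, 2.5)")
    if not 20.0 < weight_kg < 300.0:
        raise ValidationError(f"weight {weight_kg} kg outside the plausible range (20, 300)")
    return weight_kg / height_m**2


def grade_bmi(bmi: float, cuts: tuple[float, float, float] = BMI_CUTS) -> GradedLevel:
    """Grade a BMI value: Normal = 0, Moderate = 0.5, Severe = 1."""
    if bmi <= 0:
        raise DomainError(f"BMI must be positive, got {bmi}")
    lo, hi, severe = cuts
    if bmi >= severe:
        return GradedLevel("Severe", 1.0)
    if lo <= bmi < hi:
        return GradedLevel("Normal", 0.0)
    return GradedLevel("Moderate", 0.5)


def grade_rbs(rbs_mmol_l: float, cuts: tuple[float, float] = RBS_CUTS) -> GradedLevel:
    """Grade random blood sugar: < 7.9 normal, [7.9, 15.0) elevated, >= 15.0 high."""
    if rbs_mmol_l < 0:
        raise DomainError(f"RBS must be non-negative, got {rbs_mmol_l}")
    if rbs_mmol_l < cuts[0]:
        return GradedLevel("Normal", 0.0)
    if rbs_mmol_l < cuts[1]:
        return GradedLevel("Elevated", 0.5)
    return GradedLevel("High", 1.0)


_BP_LEVELS = (
    GradedLevel("Normal", 0.0),
    GradedLevel("Mild", 0.33),
    GradedLevel("Moderate", 0.66),
    GradedLevel("Severe", 1.0),
)


def _bp_grade_index(value: float, cuts: tuple[float, float, float]) -> int:
    g1, g2, g3 = cuts
    if value >= g3:
        return 3
    if value >= g2:
        return 2
    if value >= g1:
        return 1
    return 0


def grade_bp(
    systolic: float | Sequence[float],
    diastolic: float | Sequence[float],
    cuts: dict[str, tuple[float, float, float]] | None = None,
) -> GradedLevel:
    """Grade blood pressure by hypertension grade; the worse reading governs.

    Sequences of up to three repeated readings are averaged per arm before
    grading.
    """
    cuts = cuts or BP_CUTS
    if not isinstance(systolic, (int, float)):
        systolic = fmean(systolic)
    if not isinstance(diastolic, (int, float)):
        diastolic = fmean(diastolic)
    if not systolic > diastolic > 0:
        raise ValidationError(
            f"require systolic > diastolic > 0, got {systolic}/{diastolic} mmHg"
        )
    idx = max(
        _bp_grade_index(systolic, cuts["systolic"]),
        _bp_grade_index(diastolic, cuts["diastolic"]),
    )
    return _BP_LEVELS[idx]


def grade_gds(gds_total: int, cuts: tuple[int, int] = GDS_CUTS) -> GradedLevel:
    """Grade a GDS-15 total (0–15) into normal/moderate/severe depression."""
    if not float(gds_total).is_integer() or not 0 <= gds_total <= 15:
        raise DomainError(f"GDS-15 total must be an integer in [0, 15], got {gds_total}")
    if gds_total >= cuts[1]:
        return GradedLevel("Severe depression", 1.0)
    if gds_total >= cuts[0]:
        return GradedLevel("Moderate depression", 0.5)
    return GradedLevel("Normal depression", 0.0)


@dataclass(frozen=True)
class RawMeasurements:
    """One subject's raw clinical readings."""

    height_m: float
    weight_kg: float
    systolic: float
    diastolic: float
    rbs_mmol_l: float
    gds_total: int | None = None
    gds_items: tuple[int, ...] | None = None  # 15 binary answers, alternative to the total

    def __post_init__(self) -> None:
        if self.gds_total is None and self.gds_items is None:
            raise ValidationError("provide gds_total or the 15 gds_items")
        if self.gds_items is not None:
            if len(self.gds_items) != 15 or any(a not in (0, 1) for a in self.gds_items):
                raise ValidationError("gds_items must be 15 binary answers")

    @property
    def gds(self) -> int:
        return self.gds_total if self.gds_total is not None else sum(self.gds_items)


def grade_measurements(raw: RawMeasurements) -> dict[str, GradedLevel]:
    """Grade all measured deficits, keyed by the registry item names."""
    return {
        "bmi_grade": grade_bmi(compute_bmi(raw.height_m, raw.weight_kg)),
        "hbp_grade": grade_bp(raw.systolic, raw.diastolic),
        "rbs_grade": grade_rbs(raw.rbs_mmol_l),
        "gds_grade": grade_gds(raw.gds),
    }
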