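"""Health-economic cost model for 5-year CVD risk management.

Monetises risk-category membership: each category implies a number of
follow-up assessments over 5 years (low 2, moderate 3, high 5), each
assessment a fixed consultation/diagnostic bundle, and the moderate and high
categories a daily medication bundle (statin + antihypertensive, plus an
antithrombotic for high risk) costed over 365 x 5 days.  Every unit cost
carries min/mid/max tiers.

Overtreatment (a low-risk person managed as moderate) is monetised as the
incremental 5-year cost between the two categories.  Undertreatment is not
given a point estimate: the avoidable inpatient cost of a cardiovascular
event is reported as a scenario band (general ward to ICU) per person.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from .errors import ConfigurationError, InputError

__all__ = [
    "TIERS",
    "CostSchedule",
    "CostEstimate",
    "annual_consultation_cost",
    "five_year_cost",
    "misclassification_cost",
]

TIERS = ("min", "mid", "max")
_CATEGORIES = ("low", "moderate", "high")
_DAYS_PER_YEAR = 365  # no leap days; validated against the published 5-year totals


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs and per-category frequencies (all amounts NZD)."""

    consultation: dict[str, dict[str, float]]
    assessments_per_5y: dict[str, int]
    medication_daily: dict[str, dict[str, float]]
    medication_bundle: dict[str, list[str]]
    inpatient_event_cost: dict[str, float]
    version: int = 1

    def __post_init__(self) -> None:
        for group in (self.consultation, self.medication_daily):
            for item, tiers in group.items():
                if not tiers["min"] <= tiers["mid"] <= tiers["max"]:
                    raise ConfigurationError(f"cost item {item!r} violates min <= mid <= max")
        for cat, freq in self.assessments_per_5y.items():
            if not (isinstance(freq, int) and freq > 0):
                raise ConfigurationError(f"assessment frequency for {cat!r} must be a positive integer")
        for cat, meds in self.medication_bundle.items():
            unknown = [m for m in meds if m not in self.medication_daily]
            if unknown:
                raise ConfigurationError(f"unknown medication(s) in bundle {cat!r}: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "CostSchedule":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload.pop("currency", None)
        return cls(**payload)

    @classmethod
    def default(cls) -> "CostSchedule":
        """The bundled schedule mirroring the published cost tables."""
        ref = importlib.resources.files("bpround.data") / "cost_schedule.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass(frozen=True)
class CostEstimate:
    """5-year per-person cost of managing one risk category, by tier."""

    category: str
    consultation_5y: dict[str, float]
    medication_5y: dict[str, float]
    total_5y: dict[str, float]


def annual_consultation_cost(schedule: CostSchedule, tier: str) -> float:
    """Cost of one year's consultation/diagnostic bundle at a tier."""
    if tier not in TIERS:
        raise InputError(f"tier must be one of {TIERS}, got {tier!r}")
    return round(sum(item[tier] for item in schedule.consultation.values()), 2)


def five_year_cost(schedule: CostSchedule, category: str) -> CostEstimate:
    """Per-person 5-year management cost for a risk category.

    Consultation: annual bundle x category assessment frequency.
    Medication: category bundle daily cost x 365 x 5 (zero for low risk).
    """
    if category not in _CATEGORIES:
        raise InputError(f"category must be one of {_CATEGORIES}, got {category!r}")
    freq = schedule.assessments_per_5y[category]
    meds = schedule.medication_bundle[category]
    consultation = {t: round(annual_consultation_cost(schedule, t) * freq, 2) for t in TIERS}
    medication = {
        t: round(sum(schedule.medication_daily[m][t] for m in meds) * _DAYS_PER_YEAR * 5, 2)
        for t in TIERS
    }
    total = {t: round(consultation[t] + medication[t], 2) for t in TIERS}
    return CostEstimate(category, consultation, medication, total)


def misclassification_cost(
    overtreated_to_moderate: float,
    undertreated: float,
    schedule: CostSchedule | None = None,
) -> dict:
    """Financial impact of risk-category misclassification.

    Overtreatment into the moderate category costs the incremental 5-year
    spend per person, ``moderate total - low total``, at the mid tier, with a
    max-tier bound.  Undertreatment is reported as the count together with
    the avoidable inpatient cost range per patient (scenario band, not an
    estimate).
    """
    if overtreated_to_moderate < 0 or undertreated < 0:
        raise InputError("misclassification counts must be non-negative")
    if schedule is None:
        schedule = CostSchedule.default()
    low = five_year_cost(schedule, "low")
    moderate = five_year_cost(schedule, "moderate")
    incr_mid = moderate.total_5y["mid"] - low.total_5y["mid"]
    incr_max = moderate.total_5y["max"] - low.total_5y["max"]
    inpatient = schedule.inpatient_event_cost
    return {
        "overtreated_to_moderate": overtreated_to_moderate,
        "incremental_cost_per_person_mid": round(incr_mid, 2),
        "incremental_cost_per_person_max": round(incr_max, 2),
        "overtreatment_cost_mid": round(overtreated_to_moderate * incr_mid, 2),
        "overtreatment_cost_max": round(overtreated_to_moderate * incr_max, 2),
        "undertreated": undertreated,
        "undertreatment_scenario_band": (
            round(undertreated * inpatient["min"], 2),
            round(undertreated * inpatient["max"], 2),
        ),
        "inpatient_cost_per_patient_range": (inpatient["min"], inpatient["max"]),
    }
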