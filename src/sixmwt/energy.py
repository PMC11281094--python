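"""Walking energy expenditure for the 6MWT.

Basal metabolic rate comes from the Harris–Benedict equations (kcal/day),
the walking metabolic equivalent (MET) from a linear form in gait
velocity, weight and gender, and the six-minute walking energy
expenditure is BMR × MET × duration.  BMR is converted to kcal/h (÷24)
before the product and a 6-minute test contributes duration 0.1 h; the
result is reported in the kcal/h convention of the source tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import Gender, SubjectRecord


@dataclass
class EnergyInputs:
    """Intermediate quantities of the energy computation."""

    bmr_day: float   # kcal/day
    met: float       # dimensionless
    duration: float  # h

    def __post_init__(self) -> None:
        if not self.bmr_day > 0:
            raise ValueError("bmr_day must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")

    @property
    def bmr_hour(self) -> float:
        return self.bmr_day / 24.0


def bmr_harris_benedict(weight: float, height: float, age: float, gender: Gender) -> float:
    """Basal metabolic rate [kcal/day] from the Harris–Benedict equations.

    weight in kg, height in cm, age in years; gender 1 (male) or 2 (female).
    """
    if not (weight > 0 and height > 0 and age > 0):
        raise ValueError("weight, height and age must all be positive")
    gender = Gender(gender)
    if gender is Gender.MALE:
        return 66.4730 + 13.7516 * weight + 5.0033 * height - 6.7550 * age
    return 655.0955 + 9.5634 * weight + 1.8496 * height - 4.6756 * age


def met_walking(gv: float, weight: float, gender: Gender) -> float:
    """Metabolic equivalent of walking at gait velocity gv [m/s].

    MET = 0.832·GV − 0.016·W − 0.196·G + 1.034 with G coded 1 (male) /
    2 (female).  Evaluated verbatim — no flooring at 1.0, so slow walkers
    can score below resting level.
    """
    if gv < 0:
        raise ValueError("gv must be non-negative")
    g = int(Gender(gender))
    return 0.832 * gv - 0.016 * weight - 0.196 * g + 1.034


def six_mwee(bmr_day: float, met: float, duration: float = 0.1) -> float:
    """Six-minute walking energy expenditure [kcal/h convention].

    (BMR/24) × MET × duration, duration in hours (0.1 h for a 6-min test).
    """
    inputs = EnergyInputs(bmr_day=bmr_day, met=met, duration=duration)
    return inputs.bmr_hour * inputs.met * inputs.duration


def walking_energy(subject: SubjectRecord, gv: float, duration: float = 0.1) -> float:
    """Convenience: 6MWEE for a subject at measured gait velocity."""
    missing = [k for k in ("weight", "height", "age", "gender") if getattr(subject, k) is None]
    if missing:
        raise ValueError(f"subject {subject.subject_id}: missing fields {missing}")
    bmr = bmr_harris_benedict(subject.weight, subject.height, subject.age, subject.gender)
    met = met_walking(gv, subject.weight, subject.gender)
    return six_mwee(bmr, met, duration)
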