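"""Hypertensive-retinopathy grading from the arteriovenous ratio.

The tabulated anchors (normal 0.667-0.75, mild at 0.5, moderate at 0.25,
malignant below 0.2) are point values; the rule makes them total by
cutting halfway between adjacent anchors with left-closed bins:

    avr >= 0.6        -> normal
    0.4 <= avr < 0.6  -> mild
    0.2 <= avr < 0.4  -> moderate
    avr < 0.2         -> malignant

AVR above 0.75 is graded normal but flagged as out-of-table.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HRGrade", "grade_from_avr", "classify_binary", "RULE_VERSION"]

RULE_VERSION = "anchor-midpoint-v1"

_SEVERITY = {"normal": 0, "mild": 1, "moderate": 2, "malignant": 3}


@dataclass(frozen=True)
class HRGrade:
    grade: str
    avr: float
    decision_rule: str = RULE_VERSION
    out_of_table: bool = False

    @property
    def severity(self) -> int:
        return _SEVERITY[self.grade]


def grade_from_avr(avr: float) -> HRGrade:
    """Map a positive AVR to an HR grade (see module docstring)."""
    if not avr > 0:
        raise ValueError(f"AVR must be positive, got {avr}")
    if avr >= 0.6:
        return HRGrade("normal", avr, out_of_table=avr > 0.75)
    if avr >= 0.4:
        return HRGrade("mild", avr)
    if avr >= 0.2:
        return HRGrade("moderate", avr)
    return HRGrade("malignant", avr)


def classify_binary(grade: HRGrade) -> str:
    """Collapse the grade to the normal / HR decision."""
    return "normal" if grade.grade == "normal" else "HR"
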