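"""ICD-10 cause-code classification for fall-mortality quality analysis.

Codes arrive in the WHO Mortality Database 4-character dialect: an
uppercase letter, two digits, and an optional 4th character (no decimal
point, so ICD-10 ``Y87.2`` appears as ``Y872``).  Classification is into
overlapping analysis categories: a fall is also an unintentional injury
and an injury.  The category spans are the conventional ICD-10
external-cause blocks:

* unspecified deaths (ill-defined): R96, R98, R99
* injury (external causes incl. sequelae): V01-Y89
* undetermined intent: Y30, Y31, Y34, Y87.2, Y89.9
* unintentional injury: V01-X59
* unspecified unintentional injury: X59
* unintentional fall: W00-W19; W19 = fall with unspecified mechanism
* place of occurrence: 4th character of W00-W19, '9' = unknown place
"""

from __future__ import annotations

import enum
import re

__all__ = [
    "CauseCategory",
    "PlaceOfOccurrence",
    "InvalidCauseCode",
    "classify",
    "place_of_occurrence",
    "category_table",
]

_CODE_RE = re.compile(r"^([A-Z])(\d{2})([0-9]?)$")


class InvalidCauseCode(ValueError):
    """Raised for a cause string that is not letter + 2 digits (+ optional digit)."""


class CauseCategory(enum.Flag):
    """Overlapping membership flags for an ICD-10 cause code."""

    NONE = 0
    UNSPECIFIED_DEATH = enum.auto()
    INJURY = enum.auto()
    UNDETERMINED_INTENT = enum.auto()
    UNINTENTIONAL_INJURY = enum.auto()
    UNSPECIFIED_UNINTENTIONAL = enum.auto()
    FALL = enum.auto()
    FALL_UNSPECIFIED_MECHANISM = enum.auto()


class PlaceOfOccurrence(enum.Enum):
    KNOWN = "known"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


def _parse(cause: str) -> tuple[str, int, str]:
    m = _CODE_RE.match(cause.strip().upper() if isinstance(cause, str) else "")
    if not m:
        raise InvalidCauseCode(f"malformed ICD-10 cause code: {cause!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def classify(cause: str) -> CauseCategory:
    """Classify one ICD-10 cause code into the analysis categories.

    Pure function of the code string.  Raises :class:`InvalidCauseCode`
    on anything that is not letter + two digits + optional digit.
    """
    letter, num, fourth = _parse(cause)
    flags = CauseCategory.NONE

    if letter == "R" and num in (96, 98, 99):
        return CauseCategory.UNSPECIFIED_DEATH

    # injury universe V01-Y89 (external causes, incl. sequelae Y85-Y89)
    injury = (
        (letter == "V" and num >= 1)
        or letter in ("W", "X")
        or (letter == "Y" and num <= 89)
    )
    if injury:
        flags |= CauseCategory.INJURY

    # undetermined intent: Y30/Y31/Y34 (any 4th digit), Y87.2, Y89.9
    if letter == "Y" and (
        num in (30, 31, 34)
        or (num == 87 and fourth == "2")
        or (num == 89 and fourth == "9")
    ):
        flags |= CauseCategory.UNDETERMINED_INTENT

    # unintentional universe V01-X59 (sequelae Y85-Y86 deliberately excluded)
    if (letter == "V" and num >= 1) or letter == "W" or (letter == "X" and num <= 59):
        flags |= CauseCategory.UNINTENTIONAL_INJURY
        if letter == "X" and num == 59:
            flags |= CauseCategory.UNSPECIFIED_UNINTENTIONAL
        if letter == "W" and num <= 19:
            flags |= CauseCategory.FALL
            if num == 19:
                flags |= CauseCategory.FALL_UNSPECIFIED_MECHANISM

    return flags


def place_of_occurrence(
    cause: str, *, missing_is_unknown: bool = True
) -> PlaceOfOccurrence:
    """Extract the place-of-occurrence 4th digit of a fall code.

    For W00-W19, a 4th character of '9' means unknown place; '0'-'8' are
    specified places.  A 3-character fall code carries no place at all and
    counts as unknown under the default policy (the information is
    unrecoverable), or as known when ``missing_is_unknown=False``.
    Non-fall codes are not applicable.
    """
    letter, num, fourth = _parse(cause)
    if not (letter == "W" and num <= 19):
        return PlaceOfOccurrence.NOT_APPLICABLE
    if fourth == "":
        return (
            PlaceOfOccurrence.UNKNOWN if missing_is_unknown else PlaceOfOccurrence.KNOWN
        )
    return PlaceOfOccurrence.UNKNOWN if fourth == "9" else PlaceOfOccurrence.KNOWN


def category_table() -> list[dict[str, str]]:
    """Machine-readable summary of the compiled-in category ranges."""
    return [
        {"category": "UNSPECIFIED_DEATH", "codes": "R96, R98, R99"},
        {"category": "INJURY", "codes": "V01-Y89"},
        {"category": "UNDETERMINED_INTENT", "codes": "Y30, Y31, Y34, Y87.2, Y89.9"},
        {"category": "UNINTENTIONAL_INJURY", "codes": "V01-X59"},
        {"category": "UNSPECIFIED_UNINTENTIONAL", "codes": "X59"},
        {"category": "FALL", "codes": "W00-W19"},
        {"category": "FALL_UNSPECIFIED_MECHANISM", "codes": "W19"},
    ]
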