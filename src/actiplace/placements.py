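"""Body-placement vocabulary and single-letter codes.

Five wear sites are supported. Each has a fixed single-letter code used to
name placement combinations compactly (e.g. ``"CE"`` = hip + wrist). Codes
are always emitted with their letters in alphabetical order.
"""

from __future__ import annotations

from collections.abc import Iterable

#: Canonical placement order (matches the fixed feature-column order).
PLACEMENTS: tuple[str, ...] = ("ankle", "upper_arm", "hip", "thigh", "wrist")

#: Single-letter code per placement.
PLACEMENT_CODES: dict[str, str] = {
    "ankle": "A",
    "upper_arm": "B",
    "hip": "C",
    "thigh": "D",
    "wrist": "E",
}

CODE_TO_PLACEMENT: dict[str, str] = {v: k for k, v in PLACEMENT_CODES.items()}

#: Most-to-least wearable placement preference used to break selection ties.
DEFAULT_USABILITY_ORDER: tuple[str, ...] = (
    "wrist",
    "hip",
    "ankle",
    "upper_arm",
    "thigh",
)


def validate_placement(placement: str) -> str:
    """Return *placement* if it is in the vocabulary, else raise ValueError."""
    if placement not in PLACEMENT_CODES:
        raise ValueError(
            f"unknown placement {placement!r}; expected one of {PLACEMENTS}"
        )
    return placement


def placements_to_code(members: Iterable[str]) -> str:
    """Map a set of placements to its sorted letter code (``{'hip','wrist'}`` -> ``'CE'``)."""
    letters = sorted(PLACEMENT_CODES[validate_placement(p)] for p in set(members))
    if not letters:
        raise ValueError("placement set must be non-empty")
    return "".join(letters)


def code_to_placements(code: str) -> tuple[str, ...]:
    """Inverse of :func:`placements_to_code`, preserving canonical order."""
    if not code:
        raise ValueError("placement code must be non-empty")
    members = set()
    for letter in code:
        if letter not in CODE_TO_PLACEMENT:
            raise ValueError(f"unknown placement code letter {letter!r}")
        members.add(CODE_TO_PLACEMENT[letter])
    return tuple(p for p in PLACEMENTS if p in members)
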