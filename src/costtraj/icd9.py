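"""ICD-9-CM code pattern matching.

Disease definitions are expressed as patterns over canonical (dot-free)
ICD-9-CM codes:

* ``"410.xx"`` — any code whose three-digit root is 410, with any (or no)
  fourth and fifth digits;
* ``"433.x1"`` — a five-digit code with root 433, any fourth digit and
  fifth digit 1;
* ``"331.0"``  — root 331 with fourth digit 0 and any (or no) fifth digit.

Codes are canonicalized by stripping an embedded dot: ``"433.01" -> "43301"``.
"""

from __future__ import annotations

import re

__all__ = ["PatternError", "canonicalize", "match_icd9", "example_code"]

_PATTERN_RE = re.compile(r"^(\d{3})\.([0-9x])([0-9x])?$")


class PatternError(ValueError):
    """Raised for an ICD-9 pattern that does not parse."""


def canonicalize(code: str) -> str:
    """Return *code* without an embedded dot, stripped of whitespace."""
    return str(code).strip().replace(".", "")


def _parse(pattern: str) -> tuple[str, str, str | None]:
    m = _PATTERN_RE.match(pattern.strip())
    if m is None:
        raise PatternError(f"malformed ICD-9 pattern: {pattern!r}")
    return m.group(1), m.group(2), m.group(3)


def match_icd9(code: str, pattern: str) -> bool:
    """True if canonical ICD-9 *code* satisfies *pattern*.

    ``NNN.xx`` matches any code with root NNN; ``NNN.x1`` matches only
    five-digit codes with fifth digit 1; ``NNN.D`` matches root NNN with
    fourth digit D and any or no fifth digit.
    """
    root, d4, d5 = _parse(pattern)
    c = canonicalize(code)
    if len(c) < 3 or not c[:3] == root:
        return False
    if d4 != "x":
        if len(c) < 4 or c[3] != d4:
            return False
    if d5 is not None and d5 != "x":
        # a constrained fifth digit requires a five-digit code
        if len(c) < 5 or c[4] != d5:
            return False
    return True


def example_code(pattern: str) -> str:
    """A concrete five-digit (or four-digit) code satisfying *pattern*.

    Used by the claims simulator to emit qualifying diagnosis codes.
    """
    root, d4, d5 = _parse(pattern)
    four = d4 if d4 != "x" else "0"
    if d5 is None:
        return root + four  # e.g. "331.0" -> "3310"
    five = d5 if d5 != "x" else "0"
    return root + four + five
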