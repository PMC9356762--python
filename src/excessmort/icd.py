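"""ICD-10 underlying-cause-of-death grouping.

Maps ICD-10 codes into the five analysis categories used throughout the
package — respiratory disease, circulatory disease, malignant neoplasms,
senility, and COVID-19 — plus a catch-all OTHER, so that every well-formed
code belongs to exactly one category (the mapping is a partition).

The code ranges are shipped as a versioned plain-text table
(``data/icd10_cause_map.tsv``) so the grouping can be audited or edited
without touching code.  Codes are matched at 3-character block resolution
(e.g. ``J12``) except where a rule is stated at 4-character resolution
(e.g. ``R09.2``), in which case the 4-character rule takes precedence.

The COVID-19 emergency code is ``U07.1``; the common shorthand spelling
``U7.1`` is accepted on input and normalised to the same code.  ``U07.2``
(probable/clinically-diagnosed COVID-19) is deliberately *not* treated as
COVID-19 here, since only the laboratory-confirmed code is excluded from
the non-COVID all-cause series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources


class CauseCategory(str, Enum):
    """Analysis category for an underlying cause of death."""

    RESPIRATORY = "RESPIRATORY"
    CIRCULATORY = "CIRCULATORY"
    MALIGNANT_NEOPLASM = "MALIGNANT_NEOPLASM"
    SENILITY = "SENILITY"
    COVID19 = "COVID19"
    OTHER = "OTHER"


class IcdClassificationError(ValueError):
    """Raised when a cause-of-death code cannot be parsed as ICD-10."""


# letter + 1-2 digits, optional "." + 1-2 subcode digits ("U7.1", "J12.9")
_DOTTED_RE = re.compile(r"([A-Z])(\d{1,2})(?:\.(\d{1,2}))?$")
# undotted 4-5 character form ("J129", "R092")
_COMPACT_RE = re.compile(r"([A-Z])(\d{2})(\d{1,2})$")


@dataclass(frozen=True)
class IcdCode:
    """A parsed ICD-10 code.

    Attributes
    ----------
    raw
        The text as supplied (whitespace/case preserved).
    letter, num, sub
        Components of the normalised code: chapter letter, two-digit
        block number, and optional subcode digits.
    """

    raw: str
    letter: str
    num: int
    sub: str | None

    @property
    def block(self) -> str:
        """3-character block, e.g. ``"J12"`` for ``"J12.9"``."""
        return f"{self.letter}{self.num:02d}"

    @property
    def normalized(self) -> str:
        """Canonical spelling: block plus dotted subcode if present."""
        return self.block if self.sub is None else f"{self.block}.{self.sub}"

    @classmethod
    def parse(cls, text: str) -> "IcdCode":
        s = str(text).strip().upper()
        m = _DOTTED_RE.fullmatch(s) or _COMPACT_RE.fullmatch(s)
        if m is None:
            raise IcdClassificationError(
                f"not a recognisable ICD-10 code: {text!r}"
            )
        letter, num, sub = m.group(1), int(m.group(2)), m.group(3)
        return cls(raw=str(text), letter=letter, num=num, sub=sub)


def _parse_endpoint(text: str) -> tuple[str, int, str | None]:
    code = IcdCode.parse(text)
    return code.letter, code.num, code.sub


@lru_cache(maxsize=1)
def load_cause_map() -> tuple[tuple[CauseCategory, str, str], ...]:
    """Load the (category, range_start, range_end) rules from package data."""
    rules: list[tuple[CauseCategory, str, str]] = []
    table = resources.files("excessmort").joinpath("data/icd10_cause_map.tsv")
    for line in table.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cat, start, end = line.split("\t")
        rules.append((CauseCategory(cat), start, end))
    return tuple(rules)


@lru_cache(maxsize=8192)
def classify_cause(code: str | IcdCode) -> CauseCategory:
    """Return the unique analysis category for an ICD-10 code.

    A 4-character input is first checked against 4-character rules
    (``R09.2``, ``U07.1``), then falls back to its 3-character block.
    Codes outside every listed range map to :attr:`CauseCategory.OTHER`.

    Raises
    ------
    IcdClassificationError
        If ``code`` cannot be parsed; the message names the raw text.
    """
    parsed = code if isinstance(code, IcdCode) else IcdCode.parse(code)
    rules = load_cause_map()

    # pass 1: subcode-resolution rules
    if parsed.sub is not None:
        for cat, start, end in rules:
            if "." not in start:
                continue
            s = _parse_endpoint(start)
            e = _parse_endpoint(end)
            key = (parsed.letter, parsed.num, parsed.sub)
            if s <= key <= e:
                return cat
    # pass 2: block-resolution rules
    key2 = (parsed.letter, parsed.num)
    for cat, start, end in rules:
        if "." in start:
            continue
        s = _parse_endpoint(start)[:2]
        e = _parse_endpoint(end)[:2]
        if s <= key2 <= e:
            return cat
    return CauseCategory.OTHER


def non_covid_all_cause(code: str | IcdCode) -> bool:
    """True iff the code does not classify as COVID-19."""
    return classify_cause(code) is not CauseCategory.COVID19
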