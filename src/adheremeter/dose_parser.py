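"""Rule-based parsing of free-text dose directions.

Dose directions in primary-care prescribing are short free-text strings
("TWO PUFFS TWICE A DAY", "1 od", "2 puffs bd prn") from which two numbers
must be recovered to compute an expected supply duration: the dose quantity
(units per administration) and the frequency (administrations per day).
Parsing is deliberately rule-based — token tables of number words, unit
words, frequency phrases and Latin abbreviations — so the behaviour is
transparent, auditable, and extensible to other conditions by editing the
shipped rule tables (``data/dose_rules.yaml``).

Parse failures are values, not exceptions: the pipeline counts them and
falls back to configured formulation defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping

import yaml


class Provenance(str, Enum):
    PARSED = "parsed"
    DEFAULT = "default"
    OVERRIDE = "override"


class RangePolicy(str, Enum):
    """How a quantity range ("1-2 puffs") resolves to a single number.

    The default is MAX: under-estimating daily use inflates apparent
    oversupply, so the conservative reading for adherence estimation is the
    top of the directed range.
    """

    MIN = "min"
    MAX = "max"
    MEAN = "mean"


@dataclass(frozen=True)
class DoseRegimen:
    """Structured daily dosing: units per administration x times per day."""

    dose_quantity: float
    frequency_per_day: float
    as_needed: bool = False
    provenance: Provenance = Provenance.PARSED

    def __post_init__(self) -> None:
        if self.dose_quantity <= 0 or self.frequency_per_day <= 0:
            raise ValueError("dose_quantity and frequency_per_day must be positive")

    @property
    def daily_units(self) -> float:
        return self.dose_quantity * self.frequency_per_day


@dataclass(frozen=True)
class ParseFailure:
    """Why no regimen could be extracted from a dose text."""

    reason: str  # "no-quantity" | "no-frequency" | "empty"
    text: str = ""


def _load_rules() -> dict:
    with resources.files("adheremeter.data").joinpath("dose_rules.yaml").open() as fh:
        return yaml.safe_load(fh)


_RULES = _load_rules()
_NUMBER_WORDS: Mapping[str, int] = _RULES["number_words"]
_UNIT_WORDS: list[str] = _RULES["unit_words"]
_FREQ_PHRASES: Mapping[str, int] = _RULES["frequency_phrases"]
_LATIN: Mapping[str, int] = _RULES["latin_abbreviations"]
_PRN_TOKENS: list[str] = _RULES["as_needed_tokens"]

_NUM = r"(?:\d+(?:\.\d+)?|" + "|".join(map(re.escape, _NUMBER_WORDS)) + r")"
_UNIT = "|".join(map(re.escape, sorted(_UNIT_WORDS, key=len, reverse=True)))

# quantity: a number optionally followed by a unit word; ranges "1-2" / "one
# to two".  The unit-adjacent form is preferred so frequency digits ("2 times
# a day") are not mistaken for quantities.
_RANGE_RE = re.compile(
    rf"\b({_NUM})\s*(?:-|–|\bto\b)\s*({_NUM})\s*(?:{_UNIT})?\b"
)
_QTY_UNIT_RE = re.compile(rf"\b({_NUM})\s*(?:{_UNIT})\b")
_QTY_BARE_RE = re.compile(rf"\b({_NUM})\b")
_FREQ_TIMES_RE = re.compile(rf"\b({_NUM})\s*(?:times|x)\s*(?:a|per|each)?\s*day\b")
_LATIN_RE = re.compile(r"\b(" + "|".join(_LATIN) + r")\b")

_FREQ_PHRASES_ORDERED = sorted(_FREQ_PHRASES, key=len, reverse=True)


def _to_number(token: str) -> float:
    token = token.strip()
    if token in _NUMBER_WORDS:
        return float(_NUMBER_WORDS[token])
    return float(token)


def _normalise(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


@lru_cache(maxsize=100_000)
def parse_dose_text(
    dose_text: str, range_policy: RangePolicy = RangePolicy.MAX
) -> DoseRegimen | ParseFailure:
    """Extract a structured daily regimen from free-text dose directions.

    Matching is case-insensitive over the shipped token tables.  Returns a
    :class:`DoseRegimen` on success or a :class:`ParseFailure` naming the
    reason category; never raises on arbitrary input.

    >>> parse_dose_text("TWO PUFFS TWICE A DAY")
    DoseRegimen(dose_quantity=2.0, frequency_per_day=2.0, ...)
    """
    text = _normalise(dose_text)
    if not text:
        return ParseFailure("empty", dose_text)

    as_needed = any(re.search(rf"\b{re.escape(tok)}\b", text) for tok in _PRN_TOKENS)

    # --- frequency -------------------------------------------------------
    frequency: float | None = None
    freq_span: tuple[int, int] | None = None
    m = _FREQ_TIMES_RE.search(text)
    if m:
        frequency = _to_number(m.group(1))
        freq_span = m.span()
    if frequency is None:
        for phrase in _FREQ_PHRASES_ORDERED:
            m = re.search(rf"\b{re.escape(phrase)}\b", text)
            if m:
                frequency = float(_FREQ_PHRASES[phrase])
                freq_span = m.span()
                break
    if frequency is None:
        m = _LATIN_RE.search(text)
        if m:
            frequency = float(_LATIN[m.group(1)])
            freq_span = m.span()

    # --- quantity --------------------------------------------------------
    def outside_freq(span: tuple[int, int]) -> bool:
        return freq_span is None or span[1] <= freq_span[0] or span[0] >= freq_span[1]

    quantity: float | None = None
    m = next((m for m in _RANGE_RE.finditer(text) if outside_freq(m.span())), None)
    if m:
        lo, hi = sorted((_to_number(m.group(1)), _to_number(m.group(2))))
        quantity = {
            RangePolicy.MIN: lo,
            RangePolicy.MAX: hi,
            RangePolicy.MEAN: (lo + hi) / 2,
        }[range_policy]
    if quantity is None:
        m = next((m for m in _QTY_UNIT_RE.finditer(text) if outside_freq(m.span())), None)
        if m:
            quantity = _to_number(m.group(1))
    if quantity is None:
        m = next((m for m in _QTY_BARE_RE.finditer(text) if outside_freq(m.span())), None)
        if m:
            quantity = _to_number(m.group(1))

    if quantity is None and frequency is None:
        return ParseFailure("no-quantity", dose_text)
    if quantity is None:
        # "take twice daily": an explicit frequency with no numeral reads as
        # one unit per administration (standard dispensing convention)
        quantity = 1.0
    if frequency is None:
        return ParseFailure("no-frequency", dose_text)
    if quantity <= 0 or frequency <= 0:
        return ParseFailure("no-quantity", dose_text)

    return DoseRegimen(
        dose_quantity=quantity,
        frequency_per_day=frequency,
        as_needed=as_needed,
        provenance=Provenance.PARSED,
    )


def expected_supply_duration(dispensed_quantity: float, regimen: DoseRegimen) -> float:
    """Days a dispensing lasts if taken exactly as directed.

    ``dispensed_quantity / (dose_quantity x frequency_per_day)``; fractional
    results are preserved (rounding, if any, happens on the supply engine's
    day grid).  A 60-dose inhaler at two puffs twice a day lasts 15 days.
    """
    if dispensed_quantity <= 0:
        raise ValueError("dispensed_quantity must be positive")
    daily = regimen.daily_units
    if daily <= 0:
        raise ValueError("regimen daily_units must be positive")
    return dispensed_quantity / daily


def resolve_regimen(
    record,
    parse_result: DoseRegimen | ParseFailure,
    defaults: Mapping[str, DoseRegimen] | None = None,
) -> DoseRegimen | None:
    """Pick the regimen for a record: parsed if available, else a
    formulation-keyed default (provenance=default), else ``None`` marking the
    record non-analysable."""
    if isinstance(parse_result, DoseRegimen):
        return parse_result
    defaults = defaults or {}
    fallback = defaults.get(getattr(record, "formulation", "") or "", defaults.get("*"))
    if fallback is None:
        return None
    return DoseRegimen(
        dose_quantity=fallback.dose_quantity,
        frequency_per_day=fallback.frequency_per_day,
        as_needed=fallback.as_needed,
        provenance=Provenance.DEFAULT,
    )
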