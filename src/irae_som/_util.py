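"""Small shared helpers: display rounding and name canonicalization."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "canonical_name"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (0.05 -> 0.1, never 0.0).

    Binary floats like ``(0.8 + 4.3) / 2 == 2.5499999999999998`` first get
    snapped to 8 decimals so that values that are exact halves in decimal
    arithmetic round the way a printed table would.
    """
    snapped = Decimal(repr(float(x))).quantize(Decimal("1e-8"), rounding=ROUND_HALF_EVEN)
    q = Decimal(1).scaleb(-ndigits)
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'",
                              "‐": "-", "‑": "-", "‒": "-",
                              "–": "-", "—": "-", "−": "-"})


def canonical_name(name: str) -> str:
    """Canonical form used for preferred-term matching.

    Trims whitespace, collapses internal runs of spaces, normalizes
    typographic apostrophes and hyphen/dash variants, and lower-cases.
    Matching stays string-exact otherwise (no fuzzy matching): MedDRA terms
    such as "Diarrhea" vs "Diarrhoea haemorrhagic" are distinct terms, not
    spelling variants of one another.
    """
    return " ".join(name.translate(_APOSTROPHES).split()).lower()
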