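"""Address normalization, tokenization and phonetic encoding.

All matching methods operate on canonical forms produced here: uppercase
text with punctuation stripped, whitespace-collapsed concatenation of the
address lines, and a space-free postcode token (or the MISSING sentinel).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .phonetics import metaphone, soundex

__all__ = [
    "MISSING",
    "RawAddress",
    "CanonicalAddress",
    "normalize_text",
    "concatenate",
    "canonicalize_postcode",
    "phonetic_encode",
    "canonicalize",
    "read_address_table",
]


class _Missing:
    """Sentinel for an absent postcode; distinct from the empty string."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

#: phonetic code pair used for tokens with no alphabetic content
SENTINEL_CODES = ("#", "#")

_NON_ALNUM = re.compile(r"[^A-Z0-9]+")


@dataclass(frozen=True)
class RawAddress:
    """Free-text address: ordered lines plus an optional postcode string."""

    lines: tuple[str, ...]
    postcode: str = ""

    def __post_init__(self):
        if not self.lines:
            raise ValueError("RawAddress requires at least one line")
        object.__setattr__(self, "lines", tuple(self.lines))


@dataclass(frozen=True)
class CanonicalAddress:
    """Normalized form of a RawAddress ready for matching."""

    text: str
    tokens: tuple[str, ...]
    postcode: object  # canonical postcode string or MISSING
    phonetic_tokens: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self):
        if len(self.phonetic_tokens) != len(self.tokens):
            raise ValueError("one phonetic code pair required per token")


def normalize_text(raw: str) -> str:
    """Uppercase, map punctuation to spaces, collapse whitespace, strip."""
    return _NON_ALNUM.sub(" ", raw.upper()).strip()


def concatenate(address: RawAddress) -> str:
    """Single normalized string over all non-empty lines then the postcode."""
    parts = [ln for ln in address.lines if ln.strip()]
    if address.postcode.strip():
        parts.append(address.postcode)
    return normalize_text(" ".join(parts))


def canonicalize_postcode(raw: str):
    """Uppercase with all whitespace removed; blank input yields MISSING."""
    token = "".join(raw.upper().split())
    return token if token else MISSING


def phonetic_encode(token: str) -> tuple[str, str]:
    """(metaphone, soundex) pair; sentinel pair for non-alphabetic tokens."""
    if not any(c.isalpha() for c in token):
        return SENTINEL_CODES
    return metaphone(token), soundex(token)


def canonicalize(address: RawAddress) -> CanonicalAddress:
    text = normalize_text(" ".join(ln for ln in address.lines if ln.strip()))
    tokens = tuple(text.split())
    return CanonicalAddress(
        text=text,
        tokens=tokens,
        postcode=canonicalize_postcode(address.postcode),
        phonetic_tokens=tuple(phonetic_encode(t) for t in tokens),
    )


#: columns every population address table must carry
ADDRESS_TABLE_COLUMNS = (
    "record_id", "line1", "line2", "line3", "line4", "line5",
    "postcode", "flag_code", "board", "sample",
)


def read_address_table(path):
    """Read a population address CSV into a DataFrame, validating the schema.

    Raises SchemaError (ValueError subclass) naming any missing column.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ADDRESS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"address table missing required columns: {missing}")
    return df


class SchemaError(ValueError):
    """Input table does not carry the required columns."""
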