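"""Phonetic encodings: American Soundex and classic Metaphone.

Both encoders operate on single uppercase alphabetic words. Tokens with no
alphabetic content (house numbers) are handled upstream with sentinel codes.
"""

from __future__ import annotations

__all__ = ["soundex", "metaphone"]

_SOUNDEX_CODES = {
    "B": "1", "F": "1", "P": "1", "V": "1",
    "C": "2", "G": "2", "J": "2", "K": "2", "Q": "2", "S": "2", "X": "2", "Z": "2",
    "D": "3", "T": "3",
    "L": "4",
    "M": "5", "N": "5",
    "R": "6",
}

_VOWELS = "AEIOU"


def soundex(word: str) -> str:
    """American Soundex: leading letter plus three digits, zero-padded.

    H and W are transparent (consonants separated only by H/W collapse);
    vowels break runs of equal codes but emit nothing.
    """
    word = "".join(c for c in word.upper() if c.isalpha())
    if not word:
        raise ValueError("soundex requires at least one alphabetic character")
    first = word[0]
    digits = []
    prev_code = _SOUNDEX_CODES.get(first, "")
    for ch in word[1:]:
        if ch in ("H", "W"):
            continue
        code = _SOUNDEX_CODES.get(ch, "")
        if code and code != prev_code:
            digits.append(code)
            if len(digits) == 3:
                break
        prev_code = code
    return (first + "".join(digits)).ljust(4, "0")


def metaphone(word: str) -> str:
    """Classic Metaphone (Philips 1990) for a single word."""
    word = "".join(c for c in word.upper() if c.isalpha())
    if not word:
        raise ValueError("metaphone requires at least one alphabetic character")

    # initial-cluster adjustments
    if word[:2] in ("AE", "GN", "KN", "PN", "WR"):
        word = word[1:]
    elif word.startswith("X"):
        word = "S" + word[1:]
    elif word.startswith("WH"):
        word = "W" + word[2:]

    out: list[str] = []
    n = len(word)
    i = 0
    while i < n:
        c = word[i]
        # "*" is a sentinel outside every letter class; it keeps membership
        # tests false at word boundaries ("" would be a substring of any set)
        nxt = word[i + 1] if i + 1 < n else "*"
        nxt2 = word[i + 2] if i + 2 < n else "*"
        prev = word[i - 1] if i > 0 else "*"

        # collapse doubled letters except C
        if c == prev and c != "C":
            i += 1
            continue

        if c in _VOWELS:
            if i == 0:
                out.append(c)
        elif c == "B":
            if not (i == n - 1 and prev == "M"):
                out.append("B")
        elif c == "C":
            if nxt == "I" and nxt2 == "A":
                out.append("X")
            elif nxt == "H":
                out.append("K" if prev == "S" else "X")
            elif nxt in "IEY":
                if prev != "S":
                    out.append("S")
            else:
                out.append("K")
        elif c == "D":
            if nxt == "G" and nxt2 in "EIY":
                out.append("J")
                i += 2
            else:
                out.append("T")
        elif c == "G":
            if nxt == "H":
                if not (i + 2 < n and word[i + 2] in _VOWELS):
                    pass  # silent GH
                else:
                    out.append("K")
            elif nxt == "N":
                pass  # silent in GN / GNED
            elif nxt in "IEY":
                out.append("J")
            else:
                out.append("K")
        elif c == "H":
            if prev in _VOWELS and nxt not in _VOWELS:
                pass
            elif prev in "CSPTG":
                pass  # covered by digraph rules
            else:
                out.append("H")
        elif c == "K":
            if prev != "C":
                out.append("K")
        elif c == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif c == "Q":
            out.append("K")
        elif c == "S":
            if nxt == "H":
                out.append("X")
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            else:
                out.append("S")
        elif c == "T":
            if nxt == "I" and nxt2 in ("O", "A"):
                out.append("X")
            elif nxt == "H":
                out.append("0")
                i += 1
            elif nxt == "C" and nxt2 == "H":
                pass  # silent in TCH
            else:
                out.append("T")
        elif c == "V":
            out.append("F")
        elif c == "W":
            if nxt in _VOWELS:
                out.append("W")
        elif c == "X":
            out.append("KS")
        elif c == "Y":
            if nxt in _VOWELS:
                out.append("Y")
        elif c == "Z":
            out.append("S")
        elif c in "FJLMNR":
            out.append(c)
        i += 1

    return "".join(out)
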