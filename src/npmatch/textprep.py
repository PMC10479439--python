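"""Deterministic normalization and fixed-length integer encoding of name strings.

Free-text natural-product names arrive with punctuation, digits, mixed case
and accented characters.  Every name that enters the pipeline is first
``normalize``d to a canonical form over the 27-symbol working alphabet
(A–Z plus the single space), then ``encode``d to a fixed-length integer
sequence suitable for the neural distance model: letters map to their
alphabet positions 1–26, the space maps to 27, and 0 pads the tail.  Names
longer than :data:`MAX_LEN` characters cannot be encoded and are discarded
by callers.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MAX_LEN",
    "ALPHABET_SIZE",
    "SPACE_CODE",
    "EncodedName",
    "OverLengthError",
    "EncodingDomainError",
    "normalize",
    "encode",
    "decode",
]

#: Maximum encodable name length, in characters.  Chosen near the mean name
#: length observed in adverse-event drug-name fields (~30) plus one standard
#: deviation; longer strings are discarded upstream.
MAX_LEN = 65

#: Number of distinct integer codes: 26 letters + space + the pad symbol 0.
ALPHABET_SIZE = 28

#: Integer code of the space character.
SPACE_CODE = 27


class OverLengthError(ValueError):
    """Raised when a name exceeds the fixed encoding length."""


class EncodingDomainError(ValueError):
    """Raised when an integer sequence contains codes outside [0, 27]."""


@dataclass(frozen=True)
class EncodedName:
    """A name as a zero-padded, fixed-length integer sequence.

    ``codes`` has exactly ``max_len`` entries; ``codes[i]`` is 0 only in the
    trailing pad region (positions >= ``length``).
    """

    codes: tuple[int, ...]
    length: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.codes, dtype=np.int64)


def _ascii_fold(raw: str) -> str:
    # NFKD then drop combining marks: é→E, ü→U; unmappable codepoints vanish
    # later in the alphabet filter.
    decomposed = unicodedata.normalize("NFKD", raw)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def normalize(raw: str) -> str:
    """Canonicalize a raw name string.

    Uppercases, ASCII-folds accented letters, deletes every character
    outside A–Z except whitespace, collapses whitespace runs to a single
    space and strips the ends.  Idempotent; the empty string is a legal
    output.
    """
    folded = _ascii_fold(raw).upper()
    kept = [ch if "A" <= ch <= "Z" else " " if ch.isspace() else "" for ch in folded]
    return " ".join("".join(kept).split())


def encode(name: str, max_len: int = MAX_LEN) -> EncodedName:
    """Encode a normalized name as alphabet positions, zero-padded.

    Raises :class:`OverLengthError` for names longer than ``max_len`` —
    the caller decides whether to discard or report.
    """
    if len(name) > max_len:
        raise OverLengthError(
            f"name of length {len(name)} exceeds the {max_len}-character limit: "
            f"{name[:40]!r}..."
        )
    codes = [SPACE_CODE if ch == " " else ord(ch) - ord("A") + 1 for ch in name]
    codes.extend([0] * (max_len - len(codes)))
    return EncodedName(codes=tuple(codes), length=len(name))


def decode(enc: EncodedName) -> str:
    """Invert :func:`encode`; raises :class:`EncodingDomainError` on bad codes."""
    out: list[str] = []
    for c in enc.codes:
        if not 0 <= c <= SPACE_CODE:
            raise EncodingDomainError(f"code {c} outside [0, {SPACE_CODE}]")
        if c == 0:
            break
        out.append(" " if c == SPACE_CODE else chr(ord("A") + c - 1))
    return "".join(out)
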