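"""IUPAC nucleotide ambiguity-code algebra.

Characters are represented internally as 4-bit masks over {A, C, G, T}
(A=1, C=2, G=4, T=8).  Gap (``-``) and missing (``?``) carry mask 0 and are
*not* ambiguity codes: they denote absence of information, which downstream
code treats differently from a genuine multi-base call.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

#: code -> bitmask over {A,C,G,T}; the 2-/3-/4-base codes are the NC-IUPAC set.
CODE_TO_MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": A | C | G | T,
    "-": 0, "?": 0,
}

MASK_TO_CODE: dict[int, str] = {m: c for c, m in CODE_TO_MASK.items() if c not in "-?N"}
MASK_TO_CODE[0] = "-"
MASK_TO_CODE[A | C | G | T] = "N"

#: Characters accepted in alignments ('U' is normalized to 'T' on read).
ALPHABET = frozenset(CODE_TO_MASK)

_BASES = "ACGT"
_BASE_MASKS = (A, C, G, T)

# Lookup table indexed by byte value for vectorized encoding; 255 = illegal.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _m in CODE_TO_MASK.items():
    _ENCODE_LUT[ord(_c)] = _m
    _ENCODE_LUT[ord(_c.lower())] = _m
_ENCODE_LUT[ord("U")] = T
_ENCODE_LUT[ord("u")] = T


def mask_of(ch: str) -> int:
    """Bitmask of a single IUPAC character (``U`` treated as ``T``)."""
    ch = ch.upper()
    if ch == "U":
        return T
    try:
        return CODE_TO_MASK[ch]
    except KeyError:
        raise ValueError(f"illegal character {ch!r}") from None


def code_of(mask: int) -> str:
    """IUPAC character for a base-set bitmask (0 -> ``-``)."""
    return MASK_TO_CODE[mask]


def bases_of(ch: str) -> frozenset[str]:
    """Constituent unambiguous bases of a code, e.g. R -> {A, G}."""
    m = mask_of(ch)
    return frozenset(b for b, bm in zip(_BASES, _BASE_MASKS) if m & bm)


def is_ambiguity_code(ch: str) -> bool:
    """True for 2-, 3- and 4-base codes (incl. N); False for bases/gap/missing."""
    m = mask_of(ch)
    return m != 0 and (m & (m - 1)) != 0


def popcount(masks: np.ndarray) -> np.ndarray:
    """Number of bases in each mask of an array."""
    return np.bitwise_count(masks)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 mask vector.

    Raises ``ValueError`` naming the first illegal position.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    out = _ENCODE_LUT[raw]
    bad = np.nonzero(out == 255)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"illegal character {seq[i]!r} at position {i}")
    return out


def decode(masks: np.ndarray) -> str:
    """Inverse of :func:`encode` (missing renders as ``-``)."""
    return "".join(MASK_TO_CODE[int(m)] for m in masks)
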