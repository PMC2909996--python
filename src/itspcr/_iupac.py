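"""IUPAC nucleotide alphabet helpers shared across the package.

Every symbol denotes a set of concrete bases; two symbols are *compatible*
when their sets intersect. Compatibility — not identity — is the matching
relation used throughout the amplification engine, so a degenerate primer
base (e.g. R) matches either of its concrete bases, and an N in the target
never counts as a mismatch under the default (permissive) semantics.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: deterministic symbol order used for integer encoding
SYMBOLS = "ACGTRYSWKMBDHVN"
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}

#: 15x15 boolean matrix: COMPAT[i, j] iff the base sets of SYMBOLS[i] and
#: SYMBOLS[j] intersect. Used by the vectorized site scanner.
COMPAT = np.array(
    [[bool(IUPAC_SETS[a] & IUPAC_SETS[b]) for b in SYMBOLS] for a in SYMBOLS],
    dtype=bool,
)

#: byte-value -> symbol index lookup (255 = invalid)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _s, _i in _SYM_INDEX.items():
    _ENCODE[ord(_s)] = _i
    _ENCODE[ord(_s.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(seq: str) -> bool:
    return set(seq) <= IUPAC_ALPHABET


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as symbol indices; raises on non-IUPAC characters."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({c for c in seq if c.upper() not in IUPAC_ALPHABET})
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return arr


def iupac_compatible(primer_base: str, target_base: str) -> bool:
    """True iff the concrete-base sets of the two symbols intersect."""
    try:
        return bool(IUPAC_SETS[primer_base.upper()] & IUPAC_SETS[target_base.upper()])
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol: {exc.args[0]!r}") from None
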