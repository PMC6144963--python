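"""IUPAC-aware primer definitions and degenerate-sequence matching.

Degenerate metazoan COI primers are expressed in IUPAC nucleotide codes
(W = A/T, Y = C/T, ...).  Matching is implemented with per-base bitmasks:
a primer position matches a read base iff the base's bit is contained in
the primer code's expansion.  By default an ``N`` in a *read* matches
nothing (strict mode), while ``N`` in a *primer* matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# one bit per canonical base
_A, _C, _G, _T = 1, 2, 4, 8

IUPAC_BITS: dict[str, int] = {
    "A": _A, "C": _C, "G": _G, "T": _T, "U": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T, "V": _A | _C | _G,
    "N": _A | _C | _G | _T,
}

IUPAC_SETS: dict[str, str] = {
    code: "".join(b for b in "ACGT" if IUPAC_BITS[code] & IUPAC_BITS[b])
    for code in IUPAC_BITS
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

# lookup tables from ASCII byte -> bitmask
_PRIMER_LUT = np.zeros(256, dtype=np.uint8)
for code, bits in IUPAC_BITS.items():
    _PRIMER_LUT[ord(code)] = bits
    _PRIMER_LUT[ord(code.lower())] = bits

# strict read LUT: only concrete bases carry bits; ambiguous read bases
# (incl. N) match nothing
_READ_LUT_STRICT = np.zeros(256, dtype=np.uint8)
for base in "ACGTU":
    _READ_LUT_STRICT[ord(base)] = IUPAC_BITS[base]
    _READ_LUT_STRICT[ord(base.lower())] = IUPAC_BITS[base]

_READ_LUT_LENIENT = _PRIMER_LUT


def is_iupac(seq: str) -> bool:
    """True iff every character of ``seq`` is an IUPAC nucleotide code."""
    return all(c.upper() in IUPAC_BITS for c in seq)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def primer_bits(seq: str) -> np.ndarray:
    """Bitmask array for a (possibly degenerate) primer sequence."""
    if not seq or not is_iupac(seq):
        raise ValueError(f"primer sequence is not IUPAC DNA: {seq!r}")
    return _PRIMER_LUT[seq_to_bytes(seq)]


def read_bits(seq_bytes: np.ndarray, strict_n: bool = True) -> np.ndarray:
    """Bitmask array for read bases (ASCII uint8 array or 2-D batch)."""
    lut = _READ_LUT_STRICT if strict_n else _READ_LUT_LENIENT
    return lut[seq_bytes]


def mismatch_count(pbits: np.ndarray, rbits: np.ndarray) -> np.ndarray:
    """Number of non-matching positions between primer and read window(s).

    ``rbits`` may carry leading batch dimensions; the last axis must equal
    the primer length.
    """
    return np.count_nonzero((pbits & rbits) == 0, axis=-1)


@dataclass(frozen=True)
class PrimerDefinition:
    """A marker's primer pair.

    ``expected_insert_len`` is the length of the amplified region between
    (excluding) the two primers.
    """

    marker_id: str
    forward_seq: str
    reverse_seq: str
    expected_insert_len: int
    max_mismatches: int = 0

    def __post_init__(self):
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if not seq or not is_iupac(seq):
                raise ValueError(f"{name} primer of {self.marker_id} is not IUPAC DNA")
        if self.expected_insert_len <= 0:
            raise ValueError("expected_insert_len must be positive")

    @property
    def reverse_rc(self) -> str:
        """Reverse primer as it appears at the 3' end of the merged read."""
        return reverse_complement(self.reverse_seq)

    @property
    def amplicon_len(self) -> int:
        return len(self.forward_seq) + self.expected_insert_len + len(self.reverse_seq)


# Published universal metazoan COI primer pairs used as defaults.  Inosine
# positions are written as N.  COI1 amplifies a 313 nt insert, COI2 a 325 nt
# insert.
COI1 = PrimerDefinition(
    marker_id="COI1",
    forward_seq="GGWACWGGWTGAACWGTWTAYCCYCC",        # mlCOIintF
    reverse_seq="TANACYTCNGGRTGNCCRAARAAYCA",        # jgHCO2198
    expected_insert_len=313,
)
COI2 = PrimerDefinition(
    marker_id="COI2",
    forward_seq="GGTCAACAAATCATAAAGATATTGG",         # LCO1490
    reverse_seq="GGNGGRTANACNGTTCANCC",              # ill_C_R
    expected_insert_len=325,
)

DEFAULT_PRIMERS: dict[str, PrimerDefinition] = {"COI1": COI1, "COI2": COI2}


def concrete_site(primer_seq: str, rng: np.random.Generator) -> str:
    """Sample one concrete (ACGT-only) realization of a degenerate primer."""
    return "".join(
        IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))] for c in primer_seq.upper()
    )


def scan_primer(
    seq: str,
    primer_seq: str,
    max_mismatch: int = 0,
    strict_n: bool = True,
) -> list[tuple[int, int]]:
    """All (offset, mismatches) where the primer matches within ``seq``.

    Slides the primer over every offset of the target sequence; used by the
    in-silico coverage audit.
    """
    pb = primer_bits(primer_seq)
    sb = read_bits(seq_to_bytes(seq), strict_n=strict_n)
    L, k = len(sb), len(pb)
    if L < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(sb, k)
    mm = mismatch_count(pb, windows)
    return [(int(i), int(m)) for i, m in enumerate(mm) if m <= max_mismatch]
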