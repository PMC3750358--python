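"""Low-level DNA utilities: IUPAC degeneracy, reverse complement, primer search.

These are the primitives behind primer trimming and amplicon extraction.
Primer sequences in two-step fusion-primer designs are degenerate (IUPAC
codes at variable positions), so all matching here is IUPAC-aware.
"""
from __future__ import annotations

from dataclasses import dataclass

# IUPAC nucleotide degeneracy sets. N in a *read* matches every code; a
# code's set says which concrete bases it stands for.
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

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN" + "acgtryswkmbdhvn",
    "TGCAYRSWMKVHDBN" + "tgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC codes map to their complementary codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` is compatible with the IUPAC symbol ``code``.

    ``base`` must be one of A/C/G/T/N; N matches every code (an uncalled
    read base cannot be held against a primer site).
    """
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code: {code!r}")
    if base == "N":
        return True
    if base not in "ACGT":
        raise ValueError(f"invalid base: {base!r}")
    return base in IUPAC_SETS[code]


@dataclass(frozen=True)
class PrimerMatch:
    position: int
    mismatches: int


def find_primer(seq: str, primer: str, max_mismatches: int = 2) -> PrimerMatch | None:
    """Leftmost window of ``seq`` matching ``primer`` with ≤ ``max_mismatches``.

    IUPAC-aware on the primer side; N in ``seq`` matches anything. Indels in
    the primer site are not modelled. Returns None when the primer is longer
    than ``seq`` or no window qualifies.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    m = len(primer)
    sets = [IUPAC_SETS[c] for c in primer]  # validates the primer up front
    if m == 0 or m > len(seq):
        return None
    for start in range(len(seq) - m + 1):
        mm = 0
        for j in range(m):
            b = seq[start + j]
            if b != "N" and b not in sets[j]:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return PrimerMatch(start, mm)
    return None
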