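"""IUPAC nucleotide codes, complements and degenerate-motif regexes."""

from __future__ import annotations

import re

from .errors import InvalidMotifError

BASES = "ACGT"

#: degenerate code -> set of unambiguous bases it stands for
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
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

#: set of unambiguous bases -> IUPAC code
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtn", "TGCANYRSWMKVHDBtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_motif(motif: str) -> str:
    """Uppercase *motif* and check every character is a IUPAC code."""
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC_TO_BASES:
            raise InvalidMotifError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
    if not motif:
        raise InvalidMotifError("empty motif")
    return motif


def motif_regex(motif: str) -> re.Pattern[str]:
    """Compile a degenerate motif to a regex over {A,C,G,T}.

    N sites in the genome never match because character classes list
    unambiguous bases only.
    """
    motif = validate_motif(motif)
    parts = []
    for ch in motif:
        bases = "".join(sorted(IUPAC_TO_BASES[ch]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def default_target_offset(motif: str) -> int:
    """Index of the methylated C within a recognition motif.

    Convention: the first position whose code is exactly ``C``. This matches
    the target-base annotations of all built-in recognition sequences
    (CG->0, CC->0, GC->1, GCH->1, HCG->1, CNG->0, TCG->1, GCY->1, TCTG->1,
    RGCA->2).
    """
    motif = validate_motif(motif)
    for i, ch in enumerate(motif):
        if ch == "C":
            return i
    raise InvalidMotifError(f"motif {motif!r} has no unambiguous C position")
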