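"""Independent brute-force oracles used to cross-check the implementation.

These are written as plain dict/loop code, deliberately sharing nothing
with the package's vectorised implementations.
"""

from __future__ import annotations

BASES = "ACGT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_pwm(windows):
    """Tabulate M and f by direct looping over (seq, m) pairs.

    Returns ``(M, f)`` as dicts keyed by (base, column index).
    """
    n = len(windows)
    width = len(windows[0][0])
    M = {(b, j): 0.0 for b in BASES for j in range(width)}
    for seq, m in windows:
        for j, ch in enumerate(seq):
            M[(ch, j)] += m
    for key in M:
        M[key] /= n
    f = {}
    for j in range(width):
        col = sum(M[(b, j)] for b in BASES)
        for b in BASES:
            f[(b, j)] = M[(b, j)] / col if col > 0 else 0.0
    return M, f


def revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def scan_motif_targets(seq, motif, target_offset):
    """All target cytosines of a motif on both strands, by direct scan.

    Returns a set of (pos 1-based, strand) tuples on the forward contig
    coordinate system.
    """
    L = len(motif)
    hits = set()
    for i in range(len(seq) - L + 1):
        if all(seq[i + k] in _IUPAC[motif[k]] for k in range(L)):
            hits.add((i + target_offset + 1, "+"))
    rc = revcomp(seq)
    n = len(seq)
    for i in range(len(rc) - L + 1):
        if all(rc[i + k] in _IUPAC[motif[k]] for k in range(L)):
            # rc index i+target_offset maps to forward index n-1-(i+target_offset)
            hits.add((n - (i + target_offset), "-"))
    return hits


def count_site_occurrences(seq, site):
    """Number of (possibly overlapping) plus-strand occurrences of a site."""
    L = len(site)
    return sum(
        all(seq[i + k] in _IUPAC[site[k]] for k in range(L))
        for i in range(len(seq) - L + 1)
    )
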