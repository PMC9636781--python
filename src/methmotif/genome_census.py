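"""Cytosine-context classification, genome-wide motif-target census,
analytical resolution, and in-silico methylation-sensitive digestion.

The census answers "how many informative cytosines does a probe motif give
on this genome, and how densely are they spaced?" — the analytical
resolution of an MTase-based accessibility assay is the genome size divided
by the number of the motif's target cytosines. Context classification
supports the NOMe channel conventions: HCG and GCH are disjoint carriers of
intrinsic and induced methylation respectively, while GCG is ambiguous
(either enzyme could have produced it) and is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidMotifError
from .iupac import IUPAC_TO_BASES, default_target_offset, motif_regex, revcomp, validate_motif
from .meth_io import COMPLEMENT_CODES, Genome

_H = frozenset("ACT")  # IUPAC H: not G
_D = frozenset("AGT")  # IUPAC D: not C


def _neighbor_codes(enc: np.ndarray, pos0: np.ndarray, step: int) -> np.ndarray:
    """Base codes at pos0+step with out-of-range positions coded 5 (absent)."""
    nb = pos0 + step
    out = np.full(len(pos0), 5, dtype=np.uint8)
    ok = (nb >= 0) & (nb < len(enc))
    out[ok] = enc[nb[ok]]
    return out


def classify_contexts(genome: Genome) -> pd.DataFrame:
    """Label every cytosine on both strands with its local context.

    Returns a DataFrame with columns ``contig, pos (1-based), strand,
    dinuc`` (CG/CC/CA/CT, empty when the next base is N or missing) and
    nullable-boolean flags ``hcg, gch, gcg, ccd`` (pd.NA when the needed
    neighbour is undefined). Neighbours are read 5'->3' on the cytosine's
    own strand.
    """
    frames = []
    base_char = np.array(list("ACGTN?"))
    for contig in genome:
        enc = genome.encoded(contig)
        for strand in "+-":
            if strand == "+":
                pos0 = np.flatnonzero(enc == 1)
                nxt = _neighbor_codes(enc, pos0, 1)
                prv = _neighbor_codes(enc, pos0, -1)
                nxt2 = _neighbor_codes(enc, pos0, 2)
            else:
                pos0 = np.flatnonzero(enc == 2)
                nxt = _neighbor_codes(enc, pos0, -1)
                prv = _neighbor_codes(enc, pos0, 1)
                nxt2 = _neighbor_codes(enc, pos0, -2)
                comp6 = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)
                nxt, prv, nxt2 = comp6[nxt], comp6[prv], comp6[nxt2]
            if pos0.size == 0:
                continue
            nxt_def = nxt < 4
            prv_def = prv < 4
            nxt2_def = nxt2 < 4
            dinuc = np.where(nxt_def, np.char.add("C", base_char[nxt]), "")
            is_cg = nxt == 2
            hcg = pd.array(np.where(prv_def, is_cg & np.isin(prv, [0, 1, 3]), None), dtype="boolean")
            gcg = pd.array(np.where(prv_def, is_cg & (prv == 2), None), dtype="boolean")
            gch = pd.array(
                np.where(prv_def & nxt_def, (prv == 2) & np.isin(nxt, [0, 1, 3]), None),
                dtype="boolean",
            )
            ccd = pd.array(
                np.where(nxt_def & nxt2_def, (nxt == 1) & np.isin(nxt2, [0, 2, 3]), None),
                dtype="boolean",
            )
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos0 + 1,
                        "strand": strand,
                        "dinuc": dinuc,
                        "hcg": hcg,
                        "gch": gch,
                        "gcg": gcg,
                        "ccd": ccd,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["contig", "pos", "strand", "dinuc", "hcg", "gch", "gcg", "ccd"]
        )
    return pd.concat(frames, ignore_index=True)


def _overlapping_starts(pattern, seq: str) -> list[int]:
    """Start positions of all (possibly overlapping) matches."""
    starts = []
    pos = 0
    while True:
        mt = pattern.search(seq, pos)
        if mt is None:
            return starts
        starts.append(mt.start())
        pos = mt.start() + 1


def count_motif_targets(
    genome: Genome, motif: str, target_offset: int | None = None
) -> tuple[int, pd.DataFrame]:
    """Count target cytosines of a degenerate motif on both strands.

    Occurrences may overlap; each occurrence contributes its target C.
    Palindromic motifs are counted once per strand (a plus- and a
    minus-strand target at the same locus are distinct data points, which
    makes the CG count even). Occurrences containing N never match.

    Returns ``(n_sites, positions)`` with positions columns
    ``contig, pos (1-based), strand`` of the target cytosine.
    """
    motif = validate_motif(motif)
    if target_offset is None:
        target_offset = default_target_offset(motif)
    if not 0 <= target_offset < len(motif):
        raise InvalidMotifError(f"target offset {target_offset} outside motif {motif!r}")
    if "C" not in IUPAC_TO_BASES[motif[target_offset]]:
        raise InvalidMotifError(
            f"motif position {target_offset} ({motif[target_offset]!r}) cannot be a C"
        )
    fwd = motif_regex(motif)
    rev = motif_regex(revcomp(motif))
    L = len(motif)
    rows = []
    for contig, seq in genome.items():
        for start in _overlapping_starts(fwd, seq):
            rows.append((contig, start + target_offset + 1, "+"))
        for start in _overlapping_starts(rev, seq):
            # minus-strand motif index t maps to plus position start + L-1-t
            rows.append((contig, start + (L - 1 - target_offset) + 1, "-"))
    positions = pd.DataFrame(rows, columns=["contig", "pos", "strand"])
    positions = positions.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(
        drop=True
    )
    return len(positions), positions


def analytical_resolution(genome_size: int, n_sites: int) -> int:
    """Mean spacing of a motif's target cytosines, in bp.

    genome_size / n_sites rounded to the nearest integer
    (half away from zero).
    """
    if n_sites <= 0:
        raise EmptyInputError("n_sites must be positive")
    return int(math.floor(genome_size / n_sites + 0.5))


@dataclass(frozen=True)
class CoverageSummary:
    n_sites: int
    n_covered: int
    covered_fraction: float  # percent
    degenerate: bool = False

    @property
    def formatted_fraction(self) -> str:
        return f"{self.covered_fraction:.1f}%"


def coverage_summary(
    records: pd.DataFrame, threshold: int = 10, n_sites: int | None = None
) -> CoverageSummary:
    """Count sites with read depth >= threshold among a motif's targets.

    *records* must already be restricted to the motif's target cytosines;
    *n_sites* defaults to the number of records (pass the census count when
    the table omits uncovered sites).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if n_sites is None:
        n_sites = len(records)
    n_covered = int(((records["meth"] + records["unmeth"]) >= threshold).sum()) if len(records) else 0
    if n_sites == 0:
        return CoverageSummary(0, 0, 0.0, degenerate=True)
    return CoverageSummary(n_sites, n_covered, 100.0 * n_covered / n_sites)


@dataclass(frozen=True)
class MotifCensusRow:
    motif: str
    target_offset: int
    genome_size: int
    n_sites: int
    resolution: int
    n_covered: int
    covered_fraction: float


def census_table(
    genome: Genome,
    records: pd.DataFrame,
    motifs: list,
    threshold: int = 10,
) -> pd.DataFrame:
    """One census row per motif: site count, resolution, coverage.

    *motifs* entries are IUPAC strings or ``(motif, target_offset)`` pairs.
    """
    genome_size = genome.total_length
    rows = []
    keyed = records.set_index(["contig", "pos", "strand"]) if len(records) else None
    for entry in motifs:
        if isinstance(entry, tuple):
            motif, off = entry
        else:
            motif, off = entry, None
        motif = validate_motif(motif)
        if off is None:
            off = default_target_offset(motif)
        n_sites, positions = count_motif_targets(genome, motif, off)
        if keyed is not None and n_sites:
            idx = pd.MultiIndex.from_frame(positions)
            hits = keyed.reindex(idx).dropna(subset=["meth"])
        else:
            hits = records.iloc[0:0]
        cov = coverage_summary(hits.reset_index(), threshold=threshold, n_sites=n_sites)
        resolution = analytical_resolution(genome_size, n_sites) if n_sites else 0
        rows.append(
            MotifCensusRow(
                motif=motif,
                target_offset=off,
                genome_size=genome_size,
                n_sites=n_sites,
                resolution=resolution,
                n_covered=cov.n_covered,
                covered_fraction=round(cov.covered_fraction, 1),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class Enzyme:
    """A methylation-sensitive restriction enzyme.

    ``cut_offset`` is the bp offset of the cut within the site on the plus
    strand; ``blocking`` lists (site-offset, strand) positions whose 5mC
    blocks cleavage. The built-in definitions cover the two assay enzymes:
    HaeIII (GG^CC; blocked by 5mC of the first CC cytosine on either
    strand) and HpaII (C^CGG; blocked by 5mC of either plus-strand C or
    their minus-strand mirrors).
    """

    name: str
    site: str
    cut_offset: int
    blocking: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        site = validate_motif(self.site)
        if not 0 <= self.cut_offset <= len(site):
            raise InvalidMotifError("cut offset outside site")
        for off, strand in self.blocking:
            code = site[off] if strand == "+" else revcomp(site[off])
            if "C" not in IUPAC_TO_BASES[code]:
                raise InvalidMotifError(
                    f"blocking position {off}{strand} of {site!r} cannot be a cytosine"
                )


ENZYMES: dict[str, Enzyme] = {
    "HaeIII": Enzyme("HaeIII", "GGCC", 2, frozenset({(2, "+"), (1, "-")})),
    "HpaII": Enzyme("HpaII", "CCGG", 1, frozenset({(0, "+"), (1, "+"), (2, "-"), (3, "-")})),
}


@dataclass
class DigestResult:
    """Cut positions (0-based, per contig) and resulting fragment lengths."""

    cuts: dict[str, np.ndarray]
    fragments: dict[str, np.ndarray]

    @property
    def all_fragments(self) -> np.ndarray:
        if not self.fragments:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(list(self.fragments.values()))


def digest_in_silico(
    genome: Genome,
    records: pd.DataFrame | None,
    enzyme: Enzyme,
    level_threshold: float = 0.5,
) -> DigestResult:
    """Digest each (linear) contig, honouring 5mC blocking.

    A cytosine counts as methylated when its level (meth/total) is at least
    *level_threshold*; sites with any methylated blocking position are not
    cut. With ``records=None`` the genome is treated as unmethylated.
    Fragments tile each contig exactly.
    """
    meth_state: dict[str, dict[str, np.ndarray]] = {}
    for contig in genome:
        L = genome.length(contig)
        meth_state[contig] = {
            "+": np.zeros(L, dtype=bool),
            "-": np.zeros(L, dtype=bool),
        }
    if records is not None and len(records):
        total = records["meth"] + records["unmeth"]
        lev = np.where(total > 0, records["meth"] / total.replace(0, 1), 0.0)
        hot = records.loc[np.asarray(lev) >= level_threshold]
        for (contig, strand), grp in hot.groupby(["contig", "strand"], sort=False):
            if contig in meth_state:
                meth_state[contig][strand][grp["pos"].to_numpy() - 1] = True
    pattern = motif_regex(enzyme.site)
    cuts: dict[str, np.ndarray] = {}
    fragments: dict[str, np.ndarray] = {}
    for contig, seq in genome.items():
        L = len(seq)
        contig_cuts = []
        pos = 0
        while True:
            mt = pattern.search(seq, pos)
            if mt is None:
                break
            s = mt.start()
            blocked = any(
                meth_state[contig][strand][s + off] for off, strand in enzyme.blocking
            )
            if not blocked:
                contig_cuts.append(s + enzyme.cut_offset)
            pos = s + 1
        arr = np.unique(np.array(contig_cuts, dtype=np.int64))
        arr = arr[(arr > 0) & (arr < L)]
        cuts[contig] = arr
        fragments[contig] = np.diff(np.concatenate(([0], arr, [L])))
    return DigestResult(cuts=cuts, fragments=fragments)
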