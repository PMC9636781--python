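"""Synthetic genomes and methylomes with known ground truth.

The generators emulate the statistical structure the analyses assume, so
every pipeline stage can be verified offline against a planted truth:

* random genomes (iid base composition, optionally first-order Markov);
* MTase-induced methylomes — a recognition motif methylated at a mean
  efficiency, per-site levels drawn from a Beta around that mean, read
  counts sampled binomially at Poisson coverage over a bisulfite
  non-conversion background;
* an intrinsic CG landscape of alternating highly-methylated regions and
  partially-methylated domains with geometric lengths;
* nucleosome-structured chromatin for NOMe simulations — promoter
  nucleosome-depleted regions with nucleosome footprints phased from the
  NDR edges at a configurable period.

Methylation sources combine by ``max`` (levels are probabilities of
redundant causes, not additive quantities). All generators are pure
functions of their specs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, MethMotifError
from .genome_census import count_motif_targets
from .iupac import default_target_offset, validate_motif
from .meth_io import Genome, REPORT_COLUMNS, decode_seq

#: roughly human-like base composition (GC ~ 41%)
DEFAULT_BASE_FREQS = (0.295, 0.205, 0.205, 0.295)


@dataclass(frozen=True)
class GenomeSpec:
    length: int = 1_000_000
    n_contigs: int = 1
    base_freqs: tuple = DEFAULT_BASE_FREQS
    transition: tuple | None = None  # optional 4x4 first-order transition matrix
    seed: int = 0


@dataclass(frozen=True)
class MTaseSpec:
    """A planted MTase: motif, target C, and methylation efficiency.

    Per-site levels are Beta-distributed around *efficiency* with the given
    concentration; *context_overrides* maps a trinucleotide context (the
    target C plus its next two bases, strand-local) to a different mean —
    e.g. reduced efficiency at CCC.
    """

    motif: str
    efficiency: float = 0.85
    concentration: float = 50.0
    target_offset: int | None = None
    context_overrides: dict = field(default_factory=dict)

    def resolved_offset(self) -> int:
        if self.target_offset is not None:
            return self.target_offset
        return default_target_offset(self.motif)


@dataclass(frozen=True)
class IntrinsicSpec:
    """Two-state CG methylation landscape (HMR / PMD domains)."""

    hmr_level: float = 0.85
    pmd_level: float = 0.40
    mean_domain_length: int = 100_000
    hmr_fraction: float = 0.5  # probability the first domain is an HMR
    concentration: float = 20.0
    seed: int = 1


@dataclass(frozen=True)
class ChromatinSpec:
    """Promoter NDRs plus nucleosomes phased from the NDR edges.

    Offsets are strand-oriented relative to each anchor; the default NDR
    interval and nucleosome geometry follow the canonical promoter
    architecture (147 bp footprints at ~165 bp period). *protection* is the
    fraction of MTase activity blocked under a footprint; bulk chromatin
    outside the phased windows is uniformly protected.
    """

    anchors: pd.DataFrame = None  # columns contig, pos (0-based), strand, name
    ndr: tuple = (-250, -100)
    footprint: int = 147
    period: int = 165
    protection: float = 0.9
    jitter_sd: float = 0.0
    extent: int = 1500  # half-width of the phased window around each anchor

    def __post_init__(self) -> None:
        if self.footprint > self.period:
            raise MethMotifError("nucleosome footprint exceeds period")
        if self.ndr[0] >= self.ndr[1]:
            raise MethMotifError("NDR interval must be ordered")


@dataclass(frozen=True)
class CoverageSpec:
    mean_depth: float = 20.0
    background: float = 0.001  # bisulfite non-conversion floor (~99.9% conversion)
    seed: int = 2

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise MethMotifError("mean depth must be positive")
        if not 0 <= self.background < 1:
            raise MethMotifError("background must be in [0, 1)")


def simulate_genome(spec: GenomeSpec) -> Genome:
    """Draw a random genome; deterministic given the spec's seed."""
    freqs = np.asarray(spec.base_freqs, dtype=float)
    if freqs.shape != (4,) or (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-6:
        raise MethMotifError("base frequencies must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(spec.seed)
    lengths = [spec.length // spec.n_contigs] * spec.n_contigs
    lengths[-1] += spec.length - sum(lengths)
    contigs = {}
    for ci, L in enumerate(lengths):
        name = f"contig{ci + 1}"
        if L == 0:
            contigs[name] = ""
            continue
        if spec.transition is None:
            codes = rng.choice(4, size=L, p=freqs).astype(np.uint8)
        else:
            T = np.asarray(spec.transition, dtype=float)
            if T.shape != (4, 4) or np.abs(T.sum(axis=1) - 1.0).max() > 1e-6:
                raise MethMotifError("transition matrix rows must sum to 1")
            cum = np.cumsum(T, axis=1)
            u = rng.random(L)
            codes = np.empty(L, dtype=np.uint8)
            codes[0] = rng.choice(4, p=freqs)
            for k in range(1, L):
                codes[k] = np.searchsorted(cum[codes[k - 1]], u[k])
        contigs[name] = decode_seq(codes)
    return Genome(contigs)


def cytosine_table(genome: Genome) -> pd.DataFrame:
    """All cytosines of both strands with their strand-local trinucleotide
    context (the C plus its next two bases; N-padded at contig edges)."""
    base = np.array(list("ACGTN"))
    frames = []
    for contig in genome:
        enc = genome.encoded(contig)
        for strand in "+-":
            if strand == "+":
                pos0 = np.flatnonzero(enc == 1)
                n1 = _codes_at(enc, pos0 + 1)
                n2 = _codes_at(enc, pos0 + 2)
            else:
                pos0 = np.flatnonzero(enc == 2)
                comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
                n1 = comp[_codes_at(enc, pos0 - 1)]
                n2 = comp[_codes_at(enc, pos0 - 2)]
            if pos0.size == 0:
                continue
            ctx = np.char.add(np.char.add("C", base[n1]), base[n2])
            frames.append(
                pd.DataFrame(
                    {"contig": contig, "pos": pos0 + 1, "strand": strand, "context": ctx}
                )
            )
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand", "context"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(drop=True)


def _codes_at(enc: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.full(len(idx), 4, dtype=np.uint8)
    ok = (idx >= 0) & (idx < len(enc))
    out[ok] = enc[idx[ok]]
    return out


def _intrinsic_levels(genome: Genome, table: pd.DataFrame, spec: IntrinsicSpec) -> np.ndarray:
    """Per-record intrinsic true level (NaN at non-CG-target cytosines).

    The domain landscape and the per-site Beta draws depend only on the
    genome and the intrinsic seed, so runs that differ in MTase treatment
    share an identical intrinsic truth.
    """
    rng = np.random.default_rng(spec.seed)
    domain_mean: dict[str, np.ndarray] = {}
    for contig in genome:
        L = genome.length(contig)
        mean = np.empty(L)
        state_hmr = rng.random() < spec.hmr_fraction
        pos = 0
        while pos < L:
            seg = int(rng.geometric(1.0 / spec.mean_domain_length))
            mean[pos : pos + seg] = spec.hmr_level if state_hmr else spec.pmd_level
            state_hmr = not state_hmr
            pos += seg
        domain_mean[contig] = mean
    levels = np.full(len(table), np.nan)
    is_cg = table["context"].str.startswith("CG").to_numpy()
    for contig, grp in table[is_cg].groupby("contig", sort=False):
        mu = domain_mean[contig][grp["pos"].to_numpy() - 1]
        a = mu * spec.concentration
        b = (1.0 - mu) * spec.concentration
        levels[grp.index.to_numpy()] = rng.beta(a, b)
    return levels


def _mtase_levels(
    genome: Genome,
    table: pd.DataFrame,
    mtases: list[MTaseSpec],
    master_seed: int,
    accessibility: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-record induced true level, max over MTases (NaN where untargeted)."""
    levels = np.full(len(table), np.nan)
    key = table.reset_index().set_index(["contig", "pos", "strand"])["index"]
    for mi, mt in enumerate(mtases):
        motif = validate_motif(mt.motif)
        _, positions = count_motif_targets(genome, motif, mt.resolved_offset())
        if not len(positions):
            continue
        idx = key.loc[pd.MultiIndex.from_frame(positions)].to_numpy()
        rng = np.random.default_rng([master_seed, 7919 + mi])
        mu = np.full(len(idx), float(mt.efficiency))
        if mt.context_overrides:
            ctx = table["context"].to_numpy()[idx]
            for context, mean in mt.context_overrides.items():
                mu[ctx == context.upper()] = float(mean)
        a = np.clip(mu, 1e-9, 1 - 1e-9) * mt.concentration
        b = (1.0 - np.clip(mu, 1e-9, 1 - 1e-9)) * mt.concentration
        drawn = rng.beta(a, b)
        if accessibility is not None:
            acc = np.concatenate(
                [
                    accessibility[contig][grp["pos"].to_numpy() - 1]
                    for contig, grp in positions.groupby("contig", sort=False)
                ]
            )
            drawn = drawn * acc
        prev = levels[idx]
        levels[idx] = np.where(np.isnan(prev), drawn, np.maximum(prev, drawn))
    return levels


def _sample_reads(
    table: pd.DataFrame, true_level: np.ndarray, coverage: CoverageSpec
) -> pd.DataFrame:
    rng = np.random.default_rng(coverage.seed)
    n = len(table)
    depth = rng.poisson(coverage.mean_depth, n)
    meth = rng.binomial(depth, true_level)
    out = table[["contig", "pos", "strand"]].copy()
    out["meth"] = meth
    out["unmeth"] = depth - meth
    out["context"] = table["context"].to_numpy()
    return out[REPORT_COLUMNS]


def simulate_methylome(
    genome: Genome,
    mtases: list[MTaseSpec],
    intrinsic: IntrinsicSpec | None = None,
    coverage: CoverageSpec = CoverageSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a WGBS cytosine report for a genome with planted MTases.

    Every cytosine of both strands is reported. The true level of a site is
    the max of the non-conversion background, its MTase efficiency draw (if
    a motif target) and its intrinsic CG draw (if a CG target under an
    IntrinsicSpec). Returns ``(records, truth)`` where truth carries the
    per-site ``true_level``.
    """
    table = cytosine_table(genome)
    true = np.full(len(table), coverage.background)
    if intrinsic is not None:
        intr = _intrinsic_levels(genome, table, intrinsic)
        true = np.fmax(true, np.nan_to_num(intr, nan=0.0))
    if mtases:
        ind = _mtase_levels(genome, table, mtases, coverage.seed)
        true = np.fmax(true, np.nan_to_num(ind, nan=0.0))
    records = _sample_reads(table, true, coverage)
    truth = table.copy()
    truth["true_level"] = true
    return records, truth


def accessibility_tracks(genome: Genome, chromatin: ChromatinSpec, seed: int = 0) -> dict:
    """Per-contig accessibility arrays in [0, 1].

    Bulk chromatin sits at 1 - protection; around each anchor, the NDR and
    the linkers are fully accessible and nucleosome footprints phased from
    the NDR edges are protected. Optional Gaussian jitter displaces each
    footprint independently.
    """
    anchors = chromatin.anchors
    rng = np.random.default_rng([seed, 104729])
    bulk = 1.0 - chromatin.protection
    acc = {contig: np.full(genome.length(contig), bulk) for contig in genome}
    if anchors is None or not len(anchors):
        return acc  # bulk chromatin only: no NDRs, no phased arrays
    ext = chromatin.extent
    ndr_lo, ndr_hi = chromatin.ndr
    for anchor in anchors.itertuples(index=False):
        if anchor.contig not in acc:
            raise CoordinateError(f"anchor contig {anchor.contig!r} not in genome")
        L = len(acc[anchor.contig])
        if not 0 <= anchor.pos < L:
            raise CoordinateError(f"anchor {anchor.contig}:{anchor.pos} out of bounds")
        width = 2 * ext + 1
        window = np.ones(width)  # offsets -ext..+ext; NDR and linkers open

        def occupy(start_off: int) -> None:
            lo = max(start_off + ext, 0)
            hi = min(start_off + chromatin.footprint + ext, width)
            if lo < hi:
                window[lo:hi] = bulk

        k = 0
        while ndr_hi + k * chromatin.period <= ext:
            jit = int(round(rng.normal(0, chromatin.jitter_sd))) if chromatin.jitter_sd else 0
            occupy(ndr_hi + k * chromatin.period + jit)
            k += 1
        k = 0
        # tile until the footprint end leaves the window; partial footprints
        # at the edge are clamped, not skipped
        while ndr_lo - k * chromatin.period > -ext:
            jit = int(round(rng.normal(0, chromatin.jitter_sd))) if chromatin.jitter_sd else 0
            occupy(ndr_lo - k * chromatin.period - chromatin.footprint + jit)
            k += 1
        offs = np.arange(-ext, ext + 1)
        positions = anchor.pos + offs if anchor.strand == "+" else anchor.pos - offs
        ok = (positions >= 0) & (positions < L)
        acc[anchor.contig][positions[ok]] = window[ok]
    return acc


def simulate_nome(
    genome: Genome,
    mtase: MTaseSpec,
    chromatin: ChromatinSpec,
    intrinsic: IntrinsicSpec | None = None,
    coverage: CoverageSpec = CoverageSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a NOMe-seq cytosine report with a chromatin truth track.

    The MTase's induced level at a target site is its efficiency draw
    scaled by the locus accessibility; the intrinsic CG channel is
    unaffected by chromatin. Returns ``(records, truth, accessibility)``.
    """
    acc = accessibility_tracks(genome, chromatin, seed=coverage.seed)
    table = cytosine_table(genome)
    true = np.full(len(table), coverage.background)
    if intrinsic is not None:
        intr = _intrinsic_levels(genome, table, intrinsic)
        true = np.fmax(true, np.nan_to_num(intr, nan=0.0))
    ind = _mtase_levels(genome, table, [mtase], coverage.seed, accessibility=acc)
    true = np.fmax(true, np.nan_to_num(ind, nan=0.0))
    records = _sample_reads(table, true, coverage)
    truth = table.copy()
    truth["true_level"] = true
    return records, truth, acc


def accessibility_to_track(acc: dict, bin_size: int = 10) -> pd.DataFrame:
    """Bin-average an accessibility truth array into a bedGraph-style table."""
    rows = []
    for contig, arr in acc.items():
        n_bins = int(np.ceil(len(arr) / bin_size))
        for b in range(n_bins):
            s, e = b * bin_size, min((b + 1) * bin_size, len(arr))
            rows.append((contig, s, e, float(arr[s:e].mean()), e - s))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "level", "depth"])
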