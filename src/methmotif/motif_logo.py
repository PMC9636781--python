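"""Methylation-weighted position weight matrix (PWM-M), M-logo, and
IUPAC consensus calling.

The statistic summarises sequence preference around methylated cytosines.
From a genome and a per-cytosine methylation table, every cytosine with
sufficient read depth contributes a window of length 2l+1 centred on it
(minus-strand cytosines contribute the reverse complement, so offsets read
5'->3' on the methylated strand). Each matrix element is the mean, over
windows, of the methylation level of windows carrying base i at offset j:

    M[i, j] = (1/N) * sum_k m_k * [base of window k at offset j == i]

Columns are then normalised to frequencies f[i, j], from which the
per-position Shannon entropy H_j, the information content
R_j = log2(4) - H_j - 0.541 and letter heights f[i, j] * R_j are derived.
The 0.541 term is a fixed small-sample correction constant, kept as a
literal. An unmethylated genome carries no signal: every column of M is
zero and the logo is degenerate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError, DegenerateLogoError, EmptyInputError
from .iupac import BASES, BASES_TO_IUPAC
from .meth_io import COMPLEMENT_CODES, Genome, decode_seq, encode_seq

#: information-content correction constant (bits)
LOGO_CORRECTION = 0.541

DEFAULT_HALF_WIDTH = 5
DEFAULT_MIN_DEPTH = 5
DEFAULT_THETA = 0.25
DEFAULT_KAPPA = 0.85


@dataclass(frozen=True)
class MethylationWindow:
    """A 2l+1 window centred on a cytosine, with its methylation level."""

    seq: str
    m: float
    depth: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"methylation level {self.m} outside [0,1]")
        centre = self.seq[len(self.seq) // 2]
        if centre != "C":
            raise ValueError(f"window centre is {centre!r}, not C")


class WindowSet:
    """Column-oriented container of methylation windows.

    Stores the encoded sequences as an (n, 2l+1) uint8 matrix plus level and
    depth vectors; indexing yields :class:`MethylationWindow` views.
    """

    def __init__(self, codes: np.ndarray, m: np.ndarray, depth: np.ndarray):
        self.codes = np.asarray(codes, dtype=np.uint8)
        self.m = np.asarray(m, dtype=float)
        self.depth = np.asarray(depth, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] % 2 != 1:
            raise ValueError("window matrix must be (n, 2l+1)")

    @classmethod
    def from_windows(cls, windows: Iterable[MethylationWindow]) -> "WindowSet":
        windows = list(windows)
        if not windows:
            return cls(np.empty((0, 1), dtype=np.uint8), np.empty(0), np.empty(0, dtype=int))
        codes = np.stack([encode_seq(w.seq) for w in windows])
        return cls(codes, [w.m for w in windows], [w.depth for w in windows])

    @property
    def l(self) -> int:
        return self.codes.shape[1] // 2

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __getitem__(self, i: int) -> MethylationWindow:
        return MethylationWindow(decode_seq(self.codes[i]), float(self.m[i]), int(self.depth[i]))

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


@dataclass
class PWMM:
    """Methylation-weighted PWM over a +/-l window.

    ``M`` and ``f`` are 4 x (2l+1) arrays indexed by base (A,C,G,T) and
    offset -l..+l; ``degenerate`` flags offsets whose column of M is all
    zero (no weighted observations).
    """

    l: int
    n_windows: int
    M: np.ndarray
    f: np.ndarray
    degenerate: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.l, self.l + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, off in enumerate(self.offsets):
            row = {"offset": off, "degenerate": bool(self.degenerate[j])}
            for i, b in enumerate(BASES):
                row[f"M_{b}"] = self.M[i, j]
                row[f"f_{b}"] = self.f[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class LogoTable:
    """Per-offset entropy, information content and letter heights."""

    l: int
    H: np.ndarray  # bits; NaN at degenerate offsets
    R: np.ndarray  # bits; NaN at degenerate offsets
    heights: np.ndarray  # 4 x (2l+1)
    degenerate: np.ndarray

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.l, self.l + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, off in enumerate(self.offsets):
            row = {
                "offset": off,
                "H": self.H[j],
                "R": self.R[j],
                "degenerate": bool(self.degenerate[j]),
            }
            for i, b in enumerate(BASES):
                row[f"height_{b}"] = self.heights[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConsensusMotif:
    """IUPAC consensus recognition sequence with its methylated-C index."""

    iupac: str
    target_index: int
    theta: float
    kappa: float

    def __post_init__(self) -> None:
        if self.iupac[self.target_index] != "C":
            raise ValueError("target index does not point at a C")


def extract_windows(
    genome: Genome,
    records: pd.DataFrame,
    l: int = DEFAULT_HALF_WIDTH,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> WindowSet:
    """Extract 2l+1 windows around covered cytosines.

    A record contributes when its total read count is positive and at least
    *min_depth*, its +/-l neighbourhood lies inside the contig, and the
    window contains no N. Minus-strand records yield the reverse complement
    of the genomic slice so the centre reads C on the methylated strand.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    offsets = np.arange(-l, l + 1)
    chunks_codes, chunks_m, chunks_d = [], [], []
    for (contig, strand), grp in records.groupby(["contig", "strand"], sort=False):
        if contig not in genome:
            raise CoordinateError(f"unknown contig {contig!r}")
        enc = genome.encoded(contig)
        pos0 = grp["pos"].to_numpy() - 1
        if ((pos0 < 0) | (pos0 >= len(enc))).any():
            bad = grp.iloc[int(np.flatnonzero((pos0 < 0) | (pos0 >= len(enc)))[0])]
            raise CoordinateError(f"record {contig}:{bad['pos']}{strand} out of bounds")
        want = 1 if strand == "+" else 2
        if (enc[pos0] != want).any():
            bad = grp.iloc[int(np.flatnonzero(enc[pos0] != want)[0])]
            raise CoordinateError(
                f"record {contig}:{bad['pos']}{strand} is not a cytosine on that strand"
            )
        total = (grp["meth"] + grp["unmeth"]).to_numpy()
        keep = (total > 0) & (total >= min_depth)
        keep &= (pos0 - l >= 0) & (pos0 + l < len(enc))
        if not keep.any():
            continue
        pos0 = pos0[keep]
        win = enc[pos0[:, None] + offsets[None, :]]
        if strand == "-":
            win = COMPLEMENT_CODES[win][:, ::-1]
        no_n = ~(win == 4).any(axis=1)
        win = win[no_n]
        if win.size == 0:
            continue
        m = (grp["meth"].to_numpy()[keep] / total[keep])[no_n]
        d = total[keep][no_n]
        chunks_codes.append(win)
        chunks_m.append(m)
        chunks_d.append(d)
    if not chunks_codes:
        return WindowSet(np.empty((0, 2 * l + 1), dtype=np.uint8), np.empty(0), np.empty(0, dtype=int))
    return WindowSet(
        np.concatenate(chunks_codes), np.concatenate(chunks_m), np.concatenate(chunks_d)
    )


def compute_pwm_m(windows: WindowSet | Sequence[MethylationWindow]) -> PWMM:
    """Tabulate the methylation-weighted PWM from a set of windows."""
    if not isinstance(windows, WindowSet):
        windows = WindowSet.from_windows(windows)
    n = len(windows)
    if n == 0:
        raise EmptyInputError("no windows to tabulate")
    width = windows.codes.shape[1]
    M = np.zeros((4, width))
    for j in range(width):
        M[:, j] = np.bincount(windows.codes[:, j], weights=windows.m, minlength=4)[:4]
    M /= n
    colsum = M.sum(axis=0)
    degenerate = colsum == 0
    f = np.zeros_like(M)
    np.divide(M, colsum[None, :], out=f, where=~degenerate[None, :])
    return PWMM(l=width // 2, n_windows=n, M=M, f=f, degenerate=degenerate)


def compute_logo(p: PWMM) -> LogoTable:
    """Entropy, information content and letter heights from a PWM-M.

    H_j uses the convention 0*log2(0) = 0; R_j = 2 - H_j - 0.541 with no
    clamping (negative values are reported). Degenerate offsets carry NaN
    and are excluded from consensus calling.
    """
    f = p.f
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    H = -plogp.sum(axis=0)
    H[p.degenerate] = np.nan
    R = 2.0 - H - LOGO_CORRECTION
    heights = f * R[None, :]
    heights[:, p.degenerate] = np.nan
    return LogoTable(l=p.l, H=H, R=R, heights=heights, degenerate=p.degenerate.copy())


def call_consensus(
    logo: LogoTable,
    p: PWMM,
    theta: float = DEFAULT_THETA,
    kappa: float = DEFAULT_KAPPA,
) -> ConsensusMotif:
    """Collapse a logo to an IUPAC consensus string.

    The span is the minimal contiguous offset interval containing the centre
    and every offset with R_j >= theta. Inside it, offsets below theta
    become N; at informative offsets bases are accumulated in decreasing
    frequency until the cumulative frequency reaches kappa (ties at the
    cutoff are all included) and the base set maps to its IUPAC code.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not 0.5 < kappa <= 1.0:
        raise ValueError("kappa must be in (0.5, 1]")
    if logo.degenerate.all():
        raise DegenerateLogoError("logo has no informative position (no methylation signal)")
    centre = logo.l
    informative = (~logo.degenerate) & (np.nan_to_num(logo.R, nan=-np.inf) >= theta)
    idx = np.flatnonzero(informative)
    lo = min(centre, idx.min()) if idx.size else centre
    hi = max(centre, idx.max()) if idx.size else centre
    chars = []
    for j in range(lo, hi + 1):
        if not informative[j]:
            chars.append("N")
            continue
        order = np.argsort(-p.f[:, j], kind="stable")
        cum = 0.0
        chosen: list[str] = []
        for rank, i in enumerate(order):
            if p.f[i, j] <= 0:
                break
            chosen.append(BASES[i])
            cum += p.f[i, j]
            if cum >= kappa - 1e-12:
                # include any remaining base tied with the last one added
                for i2 in order[rank + 1 :]:
                    if abs(p.f[i2, j] - p.f[i, j]) < 1e-12 and p.f[i2, j] > 0:
                        chosen.append(BASES[i2])
                    else:
                        break
                break
        chars.append(BASES_TO_IUPAC[frozenset(chosen)])
    s = "".join(chars)
    stripped = s.strip("N")
    lead = len(s) - len(s.lstrip("N"))
    target = centre - lo - lead
    return ConsensusMotif(iupac=stripped, target_index=target, theta=theta, kappa=kappa)


@dataclass
class RecognitionResult:
    """End-to-end output: consensus plus the matrices behind it."""

    consensus: ConsensusMotif
    logo: LogoTable
    pwm: PWMM
    n_windows: int


def recognition_pipeline(
    genome: Genome,
    records: pd.DataFrame,
    l: int = DEFAULT_HALF_WIDTH,
    min_depth: int = DEFAULT_MIN_DEPTH,
    theta: float = DEFAULT_THETA,
    kappa: float = DEFAULT_KAPPA,
    out_prefix: str | None = None,
) -> RecognitionResult:
    """WGBS -> recognition sequence: windows, PWM-M, M-logo, consensus.

    With *out_prefix*, writes ``<prefix>.pwm.tsv``, ``<prefix>.logo.tsv``
    and ``<prefix>.motif.txt``.
    """
    windows = extract_windows(genome, records, l=l, min_depth=min_depth)
    pwm = compute_pwm_m(windows)
    logo = compute_logo(pwm)
    consensus = call_consensus(logo, pwm, theta=theta, kappa=kappa)
    if out_prefix is not None:
        pwm.to_frame().to_csv(f"{out_prefix}.pwm.tsv", sep="\t", index=False)
        logo.to_frame().to_csv(f"{out_prefix}.logo.tsv", sep="\t", index=False)
        with open(f"{out_prefix}.motif.txt", "w") as fh:
            fh.write(f"{consensus.iupac}\t{consensus.target_index}\n")
    return RecognitionResult(consensus=consensus, logo=logo, pwm=pwm, n_windows=len(windows))
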