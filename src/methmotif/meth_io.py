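"""Readers and writers for the formats the pipeline touches.

Coordinate conventions
----------------------
* Cytosine reports (CX-style TSV) are **1-based** and strand-explicit.
* All internal coordinates are **0-based, half-open**; BED and bedGraph are
  0-based half-open as usual.
* Minus-strand context strings are reported 5'->3' on the minus strand
  (i.e. on the reverse complement): the biological recognition sequence is
  strand-local.

Cytosine tables are plain :class:`pandas.DataFrame` objects with columns
``contig, pos, strand, meth, unmeth, context`` (``pos`` 1-based). The
:class:`CytosineRecord` named tuple is the row-wise view of the same data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    CoordinateError,
    DuplicateContigError,
    EmptyFastaError,
    InvalidAnchorError,
    MalformedRecordError,
    OverlappingBinsError,
)

logger = logging.getLogger(__name__)

#: canonical column order of a cytosine table
REPORT_COLUMNS = ["contig", "pos", "strand", "meth", "unmeth", "context"]

#: canonical column order of a binned track
TRACK_COLUMNS = ["contig", "start", "end", "level", "depth"]

# base encoding: A=0 C=1 G=2 T=3 N=4
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
#: complement of the encoded alphabet (N maps to N)
COMPLEMENT_CODES = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_seq`."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


class CytosineRecord(NamedTuple):
    """One strand-resolved cytosine with its read support."""

    contig: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    meth: int
    unmeth: int
    context: str

    @property
    def total(self) -> int:
        return self.meth + self.unmeth

    @property
    def level(self) -> float:
        """Methylation level m = meth/(meth+unmeth); NaN at zero coverage."""
        t = self.total
        return self.meth / t if t > 0 else float("nan")


@dataclass
class Genome:
    """An in-memory genome: ordered map of contig name -> ACGTN sequence."""

    contigs: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in self.contigs:
            if not name:
                raise DuplicateContigError("empty contig name")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self):
        return iter(self.contigs)

    def items(self):
        return self.contigs.items()

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def encoded(self, name: str) -> np.ndarray:
        """uint8 encoding of a contig, cached."""
        arr = self._encoded.get(name)
        if arr is None:
            arr = encode_seq(self.contigs[name])
            self._encoded[name] = arr
        return arr


_INVALID_BASE = re.compile(r"[^ACGTN]")


def read_genome(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased, U is mapped to T, and any other non-ACGTN
    character becomes N with a logged warning. Missing file, duplicate
    contig names and empty files raise distinct errors.
    """
    contigs: dict[str, str] = {}
    with open(path) as fh:  # FileNotFoundError if missing
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in contigs:
                raise DuplicateContigError(f"duplicate contig name {rec.id!r} in {path}")
            seq = str(rec.seq).upper().replace("U", "T")
            seq, n_bad = _INVALID_BASE.subn("N", seq)
            if n_bad:
                logger.warning(
                    "contig %s: %d non-ACGTN character(s) replaced with N", rec.id, n_bad
                )
            contigs[rec.id] = seq
    if not contigs:
        raise EmptyFastaError(f"no FASTA records in {path}")
    return Genome(contigs)


def write_genome(genome: Genome, path, width: int = 70) -> None:
    """Write a :class:`Genome` as FASTA."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a 6-column cytosine report (CX-style TSV, no header).

    Columns: contig, position (1-based), strand (+/-), count methylated,
    count unmethylated, trinucleotide context. Malformed lines raise
    :class:`MalformedRecordError` naming the line number.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={"contig": str, "strand": str, "context": str},
            na_filter=False,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas parser errors carry the line number
        raise MalformedRecordError(f"{path}: {exc}") from exc
    if df.shape[1] != 6:
        raise MalformedRecordError(f"{path}: expected 6 columns, got {df.shape[1]}")
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals % 1 != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise MalformedRecordError(f"{path} line {line}: non-integer {col!r} field")
        df[col] = vals.astype(np.int64)
    neg = (df["meth"] < 0) | (df["unmeth"] < 0) | (df["pos"] < 1)
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise MalformedRecordError(f"{path} line {line}: negative count or position")
    badstrand = ~df["strand"].isin(["+", "-"])
    if badstrand.any():
        line = int(np.flatnonzero(badstrand.to_numpy())[0]) + 1
        raise MalformedRecordError(f"{path} line {line}: strand must be '+' or '-'")
    return df


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    """Write a cytosine table as 6-column TSV (inverse of the reader)."""
    records[REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def records_to_tuples(records: pd.DataFrame) -> list[CytosineRecord]:
    """Row-wise view of a cytosine table as named tuples."""
    return [CytosineRecord(*row) for row in records[REPORT_COLUMNS].itertuples(index=False)]


def validate_records(genome: Genome, records: pd.DataFrame) -> None:
    """Check every record points at a C on its stated strand of *genome*.

    A plus-strand record must sit on a genomic C; a minus-strand record on a
    genomic G (a C on the reverse complement). Raises
    :class:`CoordinateError` naming the first offending record.
    """
    for (contig, strand), grp in records.groupby(["contig", "strand"], sort=False):
        if contig not in genome:
            raise CoordinateError(f"unknown contig {contig!r}")
        enc = genome.encoded(contig)
        pos0 = grp["pos"].to_numpy() - 1
        oob = (pos0 < 0) | (pos0 >= len(enc))
        if oob.any():
            bad = grp.iloc[int(np.flatnonzero(oob)[0])]
            raise CoordinateError(
                f"record {contig}:{bad['pos']}{strand} outside contig bounds"
            )
        want = 1 if strand == "+" else 2  # C on plus, G on plus == C on minus
        mismatch = enc[pos0] != want
        if mismatch.any():
            bad = grp.iloc[int(np.flatnonzero(mismatch)[0])]
            raise CoordinateError(
                f"record {contig}:{bad['pos']}{strand} is not a cytosine on that strand"
            )


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    track = track.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    for contig, grp in track.groupby("contig", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends[:-1] > starts[1:]).any():
            raise OverlappingBinsError(f"overlapping bins on contig {contig!r}")
    return track


def write_binned_track(track: pd.DataFrame, path) -> None:
    """Write a binned track as bedGraph (contig, start, end, level).

    Bins must be non-overlapping per contig; levels are formatted with six
    decimals so write-then-read round-trips up to float formatting.
    """
    track = _check_track(track)
    with open(path, "w") as fh:
        for row in track.itertuples(index=False):
            fh.write(f"{row.contig}\t{int(row.start)}\t{int(row.end)}\t{row.level:.6f}\n")


def read_binned_track(path) -> pd.DataFrame:
    """Read a bedGraph written by :func:`write_binned_track`."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "level"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "level": float},
    ) if _nonempty(path) else pd.DataFrame(columns=["contig", "start", "end", "level"])
    return df


def _nonempty(path) -> bool:
    import os

    return os.path.getsize(path) > 0


def read_anchors(path) -> pd.DataFrame:
    """Read anchor points from a BED file.

    The anchor point of each interval is its start coordinate on the plus
    strand and end-1 on the minus strand (0-based). Strand comes from BED
    column 6 when present, else '+'. Returns a DataFrame with columns
    ``contig, pos, strand, name`` (``pos`` 0-based).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidAnchorError(f"{path} line {ln}: fewer than 3 BED columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise InvalidAnchorError(f"{path} line {ln}: start >= end")
            name = fields[3] if len(fields) > 3 else f"anchor{ln}"
            strand = fields[5] if len(fields) > 5 else "+"
            if strand not in ("+", "-"):
                raise InvalidAnchorError(f"{path} line {ln}: bad strand {strand!r}")
            pos = start if strand == "+" else end - 1
            rows.append((contig, pos, strand, name))
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "name"])


def anchors_from_tuples(entries: Iterable[tuple]) -> pd.DataFrame:
    """Build an anchor table from (contig, pos0, strand[, name]) tuples."""
    rows = []
    for i, e in enumerate(entries):
        contig, pos, strand = e[0], int(e[1]), e[2]
        name = e[3] if len(e) > 3 else f"anchor{i}"
        rows.append((contig, pos, strand, name))
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "name"])
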