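"""NOMe-seq analytics: channel separation, binned tracks, aggregation
profiles, periodicity estimation, and a simple accessible-region segmenter.

In a NOMe experiment an exogenous MTase methylates accessible DNA in
nuclei; WGBS then reads both the cell's intrinsic CG methylation and the
enzyme-induced methylation. The two signals are separated by sequence
context:

* GCMT mode (GC-methylating probe): intrinsic = HCG, induced = GCH, and
  the ambiguous GCG sites — where either source could have written the
  mark — are excluded.
* CCMT mode (CC-methylating probe): intrinsic = CG, induced = first C of
  CC. The two target sets are disjoint by the next base, so nothing needs
  excluding — the motivation for a CC probe.

The accessible-region segmenter is a deliberately simple threshold/merge
caller standing in for a full peak caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, MethMotifError
from .meth_io import Genome, TRACK_COLUMNS

DEFAULT_BIN_SIZE = 10
DEFAULT_DEPTH_FLOOR = 5
#: minimum normalised autocorrelation at the peak for a confident period
PERIODICITY_PROMINENCE_FLOOR = 0.1


@dataclass(frozen=True)
class ChannelSpec:
    """Context sets separating intrinsic from induced methylation."""

    mode: str  # 'CCMT' or 'GCMT'

    @property
    def intrinsic_context(self) -> str:
        return {"CCMT": "CG", "GCMT": "HCG"}[self.mode]

    @property
    def induced_context(self) -> str:
        return {"CCMT": "CC", "GCMT": "GCH"}[self.mode]

    @property
    def excluded_context(self) -> str | None:
        return {"CCMT": None, "GCMT": "GCG"}[self.mode]


class SplitResult(NamedTuple):
    intrinsic: pd.DataFrame
    induced: pd.DataFrame
    excluded: pd.DataFrame
    other: pd.DataFrame


def split_channels(records: pd.DataFrame, genome: Genome, spec: ChannelSpec) -> SplitResult:
    """Assign each cytosine record to intrinsic / induced / excluded / other.

    Contexts are read from the genome on each record's own strand, so the
    classification never trusts the report's context column. Every record
    lands in exactly one class; intrinsic and induced are disjoint.
    """
    if spec.mode not in ("CCMT", "GCMT"):
        raise MethMotifError(f"unknown NOMe mode {spec.mode!r}")
    labels = pd.Series("other", index=records.index, dtype=object)
    comp6 = np.array([3, 2, 1, 0, 4, 5], dtype=np.uint8)
    for (contig, strand), grp in records.groupby(["contig", "strand"], sort=False):
        if contig not in genome:
            raise MethMotifError(f"unknown contig {contig!r}")
        enc = genome.encoded(contig)
        pos0 = grp["pos"].to_numpy() - 1
        if strand == "+":
            nxt = _safe_codes(enc, pos0 + 1)
            prv = _safe_codes(enc, pos0 - 1)
        else:
            nxt = comp6[_safe_codes(enc, pos0 - 1)]
            prv = comp6[_safe_codes(enc, pos0 + 1)]
        lab = np.full(len(grp), "other", dtype=object)
        if spec.mode == "GCMT":
            is_cg = nxt == 2
            h_prev = np.isin(prv, [0, 1, 3])
            g_prev = prv == 2
            h_next = np.isin(nxt, [0, 1, 3])
            lab[is_cg & h_prev] = "intrinsic"
            lab[g_prev & h_next] = "induced"
            lab[is_cg & g_prev] = "excluded"
        else:  # CCMT
            lab[nxt == 2] = "intrinsic"
            lab[nxt == 1] = "induced"
        labels.loc[grp.index] = lab
    return SplitResult(
        intrinsic=records[labels == "intrinsic"],
        induced=records[labels == "induced"],
        excluded=records[labels == "excluded"],
        other=records[labels == "other"],
    )


def _safe_codes(enc: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.full(len(idx), 5, dtype=np.uint8)
    ok = (idx >= 0) & (idx < len(enc))
    out[ok] = enc[idx[ok]]
    return out


def bin_levels(records: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Coverage-weighted methylation level per fixed-width bin.

    The level of a bin is the pooled count ratio sum(meth)/sum(meth+unmeth),
    not a mean of per-site levels; bins with no reads are omitted. Returns
    a track DataFrame (contig, start, end, level, depth), 0-based half-open.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not len(records):
        return pd.DataFrame(columns=TRACK_COLUMNS)
    df = records.assign(
        start=((records["pos"] - 1) // bin_size) * bin_size,
        total=records["meth"] + records["unmeth"],
    )
    grouped = (
        df.groupby(["contig", "start"], sort=True)[["meth", "total"]].sum().reset_index()
    )
    grouped = grouped[grouped["total"] > 0]
    grouped["end"] = grouped["start"] + bin_size
    grouped["level"] = grouped["meth"] / grouped["total"]
    grouped["depth"] = grouped["total"]
    return grouped[TRACK_COLUMNS].reset_index(drop=True)


@dataclass
class AggregationProfile:
    """Mean methylation by strand-oriented offset from a set of anchors."""

    flank: int
    table: pd.DataFrame  # columns: offset, mean_level, n_sites (only offsets with n>0)

    def full_grid(self) -> pd.DataFrame:
        """Profile on the complete -F..+F grid with NaN where no sites."""
        grid = pd.DataFrame({"offset": np.arange(-self.flank, self.flank + 1)})
        return grid.merge(self.table, on="offset", how="left")


def aggregate_profile(
    records: pd.DataFrame, anchors: pd.DataFrame, flank: int
) -> AggregationProfile:
    """Aggregate per-site levels at strand-oriented offsets around anchors.

    For a minus-strand anchor the offset sign flips, so profiles read
    5'->3' of the anchored feature. The per-offset value is the unweighted
    mean of site levels across anchors (a site contributes once per anchor
    whose window covers it); zero-coverage sites are ignored.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if not len(anchors):
        raise EmptyInputError("empty anchor set")
    width = 2 * flank + 1
    sums = np.zeros(width)
    counts = np.zeros(width, dtype=np.int64)
    total = records["meth"] + records["unmeth"]
    covered = records[total > 0].copy()
    covered["level"] = covered["meth"] / (covered["meth"] + covered["unmeth"])
    by_contig = {}
    for contig, grp in covered.groupby("contig", sort=False):
        grp = grp.sort_values("pos", kind="stable")  # searchsorted needs order
        by_contig[contig] = (grp["pos"].to_numpy() - 1, grp["level"].to_numpy())
    for anchor in anchors.itertuples(index=False):
        if anchor.contig not in by_contig:
            continue
        pos0, level = by_contig[anchor.contig]
        lo = np.searchsorted(pos0, anchor.pos - flank, side="left")
        hi = np.searchsorted(pos0, anchor.pos + flank, side="right")
        if hi <= lo:
            continue
        off = pos0[lo:hi] - anchor.pos
        if anchor.strand == "-":
            off = -off
        idx = off + flank
        np.add.at(sums, idx, level[lo:hi])
        np.add.at(counts, idx, 1)
    has = counts > 0
    table = pd.DataFrame(
        {
            "offset": np.arange(-flank, flank + 1)[has],
            "mean_level": sums[has] / counts[has],
            "n_sites": counts[has],
        }
    )
    return AggregationProfile(flank=flank, table=table)


def profile_peak(profile: AggregationProfile, smooth_bp: int = 51) -> int:
    """Offset of the maximum of the moving-average-smoothed profile.

    Per-base aggregate levels are noisy and, with phased nucleosomes,
    short linkers are as accessible per base as a nucleosome-depleted
    region; a moving average of width *smooth_bp* makes the widest
    accessible region the unambiguous maximum.
    """
    grid = profile.full_grid()
    y = grid["mean_level"].to_numpy(dtype=float)
    y = _interpolate_nan(y)
    kernel = np.ones(smooth_bp) / smooth_bp
    smoothed = np.convolve(y, kernel, mode="same")
    return int(grid["offset"].iloc[int(np.argmax(smoothed))])


def _interpolate_nan(y: np.ndarray) -> np.ndarray:
    y = y.copy()
    nans = np.isnan(y)
    if nans.all():
        raise EmptyInputError("profile has no covered offsets")
    if nans.any():
        x = np.arange(len(y))
        y[nans] = np.interp(x[nans], x[~nans], y[~nans])
    return y


@dataclass(frozen=True)
class PeriodicityResult:
    period: int
    acf_peak: float  # normalised autocorrelation at the chosen lag
    confident: bool


def estimate_periodicity(
    profile: AggregationProfile,
    min_period: int,
    max_period: int,
    prominence_floor: float = PERIODICITY_PROMINENCE_FLOOR,
) -> PeriodicityResult:
    """Dominant spatial period of an aggregation profile, by autocorrelation.

    Missing offsets are linearly interpolated, the profile is
    mean-subtracted, and the period is the lag maximising the normalised
    autocorrelation within [min_period, max_period]. A peak below
    *prominence_floor* is flagged low-confidence (e.g. white noise).
    """
    grid = profile.full_grid()
    y = _interpolate_nan(grid["mean_level"].to_numpy(dtype=float))
    span = len(y)
    if not 1 <= min_period <= max_period:
        raise ValueError("need 1 <= min_period <= max_period")
    if span < 3 * max_period:
        raise MethMotifError(
            f"profile span {span} shorter than 3 x max_period {max_period}"
        )
    y = y - y.mean()
    # unbiased estimate: divide each lag by its overlap length, otherwise
    # the shrinking overlap biases the argmax toward smaller lags
    acf = np.correlate(y, y, mode="full")[span - 1 :] / (span - np.arange(span))
    if acf[0] <= 0:
        return PeriodicityResult(period=min_period, acf_peak=0.0, confident=False)
    acf = acf / acf[0]
    lags = np.arange(min_period, max_period + 1)
    best = int(np.argmax(acf[lags]))
    peak = float(acf[lags][best])
    return PeriodicityResult(
        period=int(lags[best]), acf_peak=peak, confident=peak >= prominence_floor
    )


def call_accessible_regions(
    track: pd.DataFrame,
    level_threshold: float,
    min_len: int,
    merge_gap: int = 0,
) -> pd.DataFrame:
    """Threshold segmenter for induced-methylation tracks.

    Maximal runs of bins with level >= threshold are merged across gaps of
    at most *merge_gap* bp and kept when at least *min_len* bp long. This
    is a simple, clearly-flagged stand-in for a statistical peak caller.
    Returns a DataFrame (contig, start, end, mean_level) with mean level
    depth-weighted over contributing bins.
    """
    if level_threshold <= 0 or min_len <= 0:
        raise ValueError("thresholds must be positive")
    regions = []
    for contig, grp in track.groupby("contig", sort=True):
        grp = grp.sort_values("start")
        hot = grp[grp["level"] >= level_threshold]
        current = None  # [start, end, sum_lev*depth, sum_depth]
        for row in hot.itertuples(index=False):
            if current is not None and row.start - current[1] <= merge_gap:
                current[1] = row.end
                current[2] += row.level * row.depth
                current[3] += row.depth
            else:
                if current is not None:
                    regions.append((contig, *current))
                current = [row.start, row.end, row.level * row.depth, row.depth]
        if current is not None:
            regions.append((contig, *current))
    out = pd.DataFrame(regions, columns=["contig", "start", "end", "wsum", "depth"])
    if len(out):
        out = out[out["end"] - out["start"] >= min_len].reset_index(drop=True)
        out["mean_level"] = out["wsum"] / out["depth"]
    else:
        out["mean_level"] = pd.Series(dtype=float)
    return out[["contig", "start", "end", "mean_level"]]


@dataclass(frozen=True)
class TrackComparison:
    n_bins: int
    pearson: float
    spearman: float


def compare_tracks(
    a: pd.DataFrame, b: pd.DataFrame, depth_floor: int = DEFAULT_DEPTH_FLOOR
) -> tuple[pd.DataFrame, TrackComparison]:
    """Inner-join two binned tracks and correlate their levels.

    Only bins present in both tracks with depth >= depth_floor in each
    contribute; returns the joined table and Pearson/Spearman summaries.
    """
    joined = a.merge(b, on=["contig", "start", "end"], suffixes=("_a", "_b"))
    joined = joined[(joined["depth_a"] >= depth_floor) & (joined["depth_b"] >= depth_floor)]
    if not len(joined):
        raise EmptyInputError("tracks share no bins at the requested depth floor")
    x = joined["level_a"].to_numpy()
    y = joined["level_b"].to_numpy()
    if np.ptp(x) == 0 and np.ptp(y) == 0 and np.allclose(x, y):
        pear = spear = 1.0  # identical constant tracks
    else:
        pear = float(stats.pearsonr(x, y).statistic)
        spear = float(stats.spearmanr(x, y).statistic)
    return joined.reset_index(drop=True), TrackComparison(len(joined), pear, spear)
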