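"""Enhancer stitching, rank-curve super-enhancer calling, cross-sample
rank percentiles, and spike-in (RRPM) normalization.

Super enhancers are called ROSE-style: constituent peaks within a stitch
gap (default 12.5 kb) are merged into regions whose signal is the sum of
constituent signals; regions are ranked by signal, both axes of the
rank-signal curve are min-max scaled to [0, 1], and the cutoff is placed
where a line of slope 1 is tangent to the curve. Regions above the
cutoff are super
enhancers — typically a few percent of all enhancers.

RRPM = reads per million *spike-in* (reference exogenous) reads; delta
RRPM tracks give the signed change in spike-in-normalized signal between
a perturbed and a control condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

REGION_COLS = ["chrom", "start", "end", "signal"]


class EnhancerRankError(ValueError):
    pass


def _check_regions(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGION_COLS if c not in df.columns]
    if missing:
        raise EnhancerRankError(f"region table missing columns {missing}")
    if (df["signal"] < 0).any():
        raise EnhancerRankError("signals must be non-negative")
    if (df["start"] >= df["end"]).any():
        raise EnhancerRankError("intervals must satisfy start < end")
    return df


def stitch_enhancers(
    peaks: pd.DataFrame,
    gap: int = 12_500,
    tss_exclusion: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge peaks within ``gap`` bp into stitched enhancer regions.

    Stitched signal is the sum over constituent peaks (rank-by-load
    convention). ``tss_exclusion`` optionally removes peaks overlapping
    promoter windows before stitching. Stitching is idempotent for any
    already-stitched output.
    """
    if gap < 0:
        raise EnhancerRankError("gap must be non-negative")
    peaks = _check_regions(peaks.copy())
    if tss_exclusion is not None:
        drop = np.zeros(len(peaks), dtype=bool)
        for _, t in tss_exclusion.iterrows():
            drop |= (
                (peaks["chrom"] == t["chrom"])
                & (peaks["start"] < t["end"])
                & (t["start"] < peaks["end"])
            ).to_numpy()
        peaks = peaks.loc[~drop]
    out = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for _, row in grp.iterrows():
            if cur is None:
                cur = [chrom, int(row["start"]), int(row["end"]), float(row["signal"])]
            elif row["start"] - cur[2] <= gap:
                cur[2] = max(cur[2], int(row["end"]))
                cur[3] += float(row["signal"])
            else:
                out.append(cur)
                cur = [chrom, int(row["start"]), int(row["end"]), float(row["signal"])]
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out, columns=REGION_COLS)


def call_superenhancers(regions: pd.DataFrame) -> pd.DataFrame:
    """Rank stitched regions and flag super enhancers by the elbow cutoff.

    Returns the regions with ``rank`` (1 = highest signal; signal ties
    broken by genomic position), ``percentile`` = 100 (N - rank + 1) / N,
    ``is_se``, and a ``cutoff_signal`` column (constant). With all-equal
    signals no cutoff exists: zero SEs, with a warning.
    """
    regions = _check_regions(regions.copy())
    n = len(regions)
    if n < 3:
        raise EnhancerRankError("need >= 3 regions to place a rank-curve cutoff")
    asc = regions.sort_values(
        ["signal", "chrom", "start"], ascending=[True, True, True]
    ).reset_index(drop=True)
    sig = asc["signal"].to_numpy(dtype=float)
    smin, smax = sig.min(), sig.max()
    if smax == smin:
        warnings.warn("all signals equal; no super-enhancer cutoff", stacklevel=2)
        cutoff = np.inf
    else:
        y = (sig - smin) / (smax - smin)
        x = np.arange(n, dtype=float) / (n - 1)
        # tangent of the slope-1 line to the scaled rank curve: the curve is
        # non-decreasing, so the tangent point is where y - x is minimal
        # (equivalently where the smoothed slope crosses 1); more stable
        # than thresholding raw adjacent slopes, which a single mid-curve
        # gap can trip
        cutoff = sig[int(np.argmin(y - x))]
    ranked = asc.iloc[::-1].reset_index(drop=True)  # descending signal
    ranked["rank"] = np.arange(1, n + 1)
    ranked["percentile"] = 100.0 * (n - ranked["rank"] + 1) / n
    ranked["is_se"] = ranked["signal"] > cutoff
    ranked["cutoff_signal"] = cutoff if np.isfinite(cutoff) else np.nan
    return ranked


def rank_percentile(
    query: tuple[str, int, int],
    ranked_by_sample: "dict[str, pd.DataFrame]",
) -> pd.Series:
    """Rank percentile of the enhancer landscape at a query locus, per sample.

    For each sample the percentile of the best (highest-percentile)
    stitched region sharing at least one base with the query interval is
    reported; samples with no overlapping region get NaN (explicit
    absence).
    """
    chrom, qstart, qend = query
    if qstart >= qend:
        raise EnhancerRankError("query interval must satisfy start < end")
    out = {}
    for sample, ranked in ranked_by_sample.items():
        hit = ranked[
            (ranked["chrom"] == chrom)
            & (ranked["start"] < qend)
            & (qstart < ranked["end"])
        ]
        out[sample] = float(hit["percentile"].max()) if len(hit) else np.nan
    return pd.Series(out, name="percentile")


@dataclass
class RxTrack:
    """Binned spike-in-normalized coverage (RRPM = count * 1e6 / spike-in)."""

    bins: pd.DataFrame  # chrom, start, end
    counts: np.ndarray
    spike_in_total: float

    def __post_init__(self) -> None:
        if self.spike_in_total <= 0:
            raise EnhancerRankError("spike-in total must be positive")
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bins):
            raise EnhancerRankError("counts and bins disagree in length")

    @property
    def rrpm(self) -> np.ndarray:
        return self.counts * 1e6 / self.spike_in_total


def rx_normalize(bins: pd.DataFrame, counts, spike_in_total: float) -> RxTrack:
    """Spike-in normalize binned counts to RRPM."""
    return RxTrack(bins=bins.reset_index(drop=True), counts=counts, spike_in_total=spike_in_total)


def delta_rrpm(treated: RxTrack, control: RxTrack) -> pd.DataFrame:
    """Signed difference track: RRPM(treated) - RRPM(control) per bin."""
    if len(treated.bins) != len(control.bins) or not (
        treated.bins[["chrom", "start", "end"]].reset_index(drop=True)
        .equals(control.bins[["chrom", "start", "end"]].reset_index(drop=True))
    ):
        raise EnhancerRankError("treated and control tracks have mismatched bins")
    out = treated.bins[["chrom", "start", "end"]].copy()
    out["delta_rrpm"] = treated.rrpm - control.rrpm
    return out
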