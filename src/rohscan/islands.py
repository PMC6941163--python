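"""ROH islands: population-level hotspots of ROH incidence.

For each marker, the incidence track counts how many individuals carry a
(deduplicated) ROH covering that position.  Markers whose count reaches the
nearest-rank top-percentile threshold (top 1% by default) are flagged, and
maximal runs of consecutive flagged markers on a chromosome are merged into
"ROH islands" — candidate signatures of directional selection — provided
they contain at least ``min_snps_island`` markers (3 by default, the smallest
region observed on bovine 54K panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerMap
from .roh import RohSegment

__all__ = [
    "IncidenceTrack",
    "Island",
    "incidence",
    "threshold_top1",
    "call_islands",
    "region_length_kb",
    "island_stats",
    "islands_to_frame",
    "write_islands_bed",
]


@dataclass
class IncidenceTrack:
    """Per-marker ROH membership counts across a population, aligned to a map."""

    counts: np.ndarray
    n_individuals: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if (self.counts < 0).any() or (self.counts > self.n_individuals).any():
            raise ValueError("counts must lie in [0, n_individuals]")

    @property
    def freq(self) -> np.ndarray:
        return self.counts / self.n_individuals


@dataclass(frozen=True)
class Island:
    """A merged run of consecutive high-incidence markers."""

    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    max_count: int = 0

    @property
    def length_kb(self) -> int:
        return region_length_kb(self.start_bp, self.end_bp)


def region_length_kb(start_bp: int, end_bp: int) -> int:
    """Region length in kb, truncated: (end − start) // 1000."""
    if end_bp < start_bp:
        raise ValueError("end_bp must be >= start_bp")
    return int((end_bp - start_bp) // 1000)


def incidence(
    segments: list[RohSegment],
    marker_map: MarkerMap,
    n_individuals: int,
) -> IncidenceTrack:
    """Count, per marker, the individuals whose ROH cover it.

    ``segments`` must be deduplicated per individual (pairwise disjoint), so a
    marker is counted at most once per individual.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    counts = np.zeros(len(marker_map), dtype=np.int64)
    slices = marker_map.chrom_slices()
    all_pos = marker_map.df["pos_bp"].to_numpy()
    for seg in segments:
        sl = slices.get(seg.chrom)
        if sl is None:
            continue
        pos = all_pos[sl]
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        counts[sl.start + lo : sl.start + hi] += 1
    return IncidenceTrack(counts, n_individuals)


def threshold_top1(track: IncidenceTrack, top_fraction: float = 0.01) -> int:
    """Nearest-rank top-percentile threshold on incidence counts.

    Returns the count value at rank ceil(top_fraction x n_markers) of the
    descending-sorted counts; markers with count >= the returned value are
    flagged downstream (ties at the threshold are all included).
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must be in (0, 1)")
    n = len(track.counts)
    if n == 0:
        raise ValueError("empty incidence track")
    k = math.ceil(top_fraction * n)
    return int(np.sort(track.counts)[::-1][k - 1])


def call_islands(
    track: IncidenceTrack,
    marker_map: MarkerMap,
    threshold: int,
    min_snps_island: int = 3,
) -> list[Island]:
    """Merge maximal runs of consecutive flagged markers into islands.

    A marker is flagged when its count >= ``threshold``.  Runs never bridge an
    unflagged marker or a chromosome break; runs shorter than
    ``min_snps_island`` markers are dropped.
    """
    flagged = track.counts >= threshold
    out = []
    all_pos = marker_map.df["pos_bp"].to_numpy()
    for chrom, sl in marker_map.chrom_slices().items():
        f = flagged[sl]
        pos = all_pos[sl]
        cnt = track.counts[sl]
        i = 0
        n = len(f)
        while i < n:
            if not f[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and f[j + 1]:
                j += 1
            if j - i + 1 >= min_snps_island:
                out.append(
                    Island(
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        n_snps=j - i + 1,
                        max_count=int(cnt[i : j + 1].max()),
                    )
                )
            i = j + 1
    return out


def islands_to_frame(islands: list[Island], group: str | None = None) -> pd.DataFrame:
    rows = [
        (isl.chrom, isl.start_bp, isl.end_bp, isl.n_snps, isl.length_kb, isl.max_count)
        for isl in islands
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "length_kb", "max_count"]
    )
    if group is not None:
        df.insert(0, "group", group)
    return df


def island_stats(islands: pd.DataFrame, group_col: str | None = "group") -> pd.DataFrame:
    """Region statistics per group and overall.

    ``islands`` needs columns chrom, n_snps, length_kb (plus ``group_col`` when
    grouped): region count, distinct chromosomes, min/max/mean region length
    (kb) and mean SNPs per region.
    """
    if len(islands) == 0:
        raise ValueError("no islands to summarize")

    def one(df, label):
        return {
            "group": label,
            "n_regions": len(df),
            "n_chromosomes": df["chrom"].nunique(),
            "length_kb_min": float(df["length_kb"].min()),
            "length_kb_max": float(df["length_kb"].max()),
            "length_kb_mean": float(df["length_kb"].mean()),
            "n_snps_mean": float(df["n_snps"].mean()),
        }

    rows = []
    if group_col is not None and group_col in islands.columns:
        for g, df in islands.groupby(group_col, sort=False):
            rows.append(one(df, g))
    rows.append(one(islands, "overall"))
    return pd.DataFrame(rows)


def write_islands_bed(islands: list[Island], path, group: str = "islands") -> None:
    """Write islands as BED (0-based half-open; name = group, score = max count)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(
                f"{isl.chrom}\t{isl.start_bp - 1}\t{isl.end_bp}\t{group}\t{isl.max_count}\n"
            )
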