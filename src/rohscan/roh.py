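"""Run-of-homozygosity detection with length-class-specific error allowances.

A run of homozygosity (ROH) is a maximal stretch of consecutive markers in
which an individual is homozygous at (nearly) every assayed SNP.  Detection
here follows the sliding-window-free ("consecutive SNP") approach: within each
chromosome, maximal marker intervals are found such that

(a) every gap between consecutive panel markers is at most ``max_gap_bp``
    (1 Mb default),
(b) the number of heterozygous calls does not exceed the class allowance,
(c) the number of missing calls does not exceed the class allowance,
(d) the run contains at least ``min_snps`` homozygous calls (30 by default;
    tolerated het/missing markers sit inside the run but do not count),
(e) the run is trimmed so its first and last marker are homozygous calls,

and the trimmed run falls inside the class length bounds.  Runs are detected
separately for five length classes (1-2, 2-4, 4-8, 8-16, >16 Mb) because the
tolerated heterozygote and missing-call counts grow with expected run length:
at a ~0.2% array genotyping error rate a >16 Mb run is expected to contain a
spurious heterozygote, while a 1-2 Mb run is not.  Per-class detections are
then merged per individual with a longest-wins deduplication so no base pair
is counted twice in downstream inbreeding estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)

__all__ = [
    "LengthClass",
    "RohSegment",
    "DEFAULT_CLASSES",
    "default_classes",
    "validate_classes",
    "scan_class",
    "detect_roh",
    "allowed_errors",
    "calibrate_allowances",
    "segments_to_frame",
    "write_segments",
]


@dataclass(frozen=True)
class LengthClass:
    """One ROH length category with its heterozygote/missing allowances."""

    name: str
    lower_mb: float
    upper_mb: float  # math.inf for the open-ended class
    max_het: int
    max_missing: int
    min_snps: int = 30

    def contains_length(self, length_bp: int) -> bool:
        mb = length_bp / 1e6
        return self.lower_mb <= mb < self.upper_mb


def default_classes() -> list[LengthClass]:
    """The standard five bovine-array classes: het allowances (0,0,0,0,1),
    missing allowances (0,0,1,2,4), 30 homozygous SNPs minimum."""
    return [
        LengthClass("1-2", 1, 2, 0, 0),
        LengthClass("2-4", 2, 4, 0, 0),
        LengthClass("4-8", 4, 8, 0, 1),
        LengthClass("8-16", 8, 16, 0, 2),
        LengthClass("16+", 16, math.inf, 1, 4),
    ]


DEFAULT_CLASSES = default_classes()


@dataclass(frozen=True)
class RohSegment:
    """One called run: marker span, composition counts and length class."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int       # markers spanned (incl. tolerated het/missing)
    n_het: int
    n_missing: int
    class_name: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_hom(self) -> int:
        return self.n_snps - self.n_het - self.n_missing

    def overlaps(self, other: "RohSegment") -> bool:
        return (
            self.sample_id == other.sample_id
            and self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and self.end_bp >= other.start_bp
        )


def validate_classes(classes: list[LengthClass]) -> None:
    """Classes must tile [1 Mb, inf) without overlap."""
    cs = sorted(classes, key=lambda c: c.lower_mb)
    if not cs:
        raise ValueError("no length classes given")
    if cs[0].lower_mb != 1:
        raise ValueError("length classes must start at 1 Mb")
    for a, b in zip(cs, cs[1:]):
        if a.upper_mb != b.lower_mb:
            raise ValueError(
                f"length classes {a.name!r} and {b.name!r} do not tile: "
                f"{a.upper_mb} != {b.lower_mb}"
            )
    if cs[-1].upper_mb != math.inf:
        raise ValueError("last length class must be open-ended")


def _maximal_windows(pos, het, miss, max_het, max_missing, max_gap_bp):
    """All maximal index windows satisfying the gap/het/missing constraints.

    Within each gap-block the largest right end j(i) for every left end i is
    found via prefix-count bisection; a window [i, j(i)] is maximal iff it
    cannot be extended left, i.e. i is the block start or j(i-1) < j(i).
    """
    n = len(pos)
    if n == 0:
        return []
    gaps = np.diff(pos)
    block_starts = np.concatenate(([0], np.nonzero(gaps > max_gap_bp)[0] + 1, [n]))
    out = []
    ph = np.concatenate(([0], np.cumsum(het)))
    pm = np.concatenate(([0], np.cumsum(miss)))
    for bs, be in zip(block_starts[:-1], block_starts[1:]):
        # j+1 is the largest k <= be with ph[k] <= ph[i] + H and pm[k] <= pm[i] + M
        i_idx = np.arange(bs, be)
        jh = np.searchsorted(ph[: be + 1], ph[i_idx] + max_het, side="right") - 1
        jm = np.searchsorted(pm[: be + 1], pm[i_idx] + max_missing, side="right") - 1
        j = np.minimum(jh, jm) - 1  # inclusive right index
        j = np.minimum(j, be - 1)
        keep = np.empty(len(i_idx), dtype=bool)
        keep[0] = True
        keep[1:] = j[1:] > j[:-1]
        for i, jj in zip(i_idx[keep], j[keep]):
            if jj >= i:
                out.append((int(i), int(jj)))
    return out


def scan_class(
    calls: np.ndarray,
    marker_map: MarkerMap,
    cls: LengthClass,
    max_gap_bp: int = 1_000_000,
    sample_id: str = "",
) -> list[RohSegment]:
    """Detect all runs for one individual under one length class's rules.

    Returns trimmed maximal runs (homozygous first/last marker) containing at
    least ``cls.min_snps`` homozygous calls, with lengths inside the class
    bounds.  ``calls`` must be aligned to the sorted ``marker_map``.
    """
    calls = np.asarray(calls)
    if calls.shape[0] != len(marker_map):
        raise ValueError("calls not aligned to marker map")
    segments = []
    all_pos = marker_map.df["pos_bp"].to_numpy()
    for chrom, sl in marker_map.chrom_slices().items():
        pos = all_pos[sl]
        c = calls[sl]
        het = (c == 1).astype(np.int64)
        miss = (c == MISSING).astype(np.int64)
        hom = (c == 0) | (c == 2)
        hom_idx = np.nonzero(hom)[0]
        if len(hom_idx) < cls.min_snps:
            continue
        ph = np.concatenate(([0], np.cumsum(het)))
        pm = np.concatenate(([0], np.cumsum(miss)))
        phom = np.concatenate(([0], np.cumsum(hom.astype(np.int64))))
        seen = set()
        for i, j in _maximal_windows(pos, het, miss, cls.max_het, cls.max_missing, max_gap_bp):
            # trim to homozygous endpoints
            lo = np.searchsorted(hom_idx, i, side="left")
            hi = np.searchsorted(hom_idx, j, side="right") - 1
            if lo >= len(hom_idx) or hi < 0 or hom_idx[lo] > j or lo > hi:
                continue
            ti, tj = int(hom_idx[lo]), int(hom_idx[hi])
            if (ti, tj) in seen:
                continue
            seen.add((ti, tj))
            n_hom = int(phom[tj + 1] - phom[ti])
            if n_hom < cls.min_snps:
                continue
            length_bp = int(pos[tj] - pos[ti])
            if length_bp < 1_000_000 or not cls.contains_length(length_bp):
                continue
            segments.append(
                RohSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_bp=int(pos[ti]),
                    end_bp=int(pos[tj]),
                    n_snps=tj - ti + 1,
                    n_het=int(ph[tj + 1] - ph[ti]),
                    n_missing=int(pm[tj + 1] - pm[ti]),
                    class_name=cls.name,
                )
            )
    return segments


def _dedup_sample_chrom(segs: list[RohSegment]) -> list[RohSegment]:
    """Longest-wins deduplication: ties by homozygous SNP count, then leftmost."""
    order = sorted(segs, key=lambda s: (-s.length_bp, -s.n_hom, s.start_bp))
    kept: list[RohSegment] = []
    for s in order:
        if not any(s.overlaps(k) for k in kept):
            kept.append(s)
    kept.sort(key=lambda s: s.start_bp)
    return kept


def detect_roh(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    classes: list[LengthClass] | None = None,
    max_gap_bp: int = 1_000_000,
) -> list[RohSegment]:
    """Detect runs for every individual across all length classes.

    Each class is scanned independently (its allowances differ); the per-class
    detections are then deduplicated per individual and chromosome keeping the
    longest segment (ties: most homozygous SNPs, then leftmost) and dropping
    anything overlapping it, so no base pair is counted twice per individual.
    """
    classes = default_classes() if classes is None else classes
    validate_classes(classes)
    out: list[RohSegment] = []
    for i, sid in enumerate(gm.sample_ids):
        calls = gm.calls[i]
        per_chrom: dict = {}
        for cls in classes:
            for seg in scan_class(calls, marker_map, cls, max_gap_bp, sample_id=sid):
                per_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom in per_chrom:
            out.extend(_dedup_sample_chrom(per_chrom[chrom]))
    out.sort(key=lambda s: (s.sample_id, _chrom_key(s.chrom), s.start_bp))
    return out


def _chrom_key(c):
    return (0, c) if isinstance(c, (int, np.integer)) else (1, str(c))


def allowed_errors(expected_snps_in_class: float, error_rate: float = 0.002) -> int:
    """Tolerated spurious heterozygotes for a run of the given expected SNP
    count at the array genotyping error rate (round half up)."""
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")
    if expected_snps_in_class < 0:
        raise ValueError("expected SNP count must be non-negative")
    return int(math.floor(expected_snps_in_class * error_rate + 0.5))


def calibrate_allowances(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    classes: list[LengthClass] | None = None,
    error_rate: float = 0.002,
    max_gap_bp: int = 1_000_000,
) -> list[LengthClass]:
    """Re-derive per-class heterozygote allowances from a zero-het pilot scan.

    A pilot detection pass allowing no heterozygotes yields the typical SNP
    count of runs in each length class; the allowance is then the expected
    number of genotyping errors in a run of that size.  Missing-call
    allowances are left at their configured values.  A class with no pilot
    segments gets allowance 0 (warning logged).
    """
    classes = default_classes() if classes is None else classes
    validate_classes(classes)
    counts: dict[str, list[int]] = {c.name: [] for c in classes}
    for i, sid in enumerate(gm.sample_ids):
        for cls in classes:
            pilot = replace(cls, max_het=0)
            for seg in scan_class(gm.calls[i], marker_map, pilot, max_gap_bp, sample_id=sid):
                counts[cls.name].append(seg.n_snps)
    out = []
    for cls in classes:
        cnt = counts[cls.name]
        if not cnt:
            log.warning("no pilot segments in class %s; heterozygote allowance set to 0", cls.name)
            out.append(replace(cls, max_het=0))
        else:
            out.append(replace(cls, max_het=allowed_errors(float(np.mean(cnt)), error_rate)))
    return out


_SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start_bp", "end_bp",
    "n_snps", "n_het", "n_missing", "length_bp", "class",
]


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    rows = [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het,
         s.n_missing, s.length_bp, s.class_name)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_SEGMENT_COLUMNS)


def write_segments(segments: list[RohSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def _read_segments_tsv(path) -> list[RohSegment]:
    """Read a segment TSV written by :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t")
    return [
        RohSegment(
            sample_id=str(r["sample_id"]),
            chrom=int(r["chrom"]) if str(r["chrom"]).isdigit() else r["chrom"],
            start_bp=int(r["start_bp"]),
            end_bp=int(r["end_bp"]),
            n_snps=int(r["n_snps"]),
            n_het=int(r["n_het"]),
            n_missing=int(r["n_missing"]),
            class_name=str(r["class"]),
        )
        for r in df.to_dict("records")
    ]
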