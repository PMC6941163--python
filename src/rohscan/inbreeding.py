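"""Genomic inbreeding from runs of homozygosity (F_ROH).

F_ROH for an individual is the summed length of its ROH segments at or above
a length threshold, divided by the SNP-covered autosomal genome length.  The
default denominator, 2510.6 Mb, is the autosomal coverage of a filtered
bovine 54K array panel; it can be replaced by the coverage recomputed from
the marker map (``io.genome_coverage_mb``) — the choice is logged.

Thresholds follow the cumulative convention: F_ROH(>=4 Mb) sums every
segment at least 4 Mb long, so F_ROH is non-increasing in the threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .roh import RohSegment, segments_to_frame

log = logging.getLogger(__name__)

GENOME_LENGTH_MB = 2510.6  # SNP-covered bovine autosomes, 54K panel
DEFAULT_THRESHOLDS = (1, 2, 4, 8, 16)

__all__ = [
    "GENOME_LENGTH_MB",
    "DEFAULT_THRESHOLDS",
    "froh",
    "froh_table",
    "summarize_population",
    "summarize_froh",
]


def froh(
    segments: list[RohSegment],
    threshold_mb: float,
    genome_length_mb: float = GENOME_LENGTH_MB,
) -> float:
    """F_ROH of one individual: summed Mb of segments with length >= threshold,
    over the SNP-covered genome length.  ``segments`` must be that
    individual's deduplicated segments."""
    if threshold_mb < 0:
        raise ValueError("threshold_mb must be non-negative")
    if genome_length_mb <= 0:
        raise ValueError("genome_length_mb must be positive")
    total = sum(s.length_bp for s in segments if s.length_bp >= threshold_mb * 1e6)
    return (total / 1e6) / genome_length_mb


def _per_sample_totals(segments, sample_ids, thresholds):
    """Per-sample segment count and summed Mb at each cumulative threshold."""
    df = segments_to_frame(segments)
    unknown = set(df["sample_id"]) - set(sample_ids)
    if unknown:
        raise ValueError(f"segments reference unknown samples: {sorted(unknown)[:3]}")
    rows = []
    for sid in sample_ids:
        lens = df.loc[df["sample_id"] == sid, "length_bp"].to_numpy()
        for t in thresholds:
            sel = lens >= t * 1e6
            rows.append((sid, t, int(sel.sum()), float(lens[sel].sum() / 1e6)))
    return pd.DataFrame(rows, columns=["sample_id", "threshold_mb", "n_roh", "total_mb"])


def froh_table(
    segments: list[RohSegment],
    sample_ids: list[str],
    thresholds=DEFAULT_THRESHOLDS,
    genome_length_mb: float = GENOME_LENGTH_MB,
) -> pd.DataFrame:
    """Per-individual F_ROH at each cumulative threshold.

    Columns: sample_id, threshold_mb, total_roh_mb, froh.  Individuals with no
    segments contribute zeros.
    """
    log.info("F_ROH denominator: %.1f Mb", genome_length_mb)
    df = _per_sample_totals(segments, sample_ids, thresholds)
    df = df.rename(columns={"total_mb": "total_roh_mb"}).drop(columns="n_roh")
    df["froh"] = df["total_roh_mb"] / genome_length_mb
    return df


def _stats(values: np.ndarray) -> dict:
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return {
        "mean": float(np.mean(values)),
        "sd": sd,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def summarize_population(
    segments: list[RohSegment],
    sample_ids: list[str],
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Population summary of per-animal ROH count and summed length (Mb).

    One row per cumulative threshold and statistic kind, with mean / SD
    (n-1 denominator) / min / max across animals.  Animals with no ROH
    contribute zeros.
    """
    if not sample_ids:
        raise ValueError("empty sample list")
    totals = _per_sample_totals(segments, sample_ids, thresholds)
    rows = []
    for t in thresholds:
        sub = totals[totals["threshold_mb"] == t]
        for kind, col in (("n_roh", "n_roh"), ("total_mb", "total_mb")):
            s = _stats(sub[col].to_numpy(dtype=float))
            rows.append({"threshold_mb": t, "statistic": kind, **s})
    return pd.DataFrame(rows)


def summarize_froh(
    segments: list[RohSegment],
    sample_ids: list[str],
    thresholds=DEFAULT_THRESHOLDS,
    genome_length_mb: float = GENOME_LENGTH_MB,
) -> pd.DataFrame:
    """Mean/SD/min/max of per-individual F_ROH at each threshold (means of
    per-animal ratios)."""
    if not sample_ids:
        raise ValueError("empty sample list")
    ft = froh_table(segments, sample_ids, thresholds, genome_length_mb)
    rows = []
    for t in thresholds:
        vals = ft.loc[ft["threshold_mb"] == t, "froh"].to_numpy()
        rows.append({"threshold_mb": t, **_stats(vals)})
    return pd.DataFrame(rows)
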