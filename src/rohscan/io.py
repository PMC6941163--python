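"""Genotype panel I/O, validation and quality-control filtering.

Reads PLINK-style text PED/MAP files into the package's in-memory containers
(:class:`MarkerMap`, :class:`GenotypeMatrix`), applies the standard SNP-array
QC steps (sample call rate, per-marker GenCall/GenTrain scores, autosome
restriction) and computes the SNP-covered genome length used as the F_ROH
denominator.

Genotype calls are coded ``0`` = homozygous reference, ``1`` = heterozygous,
``2`` = homozygous alternate and ``-1`` = missing.  "Reference" is simply the
first allele observed in the file for a marker: downstream run-of-homozygosity
logic only distinguishes homozygous / heterozygous / missing, so allele
polarity is irrelevant and is documented as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
N_AUTOSOMES = 29  # bovine karyotype

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "read_map",
    "read_ped",
    "read_quality_table",
    "write_map",
    "write_ped",
    "filter_samples",
    "filter_markers",
    "genome_coverage_mb",
    "MISSING",
    "N_AUTOSOMES",
]


def _normalize_chrom(label):
    """Normalize a chromosome label: 'chr5'/'5' -> 5; 'X', contigs stay strings."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        return s


def _chrom_sort_key(c):
    # autosomes (ints) first in numeric order, then everything else lexically
    return (0, c, "") if isinstance(c, int) else (1, 0, str(c))


@dataclass
class MarkerMap:
    """Ordered marker positions — the coordinate backbone for ROH scanning.

    ``df`` has columns ``marker_id`` (str), ``chrom`` (int for autosomes,
    str otherwise) and ``pos_bp`` (1-based physical position).  Markers are
    sorted by (chromosome, position) and strictly increasing in position
    within each chromosome.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id {dup!r} in marker map")
        for chrom, grp in df.groupby("chrom", sort=False):
            d = np.diff(grp["pos_bp"].to_numpy())
            if len(d) and (d <= 0).any():
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_markers(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def is_autosome(self) -> np.ndarray:
        c = self.df["chrom"]
        return np.array(
            [isinstance(v, (int, np.integer)) and 1 <= v <= N_AUTOSOMES for v in c]
        )

    def chrom_slices(self) -> dict:
        """Mapping chromosome -> ``slice`` of its (contiguous) marker rows."""
        out = {}
        codes = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(codes) + 1):
            if i == len(codes) or codes[i] != codes[start]:
                out[codes[start]] = slice(start, i)
                start = i
        return out

    def positions(self, chrom) -> np.ndarray:
        sl = self.chrom_slices()[chrom]
        return self.df["pos_bp"].to_numpy()[sl]

    def subset(self, mask: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Individuals x markers call matrix aligned 1:1 to a :class:`MarkerMap`.

    ``calls`` is int8 with codes {0, 1, 2, -1}; ``alleles`` optionally records
    the two allele symbols per marker (for round-tripping PED files).
    """

    sample_ids: list
    calls: np.ndarray
    alleles: list | None = field(default=None, repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array (samples x markers)")
        if len(self.sample_ids) != self.calls.shape[0]:
            raise ValueError("sample_ids length does not match call matrix rows")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be coded 0/1/2/-1")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=1)

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return GenotypeMatrix(ids, self.calls[mask], self.alleles)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        alleles = None
        if self.alleles is not None:
            alleles = [a for a, m in zip(self.alleles, mask) if m]
        return GenotypeMatrix(list(self.sample_ids), self.calls[:, mask], alleles)


def read_map(path) -> MarkerMap:
    """Read a whitespace-delimited PLINK MAP file (chrom, id, cM, bp).

    Rows are sorted by (chromosome, position); if the file was unsorted a
    notice is logged.  Duplicate marker ids and non-numeric positions are
    hard errors.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            chrom, marker_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            try:
                pos_bp = int(pos)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric position {pos!r}"
                ) from None
            rows.append((_normalize_chrom(chrom), marker_id, pos_bp))
    if not rows:
        raise ValueError(f"{path}: empty marker map")
    df = pd.DataFrame(rows, columns=["chrom", "marker_id", "pos_bp"])
    df = df[["marker_id", "chrom", "pos_bp"]]
    order = sorted(range(len(df)), key=lambda i: (_chrom_sort_key(df["chrom"].iat[i]), df["pos_bp"].iat[i]))
    if order != list(range(len(df))):
        log.info("marker map %s was not sorted; sorted by (chrom, pos_bp)", path)
        df = df.iloc[order].reset_index(drop=True)
    return MarkerMap(df)


def read_ped(path, marker_map: MarkerMap) -> GenotypeMatrix:
    """Read a PLINK PED file against ``marker_map``.

    Six leading columns, then two allele columns per marker; allele "0" means
    missing.  Two equal alleles code homozygous (the first allele seen at a
    marker is taken as reference), unequal alleles code heterozygous.
    """
    m = len(marker_map)
    sample_ids = []
    rows = []
    first_allele = [None] * m
    second_allele = [None] * m
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} markers), got {len(parts)}"
                )
            sample_ids.append(parts[1])
            calls = np.empty(m, dtype=np.int8)
            al = parts[6:]
            for j in range(m):
                a, b = al[2 * j], al[2 * j + 1]
                if a == "0" or b == "0":
                    calls[j] = MISSING
                    continue
                for x in (a, b):
                    if first_allele[j] is None:
                        first_allele[j] = x
                    elif x != first_allele[j]:
                        if second_allele[j] is None:
                            second_allele[j] = x
                        elif x != second_allele[j]:
                            raise ValueError(
                                f"{path}: line {lineno}: marker "
                                f"{marker_map.df['marker_id'].iat[j]!r} has >2 alleles"
                            )
                if a == b:
                    calls[j] = 0 if a == first_allele[j] else 2
                else:
                    calls[j] = 1
            rows.append(calls)
    if not rows:
        raise ValueError(f"{path}: empty PED file")
    alleles = [
        (first_allele[j] or "A", second_allele[j] or "B") for j in range(m)
    ]
    return GenotypeMatrix(sample_ids, np.vstack(rows), alleles)


def read_quality_table(path) -> pd.DataFrame:
    """Read a 3-column TSV (marker_id, gencall, gentrain) with a header."""
    df = pd.read_csv(path, sep="\t")
    expected = {"marker_id", "gencall", "gentrain"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: quality table needs columns {sorted(expected)}")
    if df["marker_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate marker_id rows in quality table")
    return df


def write_map(marker_map: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        for row in marker_map.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker_id}\t0\t{row.pos_bp}\n")


def write_ped(gm: GenotypeMatrix, path) -> None:
    alleles = gm.alleles or [("A", "B")] * gm.n_markers
    with open(path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, c in enumerate(gm.calls[i]):
                a, b = alleles[j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a, a]
                elif c == 2:
                    fields += [b, b]
                else:
                    fields += [a, b]
            fh.write(" ".join(fields) + "\n")


def filter_samples(gm: GenotypeMatrix, min_call_rate: float = 0.95) -> GenotypeMatrix:
    """Drop samples whose call rate is not strictly above ``min_call_rate``.

    The comparison is strict ("more than 95% genotypes"): a sample at exactly
    the threshold is removed.  Removals are logged per sample.
    """
    if not (0 < min_call_rate <= 1):
        raise ValueError("min_call_rate must be in (0, 1]")
    rates = gm.call_rates()
    keep = rates > min_call_rate
    for sid, r in zip(gm.sample_ids, rates):
        if not r > min_call_rate:
            log.info("sample %s removed: call rate %.4f <= %.4f", sid, r, min_call_rate)
    if not keep.any():
        raise ValueError("all samples removed by call-rate filter")
    return gm.subset_samples(keep)


def filter_markers(
    gm: GenotypeMatrix,
    marker_map: MarkerMap,
    quality: pd.DataFrame | None = None,
    gencall_min: float = 0.7,
    gentrain_min: float = 0.4,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Remove markers failing quality thresholds or lying off the autosomes.

    GenCall/GenTrain thresholds are strict ("above 0.7", "above 0.4").  Sex
    chromosomes and contig-mapped markers (non-integer chromosome labels, or
    labels outside 1..29) are removed when ``autosomes_only`` is set.  Marker
    order is preserved.
    """
    keep = np.ones(len(marker_map), dtype=bool)
    if autosomes_only:
        keep &= marker_map.is_autosome
    if quality is not None:
        q = quality.set_index("marker_id")
        ids = marker_map.df["marker_id"]
        missing_q = set(ids) - set(q.index)
        if missing_q:
            raise ValueError(
                f"quality table does not cover {len(missing_q)} markers "
                f"(e.g. {sorted(missing_q)[:3]})"
            )
        gc = q.loc[ids, "gencall"].to_numpy(dtype=float)
        gt = q.loc[ids, "gentrain"].to_numpy(dtype=float)
        keep &= (gc > gencall_min) & (gt > gentrain_min)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("marker filter removed %d of %d markers", n_removed, len(marker_map))
    if not keep.any():
        raise ValueError("all markers removed by marker filter")
    return gm.subset_markers(keep), marker_map.subset(keep)


def genome_coverage_mb(marker_map: MarkerMap) -> float:
    """SNP-covered genome length: sum over chromosomes of (last − first) / 1e6.

    This is the denominator of F_ROH.  A chromosome carrying a single marker
    contributes 0 Mb (logged).
    """
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    total = 0.0
    for chrom in marker_map.chroms:
        pos = marker_map.positions(chrom)
        if len(pos) < 2:
            log.info("chromosome %s has a single marker; contributes 0 Mb", chrom)
            continue
        total += (pos[-1] - pos[0]) / 1e6
    return total
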