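"""Synthetic SNP-array panels with planted autozygous tracts.

Emulates a medium-density (~50K) bovine array: 29 autosomes with roughly
assembly-like spans, inter-marker spacing drawn from a normal distribution
(mean 55.4 kb, SD 44.4 kb, truncated at 1 bp), Hardy-Weinberg background
genotypes from per-marker allele frequencies, planted fully-homozygous
(autozygous) tracts with controlled lengths and population frequencies, a
hom-to-het genotyping error process (~0.2% by default — the error class that
breaks runs), and configurable missingness.  Machine-readable truth (tract
coordinates, corrupted-call coordinates, realized autozygous fraction) makes
every downstream stage testable without external data.

Autozygosity is modelled as forced homozygosity, not coalescent IBD: each
tract is a run of markers where the genotype is homozygous with the allele
drawn by its population frequency.  Tracts are marker-aligned (boundaries are
marker positions) and, by default, the single marker flanking each tract on
either side is forced heterozygous, so that true boundaries are identifiable
by a caller; see docs/methods.md for what this simplification does and does
not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MarkerMap, write_map, write_ped
from .roh import RohSegment

__all__ = [
    "BOVINE_CHROM_SPANS_MB",
    "TractSpec",
    "SimConfig",
    "SimTruth",
    "generate_map",
    "simulate_panel",
    "evaluate_recovery",
    "RecoveryMetrics",
    "write_panel",
]

# Approximate bovine autosome lengths (Mb), largest to smallest; sum ~2512 Mb.
BOVINE_CHROM_SPANS_MB = [
    158, 137, 121, 120, 121, 119, 110, 113, 105, 104,
    107, 91, 84, 84, 85, 81, 75, 66, 64, 72,
    71, 61, 52, 62, 43, 52, 45, 46, 51,
]


@dataclass(frozen=True)
class TractSpec:
    """One planted-tract design.

    ``frequency`` is the probability an individual carries the tract;
    ``length_bp`` is either a fixed length or a (low, high) uniform range;
    ``placement`` is ``"fixed"`` (one shared block, at ``chrom``/``start_bp``
    or a random location chosen once) or ``"random"`` (independent location
    per carrier); ``n_per_carrier`` tracts are planted per carrying
    individual.
    """

    frequency: float
    length_bp: float | tuple = 2_000_000
    placement: str = "random"
    chrom: int | None = None
    start_bp: int | None = None
    n_per_carrier: int = 1

    def __post_init__(self):
        if not (0 <= self.frequency <= 1):
            raise ValueError("tract frequency must be in [0, 1]")
        if self.placement not in ("random", "fixed"):
            raise ValueError("placement must be 'random' or 'fixed'")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic panel.

    Defaults emulate the filtered bovine 54K panel: 29 autosomes, mean
    spacing 55.4 kb (SD 44.4 kb), genotyping error rate 0.2% and a small
    residual missingness (0.5%) typical of a post-QC array panel.
    ``target_autozygosity``, when set, plants random non-overlapping tracts
    (lengths uniform in ``tract_length_bp``) in every individual until that
    fraction of the genome is covered.  ``seed`` is mandatory: all randomness
    flows from it through named child generators.
    """

    seed: int
    n_chrom: int = 29
    chrom_span_bp: list | None = None   # default: bovine-like spans
    mean_spacing_bp: float = 55_400.0
    sd_spacing_bp: float = 44_400.0
    n_snps_per_chrom: int | None = None  # fixed marker count instead of span fill
    n_individuals: int = 50
    allele_freq_range: tuple = (0.05, 0.95)
    tract_specs: list = field(default_factory=list)
    target_autozygosity: float | None = None
    tract_length_bp: tuple = (2_000_000, 8_000_000)
    error_rate: float = 0.002
    het_to_hom_rate: float = 0.0
    missing_rate: float = 0.005
    delimit_tracts: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.error_rate, self.het_to_hom_rate, self.missing_rate):
            if not (0 <= r <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.mean_spacing_bp <= 0:
            raise ValueError("mean spacing must be positive")
        if self.chrom_span_bp is None:
            spans = [int(mb * 1e6) for mb in BOVINE_CHROM_SPANS_MB]
            self.chrom_span_bp = (spans * (self.n_chrom // 29 + 1))[: self.n_chrom]
        elif np.isscalar(self.chrom_span_bp):
            self.chrom_span_bp = [int(self.chrom_span_bp)] * self.n_chrom
        if len(self.chrom_span_bp) != self.n_chrom:
            raise ValueError("chrom_span_bp length must equal n_chrom")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Ground truth for one simulated panel."""

    tracts: pd.DataFrame          # sample_id, chrom, start_bp, end_bp, n_snps
    genome_bp: int                # sum over chromosomes of (last − first) marker pos
    per_sample_fraction: pd.Series
    error_coords: list            # (sample_idx, marker_idx) hom→het flips
    missing_coords: list

    @property
    def realized_fraction(self) -> float:
        """Mean per-individual planted autozygous fraction."""
        return float(self.per_sample_fraction.mean())

    def write_tsv(self, path) -> None:
        df = self.tracts.copy()
        df["length_bp"] = df["end_bp"] - df["start_bp"]
        df.to_csv(path, sep="\t", index=False)


def generate_map(cfg: SimConfig) -> MarkerMap:
    """Draw a marker map: per chromosome, cumulative spacings from
    N(mean, sd) truncated at 1 bp, starting at position 1.  Deterministic
    under ``cfg.seed``."""
    rng = _rng(cfg.seed, 0)
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        span = cfg.chrom_span_bp[c - 1]
        pos = 1
        positions = [pos]
        if cfg.n_snps_per_chrom is not None:
            for _ in range(cfg.n_snps_per_chrom - 1):
                pos += _draw_spacing(rng, cfg)
                positions.append(pos)
            if positions[-1] > span:
                raise ValueError(
                    f"chromosome {c}: span {span} too small for "
                    f"{cfg.n_snps_per_chrom} markers"
                )
        else:
            while True:
                nxt = pos + _draw_spacing(rng, cfg)
                if nxt > span:
                    break
                positions.append(nxt)
                pos = nxt
        rows += [(f"c{c}_m{i + 1}", c, p) for i, p in enumerate(positions)]
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"]))


def _draw_spacing(rng, cfg) -> int:
    if cfg.sd_spacing_bp == 0:
        return int(round(cfg.mean_spacing_bp))
    return max(1, int(round(rng.normal(cfg.mean_spacing_bp, cfg.sd_spacing_bp))))


def _plant_tract(calls_row, tract_mask, sl, i0, i1, alt_freq, rng, cfg, taken):
    """Force markers i0..i1 (chromosome-local) homozygous; returns marker count."""
    lo, hi = sl.start + i0, sl.start + i1 + 1
    q = alt_freq[lo:hi]
    calls_row[lo:hi] = np.where(rng.random(hi - lo) < q, 2, 0)
    tract_mask[lo:hi] = True
    if cfg.delimit_tracts:
        for edge in (sl.start + i0 - 1, sl.start + i1 + 1):
            if sl.start <= edge < sl.stop and not tract_mask[edge]:
                calls_row[edge] = 1
    taken[lo:hi] = True
    return hi - lo


def simulate_panel(cfg: SimConfig, marker_map: MarkerMap) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate genotypes over ``marker_map`` with planted autozygous tracts.

    Background genotypes are Binomial(2, q) per marker under Hardy-Weinberg;
    tracts are planted (forced homozygous), then hom-to-het genotyping errors
    and missingness are applied.  Truth is recorded before corruption.
    """
    rng = _rng(cfg.seed, 1)
    n_markers = len(marker_map)
    slices = marker_map.chrom_slices()
    all_pos = marker_map.df["pos_bp"].to_numpy()
    genome_bp = int(sum(
        all_pos[sl][-1] - all_pos[sl][0] for sl in slices.values() if sl.stop - sl.start > 1
    ))

    lo_f, hi_f = cfg.allele_freq_range
    alt_freq = rng.uniform(lo_f, hi_f, n_markers)
    calls = rng.binomial(2, alt_freq, size=(cfg.n_individuals, n_markers)).astype(np.int8)

    sample_ids = [f"ind{i + 1:04d}" for i in range(cfg.n_individuals)]
    chrom_list = list(slices)
    chrom_weights = np.array(
        [max(all_pos[slices[c]][-1] - all_pos[slices[c]][0], 1) for c in chrom_list],
        dtype=float,
    )
    chrom_weights /= chrom_weights.sum()

    tract_rows = []

    def random_block(target_len, taken, max_tries=200):
        """A marker run covering >= target_len bp, avoiding taken markers."""
        for _ in range(max_tries):
            c = chrom_list[rng.choice(len(chrom_list), p=chrom_weights)]
            sl = slices[c]
            pos = all_pos[sl]
            n = len(pos)
            if n < 2:
                continue
            i0 = int(rng.integers(0, n))
            if pos[i0] + target_len > pos[-1]:
                continue
            i1 = int(np.searchsorted(pos, pos[i0] + target_len, side="left"))
            i1 = min(i1, n - 1)
            # 2-marker buffer keeps tracts separated by their het delimiters
            lo = max(sl.start, sl.start + i0 - 2)
            hi = min(sl.stop, sl.start + i1 + 3)
            if taken[lo:hi].any():
                continue
            return c, sl, i0, i1
        return None

    # fixed-block specs: choose each shared location once
    fixed_blocks = []
    global_taken = np.zeros(n_markers, dtype=bool)
    for spec in cfg.tract_specs:
        if spec.placement != "fixed":
            continue
        if spec.chrom is not None and spec.start_bp is not None:
            sl = slices[spec.chrom]
            pos = all_pos[sl]
            i0 = int(np.searchsorted(pos, spec.start_bp, side="left"))
            length = _spec_length(spec, rng)
            i1 = min(int(np.searchsorted(pos, pos[i0] + length, side="left")), len(pos) - 1)
            fixed_blocks.append((spec, spec.chrom, sl, i0, i1))
        else:
            blk = random_block(_spec_length(spec, rng), global_taken)
            if blk is None:
                raise ValueError("could not place fixed tract block")
            c, sl, i0, i1 = blk
            global_taken[sl.start + i0 : sl.start + i1 + 1] = True
            fixed_blocks.append((spec, c, sl, i0, i1))
        c, sl, i0, i1 = fixed_blocks[-1][1:]
        if all_pos[sl][i1] - all_pos[sl][i0] > (all_pos[sl][-1] - all_pos[sl][0]):
            raise ValueError("tract longer than its chromosome")

    per_sample_bp = np.zeros(cfg.n_individuals)
    for ind in range(cfg.n_individuals):
        taken = np.zeros(n_markers, dtype=bool)
        tract_mask = np.zeros(n_markers, dtype=bool)
        row = calls[ind]

        for spec, c, sl, i0, i1 in fixed_blocks:
            if rng.random() < spec.frequency:
                _plant_tract(row, tract_mask, sl, i0, i1, alt_freq, rng, cfg, taken)
                tract_rows.append((sample_ids[ind], c, int(all_pos[sl][i0]),
                                   int(all_pos[sl][i1]), i1 - i0 + 1))
                per_sample_bp[ind] += all_pos[sl][i1] - all_pos[sl][i0]

        for spec in cfg.tract_specs:
            if spec.placement != "random" or rng.random() >= spec.frequency:
                continue
            for _ in range(spec.n_per_carrier):
                blk = random_block(_spec_length(spec, rng), taken)
                if blk is None:
                    continue
                c, sl, i0, i1 = blk
                _plant_tract(row, tract_mask, sl, i0, i1, alt_freq, rng, cfg, taken)
                tract_rows.append((sample_ids[ind], c, int(all_pos[sl][i0]),
                                   int(all_pos[sl][i1]), i1 - i0 + 1))
                per_sample_bp[ind] += all_pos[sl][i1] - all_pos[sl][i0]

        if cfg.target_autozygosity:
            target_bp = cfg.target_autozygosity * genome_bp
            while per_sample_bp[ind] < target_bp:
                length = rng.uniform(*cfg.tract_length_bp)
                blk = random_block(length, taken)
                if blk is None:
                    break
                c, sl, i0, i1 = blk
                _plant_tract(row, tract_mask, sl, i0, i1, alt_freq, rng, cfg, taken)
                tract_rows.append((sample_ids[ind], c, int(all_pos[sl][i0]),
                                   int(all_pos[sl][i1]), i1 - i0 + 1))
                per_sample_bp[ind] += all_pos[sl][i1] - all_pos[sl][i0]

    tracts = pd.DataFrame(
        tract_rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps"]
    )

    # corruption: hom→het errors (the class that breaks runs), optional
    # het→hom errors, then missingness; truth recorded above
    error_coords = []
    if cfg.error_rate > 0:
        hom = (calls == 0) | (calls == 2)
        flip = hom & (rng.random(calls.shape) < cfg.error_rate)
        error_coords = list(zip(*np.nonzero(flip)))
        calls[flip] = 1
    if cfg.het_to_hom_rate > 0:
        het = calls == 1
        flip = het & (rng.random(calls.shape) < cfg.het_to_hom_rate)
        error_coords += list(zip(*np.nonzero(flip)))
        q = np.broadcast_to(alt_freq, calls.shape)
        calls[flip] = np.where(rng.random(calls.shape) < q, 2, 0)[flip]
    missing_coords = []
    if cfg.missing_rate > 0:
        drop = rng.random(calls.shape) < cfg.missing_rate
        missing_coords = list(zip(*np.nonzero(drop)))
        calls[drop] = MISSING

    alleles = [("A", "B")] * n_markers
    gm = GenotypeMatrix(sample_ids, calls, alleles)
    truth = SimTruth(
        tracts=tracts,
        genome_bp=genome_bp,
        per_sample_fraction=pd.Series(per_sample_bp / genome_bp, index=sample_ids),
        error_coords=error_coords,
        missing_coords=missing_coords,
    )
    return gm, truth


def _spec_length(spec: TractSpec, rng) -> float:
    if np.isscalar(spec.length_bp):
        return float(spec.length_bp)
    lo, hi = spec.length_bp
    return float(rng.uniform(lo, hi))


@dataclass
class RecoveryMetrics:
    """Detection quality of a segment call set against planted truth."""

    per_tract: pd.DataFrame   # detected flag, boundary errors, best overlap
    sensitivity: float
    precision: float
    froh_errors: pd.Series    # per-sample |detected − planted| fraction

    @property
    def exact_boundary_fraction(self) -> float:
        det = self.per_tract[self.per_tract["detected"]]
        if len(det) == 0:
            return 0.0
        return float(((det["start_err"] == 0) & (det["end_err"] == 0)).mean())


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def evaluate_recovery(
    truth: SimTruth,
    segments: list[RohSegment],
    min_reciprocal_overlap: float = 0.9,
) -> RecoveryMetrics:
    """Score called segments against planted tracts.

    A tract is detected when some segment of the same individual/chromosome
    achieves reciprocal overlap >= ``min_reciprocal_overlap``; precision is
    the fraction of called segments matching some tract the same way.
    """
    seg_by_sample: dict = {}
    for s in segments:
        seg_by_sample.setdefault((s.sample_id, s.chrom), []).append(s)

    rows = []
    matched_segs = set()
    for t in truth.tracts.itertuples(index=False):
        best, best_ov = None, 0.0
        for s in seg_by_sample.get((t.sample_id, t.chrom), []):
            ov = _reciprocal_overlap(t.start_bp, t.end_bp, s.start_bp, s.end_bp)
            if ov > best_ov:
                best, best_ov = s, ov
        detected = best_ov >= min_reciprocal_overlap
        if detected:
            matched_segs.add(id(best))
        rows.append({
            "sample_id": t.sample_id,
            "chrom": t.chrom,
            "start_bp": t.start_bp,
            "end_bp": t.end_bp,
            "detected": detected,
            "overlap": best_ov,
            "start_err": abs(best.start_bp - t.start_bp) if detected else np.nan,
            "end_err": abs(best.end_bp - t.end_bp) if detected else np.nan,
        })
    per_tract = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp",
                       "detected", "overlap", "start_err", "end_err"],
    )

    sensitivity = float(per_tract["detected"].mean()) if len(per_tract) else 1.0
    if segments:
        n_match = 0
        tr_by_sample: dict = {}
        for t in truth.tracts.itertuples(index=False):
            tr_by_sample.setdefault((t.sample_id, t.chrom), []).append(t)
        for s in segments:
            ok = any(
                _reciprocal_overlap(t.start_bp, t.end_bp, s.start_bp, s.end_bp)
                >= min_reciprocal_overlap
                for t in tr_by_sample.get((s.sample_id, s.chrom), [])
            )
            n_match += ok
        precision = n_match / len(segments)
    else:
        precision = 1.0

    detected_bp = pd.Series(0.0, index=truth.per_sample_fraction.index)
    for s in segments:
        if s.sample_id in detected_bp.index:
            detected_bp[s.sample_id] += s.length_bp
    froh_errors = (detected_bp / truth.genome_bp - truth.per_sample_fraction).abs()
    return RecoveryMetrics(per_tract, sensitivity, float(precision), froh_errors)


def write_panel(cfg: SimConfig, out_dir) -> tuple[GenotypeMatrix, MarkerMap, SimTruth]:
    """Simulate and write PED/MAP plus truth TSV into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    marker_map = generate_map(cfg)
    gm, truth = simulate_panel(cfg, marker_map)
    write_map(marker_map, os.path.join(out_dir, "panel.map"))
    write_ped(gm, os.path.join(out_dir, "panel.ped"))
    truth.write_tsv(os.path.join(out_dir, "truth.tsv"))
    with open(os.path.join(out_dir, "sim_config.txt"), "w") as fh:
        for k, v in asdict(cfg).items():
            fh.write(f"{k}\t{v}\n")
    return gm, marker_map, truth
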