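"""Model-style front end: ``RohAnalysis`` (data + settings) and ``RohResults``.

The underlying machinery lives in the functional modules (``io``, ``roh``,
``inbreeding``, ``islands``, ``annotation``); this wrapper presents the whole
analysis the way statistical modelling packages do — construct the analysis
object from data, call :meth:`RohAnalysis.fit`, and read estimates,
dispersions and a summary table off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inbreeding, islands as islands_mod, roh as roh_mod
from .annotation import load_genes, overlap_genes
from .io import (
    GenotypeMatrix,
    MarkerMap,
    filter_markers,
    filter_samples,
    genome_coverage_mb,
    read_map,
    read_ped,
)

__all__ = ["RohAnalysis", "RohResults"]


class RohAnalysis:
    """A runs-of-homozygosity analysis of one genotype panel.

    Parameters
    ----------
    genotypes, marker_map
        The panel (optionally pre-filtered with :func:`io.filter_samples` /
        :func:`io.filter_markers`, or via ``qc=True`` here).
    classes
        ROH length classes; defaults to the five-category bovine scheme.
    max_gap_bp
        Maximum distance between consecutive markers inside a run.
    genome_length_mb
        F_ROH denominator; ``None`` recomputes SNP coverage from the map.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        marker_map: MarkerMap,
        classes=None,
        max_gap_bp: int = 1_000_000,
        genome_length_mb: float | None = inbreeding.GENOME_LENGTH_MB,
    ):
        if genotypes.n_markers != len(marker_map):
            raise ValueError("genotype matrix not aligned to marker map")
        self.genotypes = genotypes
        self.marker_map = marker_map
        self.classes = roh_mod.default_classes() if classes is None else list(classes)
        self.max_gap_bp = max_gap_bp
        self.genome_length_mb = (
            genome_coverage_mb(marker_map) if genome_length_mb is None else genome_length_mb
        )

    @classmethod
    def from_plink(cls, ped_path, map_path, qc: bool = False, quality=None, **kwargs):
        """Build from PLINK PED/MAP text files; ``qc=True`` applies the
        standard sample-then-marker filters first."""
        marker_map = read_map(map_path)
        gm = read_ped(ped_path, marker_map)
        if qc:
            gm = filter_samples(gm)
            gm, marker_map = filter_markers(gm, marker_map, quality=quality)
        return cls(gm, marker_map, **kwargs)

    @classmethod
    def from_simulation(cls, cfg, **kwargs):
        """Build from a :class:`simulate.SimConfig`; the truth table is kept
        on the analysis object as ``.truth``."""
        from .simulate import generate_map, simulate_panel

        marker_map = generate_map(cfg)
        gm, truth = simulate_panel(cfg, marker_map)
        kwargs.setdefault("genome_length_mb", None)
        obj = cls(gm, marker_map, **kwargs)
        obj.truth = truth
        return obj

    def fit(self, calibrate_het_allowances: bool = False) -> "RohResults":
        """Run detection (optionally re-deriving per-class heterozygote
        allowances from a zero-het pilot scan) and return results."""
        classes = self.classes
        if calibrate_het_allowances:
            classes = roh_mod.calibrate_allowances(
                self.genotypes, self.marker_map, classes, max_gap_bp=self.max_gap_bp
            )
        segments = roh_mod.detect_roh(
            self.genotypes, self.marker_map, classes, self.max_gap_bp
        )
        return RohResults(self, classes, segments)


class RohResults:
    """Fitted ROH analysis: segments, F_ROH estimates and island machinery."""

    def __init__(self, model: RohAnalysis, classes, segments):
        self.model = model
        self.classes = classes
        self.segments = segments
        self.sample_ids = list(model.genotypes.sample_ids)

    # -- inbreeding ---------------------------------------------------------
    def froh(self, threshold_mb: float = 1) -> pd.Series:
        """Per-individual F_ROH at one cumulative length threshold."""
        by_sample: dict = {sid: [] for sid in self.sample_ids}
        for s in self.segments:
            by_sample[s.sample_id].append(s)
        return pd.Series(
            {
                sid: inbreeding.froh(segs, threshold_mb, self.model.genome_length_mb)
                for sid, segs in by_sample.items()
            },
            name=f"froh_{threshold_mb}mb",
        )

    def froh_table(self, thresholds=inbreeding.DEFAULT_THRESHOLDS) -> pd.DataFrame:
        return inbreeding.froh_table(
            self.segments, self.sample_ids, thresholds, self.model.genome_length_mb
        )

    def population_summary(self, thresholds=inbreeding.DEFAULT_THRESHOLDS) -> pd.DataFrame:
        return inbreeding.summarize_population(self.segments, self.sample_ids, thresholds)

    def froh_summary(self, thresholds=inbreeding.DEFAULT_THRESHOLDS) -> pd.DataFrame:
        return inbreeding.summarize_froh(
            self.segments, self.sample_ids, thresholds, self.model.genome_length_mb
        )

    # -- islands ------------------------------------------------------------
    def incidence(self) -> islands_mod.IncidenceTrack:
        return islands_mod.incidence(
            self.segments, self.model.marker_map, len(self.sample_ids)
        )

    def islands(self, top_fraction: float = 0.01, min_snps_island: int = 3):
        track = self.incidence()
        thr = islands_mod.threshold_top1(track, top_fraction)
        return islands_mod.call_islands(track, self.model.marker_map, thr, min_snps_island)

    def island_genes(self, annotation_path, fmt=None, **island_kwargs):
        genes = load_genes(annotation_path, fmt)
        return overlap_genes(self.islands(**island_kwargs), genes)

    # -- presentation -------------------------------------------------------
    def segments_frame(self) -> pd.DataFrame:
        return roh_mod.segments_to_frame(self.segments)

    def summary(self) -> str:
        """Text summary: panel dimensions, class settings, per-threshold
        F_ROH mean/SD and segment-count statistics."""
        lines = []
        w = lines.append
        w("Runs of homozygosity analysis")
        w("=" * 64)
        w(f"Individuals: {len(self.sample_ids)}    Markers: {self.model.genotypes.n_markers}")
        w(f"F_ROH denominator: {self.model.genome_length_mb:.1f} Mb")
        w(f"Max inter-marker gap: {self.model.max_gap_bp / 1e6:.1f} Mb")
        w("")
        w("Length classes (Mb)    max het   max missing   min hom SNPs")
        for c in self.classes:
            upper = "inf" if not np.isfinite(c.upper_mb) else f"{c.upper_mb:g}"
            bounds = f"[{c.lower_mb:g}, {upper})"
            w(f"  {c.name:<8} {bounds:<11}  {c.max_het:^7d}   "
              f"{c.max_missing:^11d}   {c.min_snps:^12d}")
        w("")
        w(f"Segments detected: {len(self.segments)}")
        w("")
        w("Threshold   F_ROH mean    SD        ROH/animal mean   Sum Mb mean")
        fs = self.froh_summary()
        ps = self.population_summary()
        for t in fs["threshold_mb"]:
            fr = fs[fs["threshold_mb"] == t].iloc[0]
            cn = ps[(ps["threshold_mb"] == t) & (ps["statistic"] == "n_roh")].iloc[0]
            lm = ps[(ps["threshold_mb"] == t) & (ps["statistic"] == "total_mb")].iloc[0]
            w(f"  >= {t:<4g}   {fr['mean']:.3f}       {fr['sd']:.3f}     "
              f"{cn['mean']:<15.1f}   {lm['mean']:.1f}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------
    def plot_incidence(self, ax=None):
        """ROH incidence frequency along the genome (marker index on x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        track = self.incidence()
        ax.plot(track.freq, lw=0.5)
        ax.set_xlabel("marker index (genome order)")
        ax.set_ylabel("fraction of individuals in ROH")
        return ax

    def plot_froh(self, threshold_mb: float = 1, ax=None):
        """Histogram of per-individual F_ROH at one threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.froh(threshold_mb).to_numpy(), bins=30)
        ax.set_xlabel(f"F_ROH (>= {threshold_mb:g} Mb)")
        ax.set_ylabel("individuals")
        return ax
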