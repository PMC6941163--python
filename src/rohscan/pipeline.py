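"""End-to-end pipeline: QC -> detection -> F_ROH -> islands -> annotation.

Driven by a flat YAML config with sections mirroring the module parameters;
unknown keys are rejected, and a fully-resolved copy of the config is written
next to the outputs so every run is self-describing.  Data outputs are TSV
with headers (islands additionally BED); the run log goes to a separate file
so the tables stay machine-parseable.
"""

from __future__ import annotations

import dataclasses
import logging
import os

import yaml

from . import __version__
from .annotation import load_genes, overlap_genes
from .inbreeding import GENOME_LENGTH_MB
from .io import filter_markers, filter_samples, read_map, read_ped, read_quality_table
from .islands import islands_to_frame, write_islands_bed
from .model import RohAnalysis
from .roh import LengthClass, default_classes

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the standard bovine-array values."""

    ped: str = ""
    map: str = ""
    quality_table: str | None = None
    annotation: str | None = None
    annotation_format: str | None = None
    out_dir: str = "rohscan_out"

    min_call_rate: float = 0.95
    gencall_min: float = 0.7
    gentrain_min: float = 0.4
    autosomes_only: bool = True

    min_snps: int = 30
    max_gap_bp: int = 1_000_000
    classes: list | None = None          # list of dicts or LengthClass
    calibrate_het_allowances: bool = False

    genome_mb: float | None = GENOME_LENGTH_MB  # None -> recompute from map
    thresholds: tuple = (1, 2, 4, 8, 16)

    top_fraction: float = 0.01
    min_snps_island: int = 3
    group: str = "population"

    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolved_classes(self) -> list[LengthClass]:
        if self.classes is None:
            base = default_classes()
        else:
            base = [
                c if isinstance(c, LengthClass) else LengthClass(**c)
                for c in self.classes
            ]
        return [dataclasses.replace(c, min_snps=self.min_snps) for c in base]

    def write_resolved(self, path) -> None:
        data = dataclasses.asdict(self)
        data["classes"] = [dataclasses.asdict(c) for c in self.resolved_classes()]
        data["rohscan_version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output paths.

    Any stage failure raises :class:`StageError` naming the stage, before any
    later output is written.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    handler = logging.FileHandler(out("run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("rohscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("rohscan %s", __version__)
        try:
            classes = config.resolved_classes()
            from .roh import validate_classes

            validate_classes(classes)
            config.write_resolved(out("resolved_config.yaml"))
        except Exception as exc:
            raise StageError("config", str(exc)) from exc

        try:
            marker_map = read_map(config.map)
            gm = read_ped(config.ped, marker_map)
            quality = (
                read_quality_table(config.quality_table) if config.quality_table else None
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("io", str(exc)) from exc

        try:
            gm = filter_samples(gm, config.min_call_rate)
            gm, marker_map = filter_markers(
                gm, marker_map, quality,
                config.gencall_min, config.gentrain_min, config.autosomes_only,
            )
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc

        try:
            model = RohAnalysis(
                gm, marker_map, classes, config.max_gap_bp, config.genome_mb
            )
            res = model.fit(calibrate_het_allowances=config.calibrate_het_allowances)
            res.segments_frame().to_csv(out("segments.tsv"), sep="\t", index=False)
        except Exception as exc:
            raise StageError("detect", str(exc)) from exc

        try:
            res.froh_table(config.thresholds).to_csv(out("froh.tsv"), sep="\t", index=False)
            summary = res.population_summary(config.thresholds)
            froh_sum = res.froh_summary(config.thresholds)
            summary.to_csv(out("summary.tsv"), sep="\t", index=False)
            froh_sum.to_csv(out("froh_summary.tsv"), sep="\t", index=False)
        except Exception as exc:
            raise StageError("froh", str(exc)) from exc

        try:
            islands = res.islands(config.top_fraction, config.min_snps_island)
            islands_to_frame(islands, config.group).to_csv(
                out("islands.tsv"), sep="\t", index=False
            )
            write_islands_bed(islands, out("islands.bed"), config.group)
        except Exception as exc:
            raise StageError("islands", str(exc)) from exc

        paths = {
            "segments": out("segments.tsv"),
            "froh": out("froh.tsv"),
            "summary": out("summary.tsv"),
            "froh_summary": out("froh_summary.tsv"),
            "islands": out("islands.tsv"),
            "islands_bed": out("islands.bed"),
            "config": out("resolved_config.yaml"),
            "log": out("run.log"),
        }

        if config.annotation:
            try:
                genes = load_genes(config.annotation, config.annotation_format)
                rows = []
                for isl, gene_ids in overlap_genes(islands, genes):
                    rows.append(
                        {
                            "chrom": isl.chrom,
                            "start_bp": isl.start_bp,
                            "end_bp": isl.end_bp,
                            "n_genes": len(gene_ids),
                            "genes": ",".join(gene_ids),
                        }
                    )
                import pandas as pd

                pd.DataFrame(
                    rows, columns=["chrom", "start_bp", "end_bp", "n_genes", "genes"]
                ).to_csv(out("gene_overlap.tsv"), sep="\t", index=False)
                paths["gene_overlap"] = out("gene_overlap.tsv")
            except Exception as exc:
                raise StageError("annotate", str(exc)) from exc

        log.info("pipeline complete: %d outputs", len(paths))
        return paths
    finally:
        root.removeHandler(handler)
        handler.close()
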