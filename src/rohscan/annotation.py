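"""Gene annotation overlap and multi-population shared-gene comparison.

Islands are intersected with gene intervals from a user-supplied BED or GFF3
annotation under an any-overlap (>= 1 bp) rule; gene sets per population can
then be compared for shared membership (pairwise and all-way intersections).

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on load.  A gene whose last base abuts an island's first base
therefore counts as overlapping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .io import _normalize_chrom
from .islands import Island

__all__ = ["GeneInterval", "GeneSetComparison", "load_genes", "overlap_genes", "shared_genes"]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: int
    start_bp: int  # 1-based inclusive
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_genes(path, fmt: str | None = None) -> list[GeneInterval]:
    """Load gene intervals from BED (>=4 columns) or GFF3 (``type == gene``).

    ``fmt`` is inferred from the file extension when omitted.  BED rows are
    converted from 0-based half-open to 1-based inclusive; GFF3 gene ids come
    from the ID (or Name) attribute.  Malformed rows are hard errors naming
    the line; a GFF3 file without gene rows is a hard error.
    """
    if fmt is None:
        s = str(path).lower()
        fmt = "GFF3" if s.endswith((".gff", ".gff3")) else "BED"
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unsupported annotation format {fmt!r}")
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "BED":
                    if len(fields) < 4:
                        raise ValueError("BED row needs >= 4 columns (chrom, start, end, name)")
                    chrom = _normalize_chrom(fields[0])
                    start0, end0 = int(fields[1]), int(fields[2])
                    genes.append(GeneInterval(fields[3], chrom, start0 + 1, end0))
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 row needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if gene_id is None:
                        raise ValueError("gene row lacks ID/Name attribute")
                    chrom = _normalize_chrom(fields[0])
                    genes.append(GeneInterval(gene_id, chrom, int(fields[3]), int(fields[4])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not genes:
        raise ValueError(f"{path}: no gene intervals found")
    seen = set()
    for g in genes:
        key = (g.gene_id, g.chrom, g.start_bp)
        if key in seen:
            raise ValueError(f"{path}: duplicate gene interval {key}")
        seen.add(key)
    genes.sort(key=lambda g: (str(g.chrom), g.start_bp))
    return genes


def overlap_genes(
    islands: list[Island],
    genes: list[GeneInterval],
) -> list[tuple[Island, list[str]]]:
    """Genes intersecting each island by >= 1 bp, in genomic order.

    Returns one (island, gene-id list) pair per input island, preserving
    island order.  Chromosome labels must match between inputs.
    """
    trees: dict = {}
    for g in genes:
        # IntervalTree is half-open; +1 makes the inclusive end queryable
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    out = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = sorted(tree[isl.start_bp : isl.end_bp + 1]) if tree is not None else []
        out.append((isl, [iv.data.gene_id for iv in hits]))
    return out


@dataclass
class GeneSetComparison:
    """Per-population gene sets with pairwise and all-way intersections."""

    gene_sets: dict
    pairwise: dict = field(init=False)
    all_way: frozenset = field(init=False)

    def __post_init__(self):
        pops = list(self.gene_sets)
        if len(pops) < 2:
            raise ValueError("need at least two populations")
        self.gene_sets = {p: frozenset(s) for p, s in self.gene_sets.items()}
        self.pairwise = {
            frozenset((a, b)): self.gene_sets[a] & self.gene_sets[b]
            for a, b in itertools.combinations(pops, 2)
        }
        self.all_way = frozenset(
            set.intersection(*(set(s) for s in self.gene_sets.values()))
        )

    def intersection(self, *pops) -> frozenset:
        return frozenset(set.intersection(*(set(self.gene_sets[p]) for p in pops)))

    def counts_matrix(self) -> pd.DataFrame:
        """Symmetric matrix of intersection cardinalities (diagonal: set sizes)."""
        pops = list(self.gene_sets)
        mat = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
        for p in pops:
            mat.loc[p, p] = len(self.gene_sets[p])
        for (a, b), inter in ((tuple(k), v) for k, v in self.pairwise.items()):
            mat.loc[a, b] = mat.loc[b, a] = len(inter)
        return mat


def shared_genes(gene_sets: dict) -> GeneSetComparison:
    """Compare per-population gene-id sets (>= 2 populations required)."""
    return GeneSetComparison(dict(gene_sets))
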