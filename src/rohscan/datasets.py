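"""Bundled reference datasets.

``load_cattle_island_catalog`` returns a published catalogue of ROH islands
from eleven cattle breeds kept in Poland (bovine 54K array, UMD3.1
coordinates), transcribed from the printed table: one row per region with the
breed code, chromosome, start/end coordinates, SNP count and printed region
length in kb.  A few rows print coordinates only at 10^8 scale; for those the
rounded coordinate is stored and the printed ``length_kb`` is authoritative.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cattle_island_catalog"]


def load_cattle_island_catalog() -> pd.DataFrame:
    """Columns: group, chrom, start_bp, end_bp, n_snps, length_kb."""
    with resources.files("rohscan.data").joinpath("cattle_islands_11breeds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
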