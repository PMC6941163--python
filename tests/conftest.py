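import numpy as np
import pandas as pd
import pytest

from rohscan.io import GenotypeMatrix, MarkerMap


def make_map(chrom_positions: dict) -> MarkerMap:
    """MarkerMap from {chrom: [positions]}; ids are generated."""
    rows = []
    for chrom, positions in chrom_positions.items():
        rows += [(f"c{chrom}_m{i}", chrom, int(p)) for i, p in enumerate(positions, 1)]
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp"]))


def make_gm(rows, sample_ids=None) -> GenotypeMatrix:
    """GenotypeMatrix from a list of per-sample call lists (codes 0/1/2/-1)."""
    calls = np.asarray(rows, dtype=np.int8)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(sample_ids, calls)


@pytest.fixture
def uniform_map():
    """One chromosome, 100 markers spaced 50 kb starting at 1."""
    return make_map({1: range(1, 100 * 50_000, 50_000)})


@pytest.fixture
def small_sim():
    """A small noiseless panel with planted tracts, shared across tests."""
    from rohscan.simulate import SimConfig, generate_map, simulate_panel

    cfg = SimConfig(
        seed=42, n_chrom=4, chrom_span_bp=[50_000_000] * 4, n_individuals=15,
        target_autozygosity=0.08, error_rate=0.0, missing_rate=0.0,
    )
    marker_map = generate_map(cfg)
    gm, truth = simulate_panel(cfg, marker_map)
    return cfg, marker_map, gm, truth
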