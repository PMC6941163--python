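"""Independent brute-force oracles used to validate the fast implementations.

The ROH oracle enumerates *every* marker window exhaustively with matrix
arithmetic (no two-pointer / bisection logic shared with the implementation)
and applies the run rules directly: gap, heterozygote and missing-call
constraints define candidate windows; maximality means no single-marker
extension keeps those constraints; windows are then trimmed to homozygous
endpoints, required to hold the minimum homozygous count, and filtered to the
class length bounds.
"""

import numpy as np

from rohscan.io import MISSING


def brute_force_scan(calls, marker_map, cls, max_gap_bp=1_000_000, sample_id=""):
    """Exhaustive-enumeration equivalent of ``roh.scan_class``.

    Returns a set of tuples (chrom, start_bp, end_bp, n_snps, n_het, n_missing).
    """
    out = set()
    calls = np.asarray(calls)
    all_pos = marker_map.df["pos_bp"].to_numpy()
    for chrom, sl in marker_map.chrom_slices().items():
        pos = all_pos[sl]
        c = calls[sl]
        n = len(pos)
        het = np.concatenate(([0], np.cumsum(c == 1)))
        mis = np.concatenate(([0], np.cumsum(c == MISSING)))
        hom = (c == 0) | (c == 2)
        homc = np.concatenate(([0], np.cumsum(hom)))
        # block id increments at every gap > max_gap_bp
        block = np.concatenate(([0], np.cumsum(np.diff(pos) > max_gap_bp)))

        i_idx = np.arange(n)[:, None]
        j_idx = np.arange(n)[None, :]
        n_het_w = het[j_idx + 1] - het[i_idx]
        n_mis_w = mis[j_idx + 1] - mis[i_idx]
        ok = (
            (j_idx >= i_idx)
            & (block[j_idx] == block[i_idx])
            & (n_het_w <= cls.max_het)
            & (n_mis_w <= cls.max_missing)
        )
        left_ext = np.zeros_like(ok)
        left_ext[1:, :] = ok[:-1, :]
        right_ext = np.zeros_like(ok)
        right_ext[:, :-1] = ok[:, 1:]
        maximal = ok & ~left_ext & ~right_ext

        hom_idx = np.nonzero(hom)[0]
        for i, j in zip(*np.nonzero(maximal)):
            inside = hom_idx[(hom_idx >= i) & (hom_idx <= j)]
            if len(inside) == 0:
                continue
            ti, tj = int(inside[0]), int(inside[-1])
            if homc[tj + 1] - homc[ti] < cls.min_snps:
                continue
            length = int(pos[tj] - pos[ti])
            if length < 1_000_000 or not (cls.lower_mb <= length / 1e6 < cls.upper_mb):
                continue
            out.add((
                chrom, int(pos[ti]), int(pos[tj]), tj - ti + 1,
                int(het[tj + 1] - het[ti]), int(mis[tj + 1] - mis[ti]),
            ))
    return out


def segments_as_tuples(segments):
    return {
        (s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het, s.n_missing)
        for s in segments
    }


def brute_force_incidence(segments, marker_map, n_individuals):
    """Per-marker membership by direct pairwise testing."""
    counts = np.zeros(len(marker_map), dtype=int)
    df = marker_map.df
    for k in range(len(df)):
        chrom, pos = df["chrom"].iat[k], df["pos_bp"].iat[k]
        seen = set()
        for s in segments:
            if (s.sample_id not in seen and s.chrom == chrom
                    and s.start_bp <= pos <= s.end_bp):
                counts[k] += 1
                seen.add(s.sample_id)
    return counts


def brute_force_overlap(islands, genes):
    """O(n*m) pairwise inclusive-interval intersection."""
    out = []
    for isl in islands:
        hits = [
            g.gene_id for g in genes
            if g.chrom == isl.chrom
            and g.start_bp <= isl.end_bp and g.end_bp >= isl.start_bp
        ]
        out.append(set(hits))
    return out
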