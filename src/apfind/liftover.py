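"""Project interval tracks across genomes through chain files.

An interval lifts iff the fraction of its bases covered by the chain's
alignment blocks reaches ``min_match`` (the liftOver -minMatch rule); lifted
coordinates span the first to last mapped base on the target. Because the
chains produced in this package are exact (built by construction, not by
alignment), base-level mappability equals sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Chain

TRACK_COLUMNS = ["chrom", "start", "end"]


@dataclass
class LiftConfig:
    """min_match: default 0.95 (liftOver default); 0.85 is the permissive
    setting used for chains onto incomplete de novo assemblies."""

    min_match: float = 0.95
    alt_min_match: float = 0.85

    def __post_init__(self):
        if not (0.0 < self.min_match <= 1.0):
            raise ValueError("min_match must be in (0, 1]")


def invert_chain(chain: Chain) -> Chain:
    """Swap source and target; an involution (invert(invert(c)) == c)."""
    b = chain.blocks
    return Chain(
        source_contig=chain.target_contig,
        target_contig=chain.source_contig,
        source_size=chain.target_size,
        target_size=chain.source_size,
        blocks=b[:, [2, 3, 0, 1]].copy(),
        chain_id=chain.chain_id,
    )


def compose_chains(chains_ab: list[Chain], chains_bc: list[Chain]) -> list[Chain]:
    """Compose chain sets A->B and B->C into A->C.

    Each A->B block's target interval is intersected with the B->C blocks;
    every intersection becomes an A->C block. Contigs are matched by the
    intermediate (B) contig name.
    """
    bc_by_contig: dict[str, list[Chain]] = {}
    for c in chains_bc:
        bc_by_contig.setdefault(c.source_contig, []).append(c)
    out: list[Chain] = []
    for ab in chains_ab:
        for bc in bc_by_contig.get(ab.target_contig, []):
            blocks = []
            for s0, s1, t0, _t1 in ab.blocks:
                for b0, b1, c0, _c1 in bc.blocks:
                    lo = max(t0, b0)
                    hi = min(t0 + (s1 - s0), b1)
                    if lo < hi:
                        blocks.append(
                            (
                                s0 + (lo - t0),
                                s0 + (hi - t0),
                                c0 + (lo - b0),
                                c0 + (hi - b0),
                            )
                        )
            if blocks:
                out.append(
                    Chain(
                        source_contig=ab.source_contig,
                        target_contig=bc.target_contig,
                        source_size=ab.source_size,
                        target_size=bc.target_size,
                        blocks=np.array(sorted(blocks), dtype=np.int64),
                    )
                )
    return out


def _project_arrays(
    chain: Chain, starts: np.ndarray, ends: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized projection of intervals through one chain.

    Returns (mapped_base_count, target_start, target_end); target fields are
    -1 where no base maps.
    """
    b = chain.blocks
    n = len(starts)
    if len(b) == 0:
        z = np.zeros(n, dtype=np.int64)
        return z, np.full(n, -1), np.full(n, -1)
    ss, se, ts = b[:, 0], b[:, 1], b[:, 2]
    sizes = se - ss
    cum = np.concatenate([[0], np.cumsum(sizes)])

    def coverage_upto(x):
        # mapped bases strictly before source position x
        i = np.searchsorted(ss, x, side="right") - 1
        base = cum[np.maximum(i, 0)]
        inside = np.clip(x - ss[np.maximum(i, 0)], 0, sizes[np.maximum(i, 0)])
        return np.where(i >= 0, base + inside, 0)

    mapped = coverage_upto(ends) - coverage_upto(starts)

    # first mapped base: first block ending after `start`
    i0 = np.searchsorted(se, starts, side="right")
    i0c = np.minimum(i0, len(b) - 1)
    t_start = ts[i0c] + np.maximum(starts - ss[i0c], 0)
    # last mapped base: last block starting before `end`
    i1 = np.searchsorted(ss, ends, side="left") - 1
    i1c = np.maximum(i1, 0)
    t_end = ts[i1c] + np.minimum(ends, se[i1c]) - ss[i1c]

    ok = mapped > 0
    return mapped, np.where(ok, t_start, -1), np.where(ok, t_end, -1)


def _lift_track(
    track: pd.DataFrame, chains: list[Chain], min_match: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    for col in TRACK_COLUMNS:
        if col not in track.columns:
            raise ValueError(f"track missing required column {col!r}")
    by_contig: dict[str, list[Chain]] = {}
    for c in chains:
        by_contig.setdefault(c.source_contig, []).append(c)

    n = len(track)
    out_chrom = np.empty(n, dtype=object)
    out_start = np.full(n, -1, dtype=np.int64)
    out_end = np.full(n, -1, dtype=np.int64)
    reason = np.empty(n, dtype=object)
    lifted_mask = np.zeros(n, dtype=bool)

    starts = track["start"].to_numpy(np.int64)
    ends = track["end"].to_numpy(np.int64)
    chroms = track["chrom"].to_numpy()

    for contig in pd.unique(chroms):
        sel = np.flatnonzero(chroms == contig)
        cands = by_contig.get(contig)
        if not cands:
            reason[sel] = "contig_absent_from_chain"
            continue
        # best single chain per interval (an interval spanning two chains is
        # unlifted rather than split)
        best_mapped = np.zeros(len(sel), dtype=np.int64)
        best_ts = np.full(len(sel), -1, dtype=np.int64)
        best_te = np.full(len(sel), -1, dtype=np.int64)
        best_tc = np.empty(len(sel), dtype=object)
        for ch in cands:
            m, t0, t1 = _project_arrays(ch, starts[sel], ends[sel])
            upd = m > best_mapped
            best_mapped[upd] = m[upd]
            best_ts[upd] = t0[upd]
            best_te[upd] = t1[upd]
            best_tc[upd] = ch.target_contig
        frac = best_mapped / (ends[sel] - starts[sel])
        ok = frac >= min_match
        lifted_mask[sel[ok]] = True
        out_chrom[sel[ok]] = best_tc[ok]
        out_start[sel[ok]] = best_ts[ok]
        out_end[sel[ok]] = best_te[ok]
        reason[sel[~ok]] = np.where(
            best_mapped[~ok] == 0, "no_mapped_bases", "below_min_match"
        )

    lifted = track.loc[lifted_mask].copy()
    lifted["chrom"] = out_chrom[lifted_mask]
    lifted["start"] = out_start[lifted_mask]
    lifted["end"] = out_end[lifted_mask]
    unlifted = track.loc[~lifted_mask].copy()
    unlifted["reason"] = reason[~lifted_mask]
    return lifted.reset_index(drop=True), unlifted.reset_index(drop=True)


def lift_intervals(
    track: pd.DataFrame, chains: list[Chain], config: LiftConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lift a BED-like track through a chain set.

    Returns ``(lifted, unlifted)``; every input interval appears in exactly
    one of the two, and the unlifted frame carries a ``reason`` column.
    Non-coordinate columns pass through unchanged.
    """
    config = config or LiftConfig()
    return _lift_track(track, chains, config.min_match)


def lift_reads(
    read_track: pd.DataFrame, chains: list[Chain], config: LiftConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lift per-read interval records; identifiers and strand pass through.

    Same minMatch rule as :func:`lift_intervals`.
    """
    return lift_intervals(read_track, chains, config)
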