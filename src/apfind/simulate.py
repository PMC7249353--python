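"""Synthetic study generator: reference, phased variants, enriched regions,
diploid reads, a toy gapless aligner, a toy Poisson window peak caller, and a
degraded-assembly mode emulating an incomplete de novo genome.

Every operation derives its randomness from ``(config.seed, op_tag)`` so the
whole study is bit-reproducible while operations stay independent of one
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _dna
from .liftover import LiftConfig, lift_intervals
from .types import Chain, GenomeSequence, PhasedVariant, TruthRegion

# rng stream tags, one per operation
_TAG_REF, _TAG_VAR, _TAG_REG, _TAG_READS, _TAG_DEGRADE = 11, 23, 37, 53, 71

_CONTENTS = ("none", "snv_only", "indel_only", "both")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a histone ChIP-seq experiment against a megabase-scale
    toy genome: short (36 bp) single-end reads, a background read-start
    density of 0.5 reads/bp (summed over both haplotypes), and enriched
    regions with summit-shaped (triangular) read pileups whose summit folds
    are log-uniform between ``fold_min`` and ``enrichment_fold`` — as in real
    data, peak strengths span the scale from the significance threshold
    upward, so a subset of regions sits near the caller's detection limit.
    """

    seed: int = 0
    contig_lengths: dict[str, int] = field(default_factory=lambda: {"chrS": 1_000_000})
    gc_content: float = 0.41  # human-like
    n_snv: int = 1750
    n_indel: int = 250
    indel_size_range: tuple[int, int] = (1, 50)
    indel_size_mean: float = 4.0  # geometric size law, truncated to the range
    n_enriched: int = 200
    enriched_quotas: dict[str, int] | None = None  # default: even split
    enriched_width_mean: int = 500
    enrichment_fold: float = 10.0
    fold_min: float = 2.0  # weakest summit fold; folds are log-uniform up to enrichment_fold
    background_depth: float = 0.5  # read starts per bp, both haplotypes combined
    read_length: int = 36
    error_rate: float = 0.01  # uniform per-base substitution error
    dropout_fraction: float = 0.0
    dropout_segment_mean: int = 2000

    def __post_init__(self):
        if any(n < 0 for n in (self.n_snv, self.n_indel, self.n_enriched)):
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi <= 50):
            raise ValueError("indel_size_range must lie within [1, 50]")
        for name, length in self.contig_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length contig {name!r}")

    def quotas(self) -> dict[str, int]:
        if self.enriched_quotas is not None:
            q = dict(self.enriched_quotas)
            if set(q) - set(_CONTENTS):
                raise ValueError(f"unknown quota categories: {set(q) - set(_CONTENTS)}")
            return {c: q.get(c, 0) for c in _CONTENTS}
        base, rem = divmod(self.n_enriched, 4)
        q = {c: base for c in _CONTENTS}
        q["none"] += rem
        return q


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def gen_reference(config: SimConfig) -> GenomeSequence:
    """I.i.d. toy reference at the configured GC content."""
    rng = _rng(config, _TAG_REF)
    contigs = {
        name: _dna.random_sequence(length, config.gc_content, rng)
        for name, length in config.contig_lengths.items()
    }
    return GenomeSequence(contigs)


def _place_positions(
    rng: np.random.Generator, contig_len: int, footprints: list[int], occupied: list[tuple[int, int]]
) -> list[int]:
    """Place variant footprints of the given sizes without overlap."""
    out: list[int] = []
    occ = sorted(occupied)
    starts = np.array([s for s, _ in occ], dtype=np.int64)
    ends = np.array([e for _, e in occ], dtype=np.int64)

    def collides(s: int, e: int) -> bool:
        i = np.searchsorted(starts, e, side="left")
        return i > 0 and ends[i - 1] > s

    for fp in footprints:
        placed = False
        for _ in range(200):
            s = int(rng.integers(1, contig_len - fp))  # keep pos >= 2 so indels have anchors
            e = s + fp
            if not collides(s, e):
                i = int(np.searchsorted(starts, s))
                starts = np.insert(starts, i, s)
                ends = np.insert(ends, i, e)
                out.append(s)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"genome too small for requested variant density: could not place a "
                f"{fp} bp footprint on a {contig_len} bp contig"
            )
    return out


def gen_variants(genome: GenomeSequence, config: SimConfig) -> list[PhasedVariant]:
    """Phased SNVs and indels at uniform positions with non-overlapping
    reference footprints; phases drawn uniformly from hap1/hap2/both."""
    rng = _rng(config, _TAG_VAR)
    lengths = genome.lengths()
    contigs = list(lengths)
    weights = np.array([lengths[c] for c in contigs], dtype=float)
    weights /= weights.sum()

    variants: list[PhasedVariant] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    # assign each variant to a contig proportionally to its length
    n_total = config.n_snv + config.n_indel
    if n_total == 0:
        return []
    which_contig = rng.choice(len(contigs), size=n_total, p=weights)
    is_indel = np.zeros(n_total, dtype=bool)
    is_indel[config.n_snv :] = True
    lo, hi = config.indel_size_range
    # indel sizes follow a truncated geometric law (real call sets are
    # dominated by 1-5 bp events, with a tail out to tens of bp)
    p_geom = min(1.0, 1.0 / config.indel_size_mean)
    sizes = np.clip(rng.geometric(p_geom, size=n_total), lo, hi)
    is_del = rng.random(n_total) < 0.5
    phases = rng.choice(["hap1", "hap2", "both"], size=n_total)

    for ci, contig in enumerate(contigs):
        seq = genome[contig]
        idx = np.flatnonzero(which_contig == ci)
        fps = [
            int(sizes[i] + 1) if (is_indel[i] and is_del[i]) else 1 for i in idx
        ]
        starts = _place_positions(rng, lengths[contig], fps, occupied[contig])
        for i, s in zip(idx, starts):
            if not is_indel[i]:
                ref = seq[s]
                alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
            elif is_del[i]:
                ref = seq[s : s + int(sizes[i]) + 1]
                alt = ref[0]
            else:  # insertion
                ref = seq[s]
                ins = _dna.decode(rng.integers(0, 4, size=int(sizes[i])).astype(np.uint8))
                alt = ref + ins
            variants.append(
                PhasedVariant(
                    contig=contig,
                    pos=s + 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    phase=str(phases[i]),
                )
            )
    variants.sort(key=lambda v: (v.contig, v.pos))
    return variants


def _variant_positions(variants: list[PhasedVariant], contig: str):
    snv_s, snv_e, ind_s, ind_e = [], [], [], []
    for v in variants:
        if v.contig != contig:
            continue
        s, e = v.footprint
        if v.vtype == "SNV":
            snv_s.append(s)
            snv_e.append(e)
        else:
            ind_s.append(s)
            ind_e.append(e)
    return (
        np.array(snv_s, dtype=np.int64),
        np.array(snv_e, dtype=np.int64),
        np.array(ind_s, dtype=np.int64),
        np.array(ind_e, dtype=np.int64),
    )


def _count_in(s: int, e: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Number of intervals overlapping [s, e) by >= 1 bp."""
    if len(starts) == 0:
        return 0
    return int(np.sum((starts < e) & (ends > s)))


def gen_enriched_regions(
    genome: GenomeSequence, variants: list[PhasedVariant], config: SimConfig
) -> list[TruthRegion]:
    """Non-overlapping enriched regions with controlled variant content.

    Quotas default to an even split of ``n_enriched`` over the four content
    categories (none / snv_only / indel_only / both); regions in variant
    categories are anchored on an actual variant and every emitted label is
    re-verified against the variant list. Per-region summit folds are drawn
    log-uniformly between ``fold_min`` and ``enrichment_fold``.
    """
    rng = _rng(config, _TAG_REG)
    quotas = config.quotas()
    min_gap = 4 * config.read_length

    regions: list[TruthRegion] = []
    occ: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def region_free(contig: str, s: int, e: int) -> bool:
        starts, ends = occ.get(contig, (np.empty(0, np.int64), np.empty(0, np.int64)))
        return _count_in(s - min_gap, e + min_gap, starts, ends) == 0

    def add_region(contig, s, e, content):
        starts, ends = occ.get(contig, (np.empty(0, np.int64), np.empty(0, np.int64)))
        occ[contig] = (np.append(starts, s), np.append(ends, e))
        lo = min(config.fold_min, config.enrichment_fold)
        fold = float(np.exp(rng.uniform(np.log(lo), np.log(config.enrichment_fold))))
        regions.append(TruthRegion(contig, int(s), int(e), content, fold))

    lengths = genome.lengths()
    contigs = list(lengths)
    weights = np.array([lengths[c] for c in contigs], dtype=float)
    weights /= weights.sum()
    varpos = {c: _variant_positions(variants, c) for c in contigs}

    def sample_width() -> int:
        w = rng.normal(config.enriched_width_mean, config.enriched_width_mean / 4)
        return int(max(3 * config.read_length, w))

    for content, quota in quotas.items():
        if quota == 0:
            continue
        anchor_type = {
            "none": None,
            "snv_only": "snv",
            "indel_only": "indel",
            "both": "indel",
        }[content]
        pool: list[tuple[str, int]] = []
        if anchor_type is not None:
            for contig in contigs:
                ss, _, ds, _ = varpos[contig]
                arr = ss if anchor_type == "snv" else ds
                pool.extend((contig, int(p)) for p in arr)
            if not pool:
                raise ValueError(
                    f"infeasible quota: no {anchor_type} variants available "
                    f"for category {content!r}"
                )
        for _ in range(quota):
            placed = False
            for _try in range(2000):
                width = sample_width()
                if anchor_type is None:
                    ci = int(rng.choice(len(contigs), p=weights))
                    contig = contigs[ci]
                    if lengths[contig] <= width + 2:
                        continue
                    s = int(rng.integers(0, lengths[contig] - width))
                else:
                    # anchor on a random variant of the needed type, placed
                    # near the region summit (read pileups are summit-shaped,
                    # so only summit-proximal variants can influence the call)
                    contig, apos = pool[int(rng.integers(0, len(pool)))]
                    jitter = int(rng.integers(-width // 8, width // 8 + 1))
                    s = int(apos - width // 2 + jitter)
                    s = max(0, min(s, lengths[contig] - width))
                e = s + width
                snv_s, snv_e, ind_s, ind_e = varpos[contig]
                n_snv = _count_in(s, e, snv_s, snv_e)
                n_ind = _count_in(s, e, ind_s, ind_e)
                want = {
                    "none": n_snv == 0 and n_ind == 0,
                    "snv_only": n_snv > 0 and n_ind == 0,
                    "indel_only": n_snv == 0 and n_ind > 0,
                    "both": n_snv > 0 and n_ind > 0,
                }[content]
                if want and region_free(contig, s, e):
                    add_region(contig, s, e, content)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"infeasible quota: could not place a {content!r} region "
                    f"after 2000 attempts"
                )
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions


def regions_to_track(regions: list[TruthRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.contig for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [f"region_{i}_{r.variant_content}" for i, r in enumerate(regions)],
            "variant_content": [r.variant_content for r in regions],
            "fold": [r.fold for r in regions],
        }
    )


def _lift_regions(
    regions: list[TruthRegion], chains: list[Chain] | None
) -> list[tuple[str, int, int, float]]:
    """Truth regions in one haplotype's frame (reference frame if no chain)."""
    if chains is None:
        return [(r.contig, r.start, r.end, r.fold) for r in regions]
    track = regions_to_track(regions)
    lifted, _ = lift_intervals(track, chains, LiftConfig(min_match=0.5))
    return list(
        zip(
            lifted["chrom"],
            lifted["start"].astype(int),
            lifted["end"].astype(int),
            lifted["fold"],
        )
    )


def simulate_reads(
    hap1: GenomeSequence,
    hap2: GenomeSequence,
    regions: list[TruthRegion],
    config: SimConfig,
    chain1: list[Chain] | None = None,
    chain2: list[Chain] | None = None,
) -> pd.DataFrame:
    """Single-end reads from both haplotypes with equal probability, with
    uniform per-base substitution errors at ``config.error_rate``.

    Read-start density is ``background_depth`` outside enriched regions and
    rises linearly to ``background_depth x fold`` at each region's midpoint
    (a triangular, summit-shaped pileup; fold per region), split evenly
    between the haplotypes. ``regions`` are in reference coordinates; pass
    the forge chains to place them on each haplotype (identity assumed when
    omitted).

    Returns a frame with columns name/seq/strand plus the hidden truth columns
    true_hap/true_contig/true_start used only by tests.
    """
    rng = _rng(config, _TAG_READS)
    L = config.read_length
    recs: list[pd.DataFrame] = []
    for hap_name, hap, chains in (("hap1", hap1, chain1), ("hap2", hap2, chain2)):
        if min(hap.lengths().values()) < L:
            raise ValueError("read_length exceeds shortest contig")
        hap_regions = _lift_regions(regions, chains)
        for contig, seq in hap.contigs.items():
            G = len(seq)
            rate = np.full(G, config.background_depth / 2.0)
            for rc, rs, re_, fold in hap_regions:
                if rc == contig:
                    # summit-shaped pileup: triangular enrichment peaking at
                    # `fold` over the region midpoint, background at the edges
                    x = np.arange(rs, re_)
                    center = (rs + re_) / 2.0
                    half = max((re_ - rs) / 2.0, 1.0)
                    tri = 1.0 - np.abs(x - center) / half
                    rate[rs:re_] *= 1.0 + (fold - 1.0) * tri
            # Poisson read starts per bp, then expand to positions
            counts = rng.poisson(rate)
            starts = np.repeat(np.arange(G, dtype=np.int64), counts)
            starts = starts[starts <= G - L]
            if len(starts) == 0:
                continue
            strands = np.where(rng.random(len(starts)) < 0.5, "+", "-")
            codes = _dna.encode(seq)
            mat = codes[starts[:, None] + np.arange(L)]
            if config.error_rate > 0:
                # uniform substitution errors: shift the base by 1-3 mod 4
                err = rng.random(mat.shape) < config.error_rate
                shift = rng.integers(1, 4, size=int(err.sum()))
                mat[err] = (mat[err] + shift) % 4
            flat = _dna.decode(mat.ravel())
            seqs = [flat[i * L : (i + 1) * L] for i in range(len(starts))]
            recs.append(
                pd.DataFrame(
                    {
                        "name": [f"{hap_name}_{contig}_{i}" for i in range(len(starts))],
                        "seq": seqs,
                        "strand": strands,
                        "true_hap": hap_name,
                        "true_contig": contig,
                        "true_start": starts,
                    }
                )
            )
    if not recs:
        return pd.DataFrame(
            columns=["name", "seq", "strand", "true_hap", "true_contig", "true_start"]
        )
    return pd.concat(recs, ignore_index=True)


def toy_align(
    reads: pd.DataFrame, genome: GenomeSequence, max_mismatches: int = 0
) -> pd.DataFrame:
    """Gapless exact-seed aligner with duplicate collapsing.

    Each read is reported at its best-scoring (fewest-mismatch) gapless
    position if that position has <= ``max_mismatches`` mismatches, ties
    broken by leftmost coordinate; otherwise the read is unmapped. Reads
    overlapping an indel relative to ``genome`` therefore go unmapped — the
    mechanism that produces rescued reads on the matching haplotype.
    Duplicate placements (same contig, start, end, strand) collapse to one
    record, as coordinate-duplicate marking would do. Output is a BED6-style
    frame (chrom, start, end, name, score=mismatch count, strand), one row
    per retained read, position-sorted.
    """
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    if len(reads) == 0:
        return pd.DataFrame(columns=cols)
    L = len(reads["seq"].iloc[0])
    if (reads["seq"].str.len() != L).any():
        raise ValueError("toy_align requires fixed-length reads")
    k = max(1, L // (max_mismatches + 1))
    n_seeds = min(max_mismatches + 1, L // k)

    # concatenated genome with N spacers so seeds cannot cross contigs
    names = list(genome.contigs)
    offsets: dict[str, int] = {}
    parts = []
    pos = 0
    for nm in names:
        offsets[nm] = pos
        parts.append(_dna.encode(genome[nm]))
        pos += len(genome[nm])
        parts.append(np.full(L, 4, dtype=np.uint8))  # spacer
        pos += L
    g = np.concatenate(parts)
    G = len(g)
    bounds = np.array([offsets[nm] for nm in names], dtype=np.int64)
    ends_ = bounds + np.array([len(genome[nm]) for nm in names], dtype=np.int64)

    # k-mer codes over the genome (base-5 to keep N distinct)
    powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    n_kmers = G - k + 1
    gcodes = np.zeros(n_kmers, dtype=np.int64)
    g64 = g.astype(np.int64)
    for j in range(k):
        gcodes += g64[j : j + n_kmers] * powers[j]
    order = np.argsort(gcodes, kind="stable")
    sorted_codes = gcodes[order]

    rmat = np.vstack([_dna.encode(s) for s in reads["seq"]])
    n = len(rmat)

    cand_read: list[np.ndarray] = []
    cand_pos: list[np.ndarray] = []
    r64 = rmat.astype(np.int64)
    for si in range(n_seeds):
        off = si * k
        codes = r64[:, off : off + k] @ powers
        lo = np.searchsorted(sorted_codes, codes, side="left")
        hi = np.searchsorted(sorted_codes, codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        ridx = np.repeat(np.arange(n), counts)
        base = np.repeat(lo, counts)
        within = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(counts[:-1])]), counts
        )
        flat = order[base + within]
        cand_read.append(ridx)
        cand_pos.append(flat - off)

    if not cand_read:
        return pd.DataFrame(columns=cols)
    ridx = np.concatenate(cand_read)
    cpos = np.concatenate(cand_pos)
    keep = (cpos >= 0) & (cpos + L <= G)
    ridx, cpos = ridx[keep], cpos[keep]
    # drop duplicates (same read, same candidate position from several seeds)
    key = ridx * np.int64(G) + cpos
    _, uniq = np.unique(key, return_index=True)
    ridx, cpos = ridx[uniq], cpos[uniq]

    # mismatch counting, chunked to bound memory
    mism = np.empty(len(ridx), dtype=np.int32)
    step = max(1, 4_000_000 // max(L, 1))
    ar = np.arange(L)
    for a in range(0, len(ridx), step):
        b = min(a + step, len(ridx))
        seg = g[cpos[a:b, None] + ar]
        mism[a:b] = (seg != rmat[ridx[a:b]]).sum(axis=1)
    ok = mism <= max_mismatches
    ridx, cpos, mism = ridx[ok], cpos[ok], mism[ok]
    if len(ridx) == 0:
        return pd.DataFrame(columns=cols)

    # best hit per read: fewest mismatches, then leftmost
    orderh = np.lexsort((cpos, mism, ridx))
    ridx, cpos, mism = ridx[orderh], cpos[orderh], mism[orderh]
    first = np.concatenate([[True], ridx[1:] != ridx[:-1]])
    ridx, cpos, mism = ridx[first], cpos[first], mism[first]

    ci = np.searchsorted(ends_, cpos, side="right")
    ci = np.minimum(ci, len(names) - 1)
    # a hit must lie entirely inside one contig (spacers are all-N and cannot
    # match within the mismatch budget when budget < spacer overlap, but an
    # explicit check keeps large budgets safe)
    inside = (cpos >= bounds[ci]) & (cpos + L <= ends_[ci])
    ridx, cpos, mism, ci = ridx[inside], cpos[inside], mism[inside], ci[inside]

    out = pd.DataFrame(
        {
            "chrom": np.array(names, dtype=object)[ci],
            "start": cpos - bounds[ci],
            "end": cpos - bounds[ci] + L,
            "name": reads["name"].to_numpy()[ridx],
            "score": mism,
            "strand": reads["strand"].to_numpy()[ridx],
        }
    )
    out = out.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def toy_peak_call(
    read_track: pd.DataFrame,
    genome_size: int | dict[str, int],
    fdr: float = 0.05,
    window: int | None = None,
    read_length: int | None = None,
    step: int | None = None,
    background_total: int | None = None,
) -> pd.DataFrame:
    """Poisson sliding-window peak caller (MACS2 stand-in).

    Fixed-width windows (default 2 x read length, a fragment-length surrogate
    for --nomodel) slide base by base (``step`` = 1) and are scored by the
    count of reads overlapping the window against a Poisson expectation that
    is the larger of the global rate
    lambda = total_reads x (window + read_length) / (0.8 x genome_size) —
    the 80% factor mirrors setting the effective genome size to 80% of the
    assembly and makes the background rate conservative — and a 10 kb local
    rate, as MACS2 floors its local lambda with the genome-wide one. The
    single-base step makes the window-count profile invariant under
    coordinate shifts, which matters when the same reads are called in two
    coordinate systems offset by indels (a coarser grid would flip
    threshold-level calls on grid phase alone). Upper-tail p-values are
    converted to q-values by Benjamini-Hochberg; windows with q <= fdr are
    merged when overlapping or adjacent. Output is
    narrowPeak-like: chrom, start, end, name, score (round(10 x -log10 q)),
    strand, signal (fold over lambda), neg_log10_p, neg_log10_q.
    """
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "signal", "neg_log10_p", "neg_log10_q",
    ]
    if len(read_track) == 0:
        return pd.DataFrame(columns=cols)
    if read_length is None:
        read_length = int((read_track["end"] - read_track["start"]).median())
    if window is None:
        window = 2 * read_length
    if step is None:
        step = 1
    sizes = (
        {c: int(genome_size) for c in read_track["chrom"].unique()}
        if isinstance(genome_size, (int, np.integer))
        else dict(genome_size)
    )
    total_genome = sum(sizes.values())
    # background_total lets a paired analysis (one library, two assemblies)
    # hold the global rate fixed across both calls, so that altered calls
    # reflect local read redistribution rather than small global
    # mapping-rate differences
    total_reads = background_total if background_total is not None else len(read_track)
    # a read overlaps a window iff its start falls in the (window + L - 1)
    # span left-extended by one read length
    span = window + read_length - 1
    lam = total_reads * span / (0.8 * total_genome)
    local_span = 10_000  # MACS2-style local background window

    per_contig = []
    pvals = []
    for contig, sub in read_track.groupby("chrom", sort=True):
        G = sizes[contig]
        n_win = max(1, -(-G // step))
        cum = np.concatenate(
            [[0], np.cumsum(np.bincount(sub["start"].to_numpy(np.int64), minlength=G))]
        )
        w_start = np.arange(n_win, dtype=np.int64) * step
        w_end = np.minimum(w_start + window, G)
        counts = cum[w_end] - cum[np.maximum(w_start - (read_length - 1), 0)]
        # local background: read rate in a 10 kb span around each window,
        # floored by the global rate (as MACS2 takes the max of its lambdas);
        # the local term makes per-window expectations continuous-valued
        mid = (w_start + w_end) // 2
        lo = np.clip(mid - local_span // 2, 0, G)
        hi = np.clip(mid + local_span // 2, 0, G)
        lam_local = (cum[hi] - cum[lo]) * (span / np.maximum(hi - lo, 1))
        lam_w = np.maximum(lam, lam_local)
        p = stats.poisson.sf(counts - 1, lam_w)
        per_contig.append((contig, G, w_start, w_end, counts, p))
        pvals.append(p)
    p_all = np.concatenate(pvals)
    m = len(p_all)
    # Benjamini-Hochberg
    ord_ = np.argsort(p_all, kind="stable")
    q_sorted = p_all[ord_] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_all = np.empty(m)
    q_all[ord_] = np.clip(q_sorted, 0, 1)

    rows = []
    offset = 0
    peak_i = 0
    for contig, G, w_start, w_end, counts, p in per_contig:
        n_win = len(counts)
        q = q_all[offset : offset + n_win]
        offset += n_win
        sig = np.flatnonzero(q <= fdr)
        if len(sig) == 0:
            continue
        # merge overlapping/adjacent significant windows: a gap in the window
        # index larger than window/step breaks the run
        max_gap = -(-window // step)
        breaks = np.flatnonzero(np.diff(sig) > max_gap)
        starts_run = np.concatenate([[0], breaks + 1])
        ends_run = np.concatenate([breaks, [len(sig) - 1]])
        for a, b in zip(starts_run, ends_run):
            best = sig[a : b + 1]
            qmin = max(q[best].min(), 1e-300)
            pmin = max(p[best].min(), 1e-300)
            nlq = -np.log10(qmin)
            rows.append(
                (
                    contig,
                    int(w_start[sig[a]]),
                    int(w_end[sig[b]]),
                    f"toy_peak_{peak_i}",
                    int(round(10 * nlq)),
                    ".",
                    float(counts[best].max() / lam),
                    float(-np.log10(pmin)),
                    float(nlq),
                )
            )
            peak_i += 1
    return pd.DataFrame(rows, columns=cols)


def degrade_assembly(
    hap: GenomeSequence, config: SimConfig
) -> tuple[GenomeSequence, list[Chain]]:
    """Remove random segments totaling ``dropout_fraction`` of each contig,
    emulating an incomplete de novo assembly; returns the degraded genome and
    exact chains mapping haplotype coordinates to degraded coordinates."""
    rng = _rng(config, _TAG_DEGRADE)
    frac = config.dropout_fraction
    out: dict[str, str] = {}
    chains: list[Chain] = []
    for contig, seq in hap.contigs.items():
        G = len(seq)
        target = int(frac * G)
        drops: list[tuple[int, int]] = []
        dropped = 0
        guard = 0
        while dropped < target and guard < 10_000:
            guard += 1
            size = max(1, int(rng.exponential(config.dropout_segment_mean)))
            size = min(size, target - dropped + config.dropout_segment_mean)
            s = int(rng.integers(0, max(1, G - size)))
            e = min(s + size, G)
            if any(s < de and e > ds for ds, de in drops):
                continue
            drops.append((s, e))
            dropped += e - s
        drops.sort()
        keep: list[tuple[int, int]] = []
        cursor = 0
        for ds, de in drops:
            if ds > cursor:
                keep.append((cursor, ds))
            cursor = de
        if cursor < G:
            keep.append((cursor, G))
        pieces = [seq[s:e] for s, e in keep]
        new_seq = "".join(pieces)
        blocks = []
        t = 0
        for s, e in keep:
            blocks.append((s, e, t, t + e - s))
            t += e - s
        out[contig] = new_seq
        chains.append(
            Chain(
                source_contig=contig,
                target_contig=contig,
                source_size=G,
                target_size=len(new_seq),
                blocks=np.array(blocks, dtype=np.int64).reshape(-1, 4),
            )
        )
    return GenomeSequence(out), chains
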