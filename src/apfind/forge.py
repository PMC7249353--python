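"""Build modified personal genomes (MPGs) from a reference plus phased variants.

Substituting an individual's phased SNVs and indels into the reference yields
two haplotype sequences. Because indels shift all downstream coordinates, each
haplotype comes with a chain (per contig) mapping reference coordinates to
haplotype coordinates; SNVs substitute in place and never break a chain
block, while each indel closes the current block and opens the next one with
an offset of len(alt) - len(ref).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Chain, GenomeSequence, PhasedVariant


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _check_variants(ref: GenomeSequence, variants: list[PhasedVariant]) -> None:
    last_end: dict[str, int] = {}
    last_pos: dict[str, int] = {}
    for v in variants:
        if v.contig not in ref:
            raise ValueError(f"variant contig {v.contig!r} absent from reference")
        s, e = v.footprint
        seq = ref[v.contig]
        if e > len(seq):
            raise ValueError(f"{v.contig}:{v.pos}: REF allele runs past contig end")
        if seq[s:e] != v.ref_allele:
            raise ValueError(
                f"REF mismatch at {v.contig}:{v.pos}: expected "
                f"{v.ref_allele!r}, reference has {seq[s:e]!r}"
            )
        if v.pos < last_pos.get(v.contig, 0):
            raise ValueError(f"variants not sorted at {v.contig}:{v.pos}")
        if s < last_end.get(v.contig, 0):
            raise ValueError(f"overlapping variant footprints at {v.contig}:{v.pos}")
        last_end[v.contig] = e
        last_pos[v.contig] = v.pos


def _apply_to_hap(
    contig: str, seq: str, variants: list[PhasedVariant]
) -> tuple[str, Chain]:
    """Apply one haplotype's variants to one contig; return sequence + chain."""
    pieces: list[str] = []
    blocks: list[tuple[int, int, int, int]] = []
    cursor = 0  # reference position consumed so far
    block_src = 0  # open block start on reference
    block_tgt = 0  # open block start on haplotype
    offset = 0  # hap_pos - ref_pos inside the open block

    for v in variants:
        s, e = v.footprint
        pieces.append(seq[cursor:s])
        pieces.append(v.alt_allele)
        cursor = e
        if len(v.ref_allele) == len(v.alt_allele) == 1:
            continue  # SNV: in-place substitution, block continues
        # indel: the shared prefix (the anchor base) stays aligned, the
        # remainder breaks the block
        p = _common_prefix(v.ref_allele, v.alt_allele)
        cut = s + p
        if cut > block_src:
            blocks.append((block_src, cut, block_tgt, block_tgt + (cut - block_src)))
            block_tgt += cut - block_src
        block_src = e
        block_tgt += len(v.alt_allele) - p
        offset = block_tgt - block_src

    pieces.append(seq[cursor:])
    hap_seq = "".join(pieces)
    if len(seq) > block_src:
        blocks.append((block_src, len(seq), block_tgt, block_tgt + len(seq) - block_src))
    chain = Chain(
        source_contig=contig,
        target_contig=contig,
        source_size=len(seq),
        target_size=len(hap_seq),
        blocks=np.array(blocks, dtype=np.int64).reshape(-1, 4),
    )
    return hap_seq, chain


def apply_phased_variants(
    ref: GenomeSequence, variants: list[PhasedVariant]
) -> tuple[GenomeSequence, GenomeSequence, list[Chain], list[Chain]]:
    """Substitute phased variants into the reference.

    Returns ``(hap1, hap2, chains1, chains2)`` where ``chainsN`` map
    reference coordinates to haplotype-N coordinates, one chain per contig.

    Variants must be position-sorted with non-overlapping reference
    footprints and REF alleles matching the reference; violations raise
    ``ValueError`` naming the offending contig:pos.
    """
    _check_variants(ref, variants)
    haps: list[dict[str, str]] = [{}, {}]
    chains: list[list[Chain]] = [[], []]
    for contig, seq in ref.contigs.items():
        for hap_idx, hap_name in enumerate(("hap1", "hap2")):
            vs = [v for v in variants if v.contig == contig and v.on_hap(hap_name)]
            hap_seq, chain = _apply_to_hap(contig, seq, vs)
            haps[hap_idx][contig] = hap_seq
            chains[hap_idx].append(chain)
    return (
        GenomeSequence(haps[0]),
        GenomeSequence(haps[1]),
        chains[0],
        chains[1],
    )


def downsample_variants(
    variants: list[PhasedVariant],
    target_snv: int,
    target_indel: int,
    seed: int,
) -> list[PhasedVariant]:
    """Uniformly subsample the call set to ``target_snv`` SNVs and
    ``target_indel`` indels (without replacement, within each type).

    Emulates thinning a deep call set down to low-pass density. Output is
    sorted by (contig, pos) and reproducible for a given seed.
    """
    snvs = [v for v in variants if v.vtype == "SNV"]
    indels = [v for v in variants if v.vtype == "indel"]
    if target_snv > len(snvs):
        raise ValueError(f"requested {target_snv} SNVs, only {len(snvs)} available")
    if target_indel > len(indels):
        raise ValueError(f"requested {target_indel} indels, only {len(indels)} available")
    rng = np.random.default_rng(seed)
    keep: list[PhasedVariant] = []
    for pool, k in ((snvs, target_snv), (indels, target_indel)):
        idx = rng.choice(len(pool), size=k, replace=False) if pool else []
        keep.extend(pool[i] for i in idx)
    keep.sort(key=lambda v: (v.contig, v.pos))
    return keep


def variants_to_tracks(variants: list[PhasedVariant]) -> dict[tuple[str, str], pd.DataFrame]:
    """Export variants as BED-like interval tracks keyed by (vtype, phase).

    Each variant lands in exactly one track (its own phase value, with
    homozygous calls under "both"), so per-key record counts match per-key
    input counts. SNV intervals are 1 bp; indel intervals span the
    reference footprint. Use :func:`hap_track` to view one haplotype.
    """
    rows: dict[tuple[str, str], list] = {}
    for v in variants:
        s, e = v.footprint
        key = (v.vtype, v.phase)
        rows.setdefault(key, []).append((v.contig, s, e, f"{v.vtype}_{v.contig}_{v.pos}"))
    out = {}
    for key, recs in rows.items():
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
        out[key] = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return out


def hap_track(
    tracks: dict[tuple[str, str], pd.DataFrame], vtype: str, hap: str
) -> pd.DataFrame:
    """Intervals of one variant type carried by one haplotype: the
    haplotype-specific track plus the homozygous ("both") track."""
    parts = [df for (vt, ph), df in tracks.items() if vt == vtype and ph in (hap, "both")]
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    df = pd.concat(parts, ignore_index=True)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
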