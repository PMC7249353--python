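"""Readers and writers for the standard formats the pipeline exchanges.

FASTA reading goes through pyfaidx and VCF reading through pysam; BED-like
tracks are plain pandas round-trips. Chain files follow UCSC semantics with
the source genome in the `t` fields and the target genome in the `q` fields,
forward strand only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .types import Chain, GenomeSequence, PhasedVariant

BED6 = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "neg_log10_p", "neg_log10_q",
]


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> GenomeSequence:
    fa = pyfaidx.Fasta(str(path))
    genome = GenomeSequence({name: str(fa[name][:]).upper() for name in fa.keys()})
    fa.close()
    return genome


def write_vcf(
    variants: list[PhasedVariant], genome: GenomeSequence, path: str | Path
) -> None:
    """Phased single-sample VCF; phase encodes as 1|0 (hap1), 0|1 (hap2) or
    1|1 (both)."""
    gt = {"hap1": "1|0", "hap2": "0|1", "both": "1|1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=apfind-simulate\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for v in variants:
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gt[v.phase]}\n"
            )


def read_vcf(path: str | Path) -> list[PhasedVariant]:
    """Read a phased single-sample VCF. Unphased or half-called genotypes are
    rejected, multi-allelic records must be pre-split."""
    phase_of = {(1, 0): "hap1", (0, 1): "hap2", (1, 1): "both"}
    out: list[PhasedVariant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: multi-allelic records must be pre-split"
                )
            sample = rec.samples[0]
            alleles = sample["GT"]
            if None in alleles:
                raise ValueError(f"{rec.chrom}:{rec.pos}: half-call rejected")
            if not sample.phased and alleles[0] != alleles[1]:
                raise ValueError(f"{rec.chrom}:{rec.pos}: unphased genotype rejected")
            if tuple(alleles) == (0, 0):
                continue
            out.append(
                PhasedVariant(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    phase=phase_of[tuple(alleles)],
                )
            )
    return out


def write_bed(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    cols = columns or [c for c in df.columns if c in set(BED6) | set(NARROWPEAK)]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str | Path, columns: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = columns or (NARROWPEAK if df.shape[1] >= 9 else BED6[: df.shape[1]])
    df.columns = cols[: df.shape[1]]
    return df


def write_chains(chains: list[Chain], path: str | Path) -> None:
    """UCSC chain format: header
    `chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id`
    with block lines `size dt dq`, source genome in the t fields."""
    with open(path, "w") as fh:
        for i, ch in enumerate(chains, start=1):
            b = ch.blocks
            if len(b) == 0:
                continue
            s0, s1 = int(b[0, 0]), int(b[-1, 1])
            t0, t1 = int(b[0, 2]), int(b[-1, 3])
            score = int(ch.mapped_bases)
            fh.write(
                f"chain {score} {ch.source_contig} {ch.source_size} + {s0} {s1} "
                f"{ch.target_contig} {ch.target_size} + {t0} {t1} {i}\n"
            )
            for j in range(len(b)):
                size = int(b[j, 1] - b[j, 0])
                if j < len(b) - 1:
                    dt = int(b[j + 1, 0] - b[j, 1])
                    dq = int(b[j + 1, 2] - b[j, 3])
                    fh.write(f"{size} {dt} {dq}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


def read_chains(path: str | Path) -> list[Chain]:
    chains: list[Chain] = []
    with open(path) as fh:
        header = None
        blocks: list[tuple[int, int, int, int]] = []
        spos = tpos = 0
        for raw in fh:
            line = raw.strip()
            if line.startswith("chain"):
                parts = line.split()
                header = parts
                spos = int(parts[5])
                tpos = int(parts[10])
                blocks = []
            elif line and header is not None:
                nums = [int(x) for x in line.split()]
                size = nums[0]
                blocks.append((spos, spos + size, tpos, tpos + size))
                if len(nums) == 3:
                    spos += size + nums[1]
                    tpos += size + nums[2]
                else:
                    chains.append(
                        Chain(
                            source_contig=header[2],
                            target_contig=header[7],
                            source_size=int(header[3]),
                            target_size=int(header[8]),
                            blocks=np.array(blocks, dtype=np.int64),
                            chain_id=int(header[12]) if len(header) > 12 else 1,
                        )
                    )
                    header = None
    return chains
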