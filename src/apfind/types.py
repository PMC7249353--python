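"""Domain types shared across the pipeline.

Interval tracks (peaks, reads, variants-as-intervals, genes, repeats) are
plain pandas DataFrames with BED-like columns ``chrom``, ``start``, ``end``
(0-based, half-open) plus whatever extra columns the producing step adds;
the heavier domain objects below carry the genome-scale state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


class GenomeSequence:
    """Named contigs of nucleotide sequence over {A,C,G,T,N}.

    Represents the reference, one personalized haplotype, or a degraded
    assembly. Thin mapping wrapper so downstream code can ask for lengths
    without copying sequence.
    """

    __slots__ = ("contigs",)

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = dict(contigs)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSequence) and self.contigs == other.contigs

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{n}:{len(s)} bp" for n, s in self.contigs.items())
        return f"GenomeSequence({inner})"


@dataclass(frozen=True)
class PhasedVariant:
    """One phased SNV or indel, VCF-style: 1-based ``pos``, anchor-base indels.

    ``phase`` is which haplotype carries the ALT allele: "hap1", "hap2" or
    "both" (homozygous ALT). The reference footprint is
    ``[pos-1, pos-1+len(ref_allele))`` in 0-based coordinates.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    phase: str

    def __post_init__(self):
        if not self.ref_allele:
            raise ValueError(f"{self.contig}:{self.pos}: empty REF allele")
        if not self.alt_allele:
            raise ValueError(f"{self.contig}:{self.pos}: empty ALT allele")
        if self.phase not in ("hap1", "hap2", "both"):
            raise ValueError(f"{self.contig}:{self.pos}: bad phase {self.phase!r}")

    @property
    def vtype(self) -> str:
        """"SNV" iff both alleles are single bases, else "indel"."""
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "indel"

    @property
    def footprint(self) -> tuple[int, int]:
        """0-based half-open reference interval occupied by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref_allele))

    def on_hap(self, hap: str) -> bool:
        return self.phase == "both" or self.phase == hap


@dataclass
class Chain:
    """Block-wise colinear alignment between a source and a target contig.

    UCSC chain semantics: ``blocks`` is an (n, 4) int array of
    (source_start, source_end, target_start, target_end), 0-based half-open,
    strictly increasing and non-overlapping on both sides, with equal source
    and target length per block (no reverse-strand blocks).
    """

    source_contig: str
    target_contig: str
    source_size: int
    target_size: int
    blocks: np.ndarray
    chain_id: int = 1

    def __post_init__(self):
        b = np.asarray(self.blocks, dtype=np.int64).reshape(-1, 4)
        self.blocks = b
        if len(b) == 0:
            return
        if np.any(b[:, 1] - b[:, 0] != b[:, 3] - b[:, 2]):
            raise ValueError("chain block source length != target length")
        if np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("empty or inverted chain block")
        if np.any(b[1:, 0] < b[:-1, 1]) or np.any(b[1:, 2] < b[:-1, 3]):
            raise ValueError("chain blocks overlap or are unsorted")
        if b[0, 0] < 0 or b[-1, 1] > self.source_size or b[-1, 3] > self.target_size:
            raise ValueError("chain block outside genome bounds")

    @property
    def mapped_bases(self) -> int:
        if len(self.blocks) == 0:
            return 0
        return int(np.sum(self.blocks[:, 1] - self.blocks[:, 0]))

    @classmethod
    def identity(cls, contig: str, size: int, target_contig: str | None = None) -> "Chain":
        return cls(
            source_contig=contig,
            target_contig=target_contig if target_contig is not None else contig,
            source_size=size,
            target_size=size,
            blocks=np.array([[0, size, 0, size]], dtype=np.int64),
        )


@dataclass(frozen=True)
class TruthRegion:
    """Ground-truth enriched region emitted by the simulator (reference
    coordinates) with its planted variant content and enrichment fold."""

    contig: str
    start: int
    end: int
    variant_content: str  # none | snv_only | indel_only | both
    fold: float = 1.0

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("TruthRegion start must be < end")
        if self.variant_content not in ("none", "snv_only", "indel_only", "both"):
            raise ValueError(f"bad variant_content {self.variant_content!r}")


@dataclass
class ChangedMappingSummary:
    """Read-level comparison of one dataset aligned to two genomes."""

    n_total: int
    n_far: int
    n_one_build_only: int
    n_lift_fail: int

    def __post_init__(self):
        if self.n_far + self.n_one_build_only + self.n_lift_fail > self.n_total:
            raise ValueError("changed-mapping components exceed total reads")

    @property
    def changed_fraction(self) -> float:
        return (self.n_far + self.n_one_build_only + self.n_lift_fail) / self.n_total


@dataclass
class SkewResult:
    peak_id: str
    c_ref: int
    c_personal: int
    chi2_stat: float
    p_value: float
    verdict: str  # ref_skewed | personal_skewed | no_skew
    alpha: float = 0.05


@dataclass
class APModelFit:
    """Median logistic-regression coefficients for altered-peak odds.

    ``beta_width`` is log-odds per additional 100 bp of peak width;
    ``beta_snv`` and ``beta_indel`` are log-odds per additional variant.
    """

    beta_width: float
    beta_snv: float
    beta_indel: float
    intercept: float
    n_runs: int
    aggregation: str = "median"


@dataclass
class ReplicationNull:
    """Empirical null for altered-peak replication between two genomes."""

    observed_overlap: int
    null_mean: float
    null_sd: float
    n_iterations: int
    empirical_p: float
    degenerate: bool = False
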