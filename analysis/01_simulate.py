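#!/usr/bin/env python
"""Build the synthetic benchmark: toy reference, phased variant call set,
enriched regions with controlled variant content, and diploid ChIP-like
reads.

Writes the on-disk dataset (FASTA/VCF/BED/chain/reads) to scratch/sim/ and a
compact summary table to results/01_simulation_summary.tsv.
"""

from collections import Counter

import pandas as pd

from apfind import apply_phased_variants, gen_enriched_regions, gen_reference, gen_variants, simulate_reads
from apfind import io as apio
from apfind.simulate import regions_to_track
from common import RESULTS, SCRATCH, SEED, base_sim


def main():
    cfg = base_sim()
    ref = gen_reference(cfg)
    variants = gen_variants(ref, cfg)
    regions = gen_enriched_regions(ref, variants, cfg)
    hap1, hap2, ch1, ch2 = apply_phased_variants(ref, variants)
    reads = simulate_reads(hap1, hap2, regions, cfg, chain1=ch1, chain2=ch2)

    outdir = SCRATCH / "sim"
    outdir.mkdir(parents=True, exist_ok=True)
    apio.write_fasta(ref, outdir / "reference.fa")
    apio.write_fasta(hap1, outdir / "hap1.fa")
    apio.write_fasta(hap2, outdir / "hap2.fa")
    apio.write_vcf(variants, ref, outdir / "variants.vcf")
    apio.write_chains(ch1, outdir / "ref_to_hap1.chain")
    apio.write_chains(ch2, outdir / "ref_to_hap2.chain")
    regions_to_track(regions).to_csv(outdir / "truth_regions.bed", sep="\t",
                                     header=False, index=False)
    reads.to_csv(outdir / "reads.tsv.gz", sep="\t", index=False)

    phase_counts = Counter((v.vtype, v.phase) for v in variants)
    content_counts = Counter(r.variant_content for r in regions)
    rows = [
        ("genome_bp", ref.total_length),
        ("n_variants", len(variants)),
        *[(f"n_{vt}_{ph}", n) for (vt, ph), n in sorted(phase_counts.items())],
        ("n_regions", len(regions)),
        *[(f"n_region_{c}", n) for c, n in sorted(content_counts.items())],
        ("n_reads", len(reads)),
        ("read_length_bp", cfg.read_length),
    ]
    summary = pd.DataFrame(rows, columns=["quantity", "value"])
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_simulation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\ndataset written to {outdir}")


if __name__ == "__main__":
    main()
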