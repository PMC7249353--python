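import numpy as np
import pandas as pd
import pytest

from apfind import (
    GenomeSequence,
    PhasedVariant,
    SimConfig,
    apply_phased_variants,
)


@pytest.fixture(scope="session")
def toy_ref():
    """The 8 bp worked example used across forge/liftover tests."""
    return GenomeSequence({"chr1": "ACGTACGT"})


@pytest.fixture(scope="session")
def toy_variants():
    return [
        PhasedVariant("chr1", 2, "C", "T", "hap1"),
        PhasedVariant("chr1", 4, "TA", "T", "hap2"),
    ]


@pytest.fixture(scope="session")
def toy_forge(toy_ref, toy_variants):
    return apply_phased_variants(toy_ref, toy_variants)


@pytest.fixture(scope="session")
def small_sim_config():
    """Compact study: 200 kb, scaled-down variant and region counts."""
    return SimConfig(
        seed=11,
        contig_lengths={"chrS": 200_000},
        n_snv=350,
        n_indel=50,
        n_enriched=40,
    )


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    """Reference, variants, regions and haplotypes for the compact study."""
    from apfind import gen_enriched_regions, gen_reference, gen_variants

    ref = gen_reference(small_sim_config)
    variants = gen_variants(ref, small_sim_config)
    regions = gen_enriched_regions(ref, variants, small_sim_config)
    hap1, hap2, ch1, ch2 = apply_phased_variants(ref, variants)
    return dict(
        config=small_sim_config,
        ref=ref,
        variants=variants,
        regions=regions,
        hap1=hap1,
        hap2=hap2,
        chains1=ch1,
        chains2=ch2,
    )


def brute_force_lift(chain, start, end, min_match):
    """Per-base projection oracle: map every base through the chain blocks,
    apply the min_match rule, and span the mapped bases on the target."""
    mapped = []
    for x in range(start, end):
        for s0, s1, t0, _t1 in chain.blocks:
            if s0 <= x < s1:
                mapped.append(t0 + (x - s0))
                break
    if len(mapped) / (end - start) < min_match:
        return None
    return (min(mapped), max(mapped) + 1)


@pytest.fixture
def brute_lift():
    return brute_force_lift


def overlap_count(qs, qe, starts, ends):
    """Brute-force >= 1 bp overlap counter used as the annotation oracle."""
    return sum(1 for s, e in zip(starts, ends) if s < qe and e > qs)


@pytest.fixture
def count_oracle():
    return overlap_count
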