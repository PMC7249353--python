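"""Synthetic-data generator: reference, variants, regions, reads, the toy
aligner and peak caller, and assembly degradation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apfind import (
    GenomeSequence,
    LiftConfig,
    SimConfig,
    degrade_assembly,
    gen_enriched_regions,
    gen_reference,
    gen_variants,
    lift_intervals,
    simulate_reads,
    toy_align,
    toy_peak_call,
)
from apfind._dna import gc_fraction


class TestGenReference:
    def test_length_and_gc_within_sampling_noise(self):
        cfg = SimConfig(seed=1, contig_lengths={"chrS": 10_000}, gc_content=0.5,
                        n_snv=0, n_indel=0, n_enriched=0)
        ref = gen_reference(cfg)
        assert len(ref["chrS"]) == 10_000
        sd = np.sqrt(0.25 / 10_000)
        assert abs(gc_fraction(ref["chrS"]) - 0.5) < 3 * sd

    def test_deterministic_for_equal_seeds(self):
        cfg = SimConfig(seed=42, contig_lengths={"c": 5000}, n_snv=0, n_indel=0,
                        n_enriched=0)
        assert gen_reference(cfg)["c"] == gen_reference(cfg)["c"]

    def test_extreme_gc(self):
        cfg = SimConfig(seed=2, contig_lengths={"c": 2000}, gc_content=1.0,
                        n_snv=0, n_indel=0, n_enriched=0)
        assert set(gen_reference(cfg)["c"]) <= {"G", "C"}

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SimConfig(seed=1, contig_lengths={"c": 0})


class TestGenVariants:
    def test_zero_requested_empty(self):
        cfg = SimConfig(seed=3, contig_lengths={"c": 10_000}, n_snv=0, n_indel=0,
                        n_enriched=0)
        assert gen_variants(gen_reference(cfg), cfg) == []

    def test_counts_ref_alleles_and_sorting(self):
        cfg = SimConfig(seed=4, contig_lengths={"c": 100_000}, n_snv=100,
                        n_indel=10, n_enriched=0)
        ref = gen_reference(cfg)
        vs = gen_variants(ref, cfg)
        assert sum(v.vtype == "SNV" for v in vs) == 100
        assert sum(v.vtype == "indel" for v in vs) == 10
        # direct sequence-lookup oracle for every REF field
        for v in vs:
            s, e = v.footprint
            assert ref[v.contig][s:e] == v.ref_allele
        assert [v.pos for v in vs] == sorted(v.pos for v in vs)
        assert all(v.phase in ("hap1", "hap2", "both") for v in vs)

    def test_no_overlapping_footprints(self):
        cfg = SimConfig(seed=5, contig_lengths={"c": 30_000}, n_snv=400,
                        n_indel=100, n_enriched=0)
        vs = gen_variants(gen_reference(cfg), cfg)
        prev_end = 0
        for v in vs:  # pairwise scan over the sorted list
            s, e = v.footprint
            assert s >= prev_end
            prev_end = e

    def test_genome_too_small_raises(self):
        cfg = SimConfig(seed=6, contig_lengths={"c": 300}, n_snv=250, n_indel=40,
                        n_enriched=0)
        with pytest.raises(ValueError, match="too small"):
            gen_variants(gen_reference(cfg), cfg)


class TestEnrichedRegions:
    def test_quota_labels_verified_by_recount(self, count_oracle):
        cfg = SimConfig(seed=7, contig_lengths={"c": 300_000}, n_snv=400,
                        n_indel=80, n_enriched=20,
                        enriched_quotas={"none": 5, "snv_only": 5,
                                         "indel_only": 5, "both": 5})
        ref = gen_reference(cfg)
        vs = gen_variants(ref, cfg)
        regions = gen_enriched_regions(ref, vs, cfg)
        assert len(regions) == 20
        snv = [(v.footprint) for v in vs if v.vtype == "SNV"]
        ind = [(v.footprint) for v in vs if v.vtype == "indel"]
        for r in regions:
            n_s = count_oracle(r.start, r.end, [s for s, _ in snv], [e for _, e in snv])
            n_i = count_oracle(r.start, r.end, [s for s, _ in ind], [e for _, e in ind])
            expected = {
                "none": n_s == 0 and n_i == 0,
                "snv_only": n_s > 0 and n_i == 0,
                "indel_only": n_s == 0 and n_i > 0,
                "both": n_s > 0 and n_i > 0,
            }[r.variant_content]
            assert expected, (r, n_s, n_i)
        # non-overlap
        prev = None
        for r in sorted(regions, key=lambda r: r.start):
            if prev is not None:
                assert r.start >= prev
            prev = r.end

    def test_zero_quotas_empty(self):
        cfg = SimConfig(seed=8, contig_lengths={"c": 50_000}, n_snv=10, n_indel=5,
                        n_enriched=0)
        ref = gen_reference(cfg)
        assert gen_enriched_regions(ref, gen_variants(ref, cfg), cfg) == []

    def test_infeasible_quota_raises(self):
        cfg = SimConfig(seed=9, contig_lengths={"c": 50_000}, n_snv=0, n_indel=0,
                        n_enriched=4, enriched_quotas={"snv_only": 4})
        ref = gen_reference(cfg)
        with pytest.raises(ValueError, match="infeasible"):
            gen_enriched_regions(ref, [], cfg)


class TestSimulateReads:
    def test_flat_when_fold_is_one(self):
        cfg = SimConfig(seed=10, contig_lengths={"c": 100_000}, n_snv=0, n_indel=0,
                        n_enriched=10, enriched_quotas={"none": 10},
                        enrichment_fold=1.0, fold_min=1.0,
                        background_depth=0.2, error_rate=0.0)
        ref = gen_reference(cfg)
        regions = gen_enriched_regions(ref, [], cfg)
        reads = simulate_reads(ref, ref, regions, cfg)
        starts = reads["true_start"].to_numpy()
        in_region = np.zeros(100_000, dtype=bool)
        for r in regions:
            in_region[r.start : r.end] = True
        n_in = int(in_region[starts.clip(0, 99_999)].sum())
        span_in = int(in_region.sum())
        # two-sample Poisson rate comparison via binomial conditioning
        p_expected = span_in / 100_000
        p = stats.binomtest(n_in, len(starts), p_expected).pvalue
        assert p > 0.01

    def test_summit_density_matches_triangular_expectation(self):
        """Mean in-region density equals the triangular-profile expectation
        (background x (fold+1)/2) within 20%, and the summit approaches
        background x fold."""
        cfg = SimConfig(seed=11, contig_lengths={"c": 400_000}, n_snv=0, n_indel=0,
                        n_enriched=40, enriched_quotas={"none": 40},
                        enrichment_fold=10.0, fold_min=10.0,
                        enriched_width_mean=600, background_depth=0.2,
                        error_rate=0.0)
        ref = gen_reference(cfg)
        regions = gen_enriched_regions(ref, [], cfg)
        reads = simulate_reads(ref, ref, regions, cfg)
        starts = np.sort(reads["true_start"].to_numpy())
        dens_in, dens_out, summit = [], [], []
        total_in = 0
        span_in = 0
        for r in regions:
            n = np.searchsorted(starts, r.end) - np.searchsorted(starts, r.start)
            total_in += n
            span_in += r.end - r.start
            c = (r.start + r.end) // 2
            summit.append(
                np.searchsorted(starts, c + 50) - np.searchsorted(starts, c - 50)
            )
        mean_in = total_in / span_in
        expected_in = cfg.background_depth * (cfg.enrichment_fold + 1) / 2
        assert mean_in == pytest.approx(expected_in, rel=0.2)
        summit_dens = np.mean(summit) / 100
        assert summit_dens == pytest.approx(cfg.background_depth * 10, rel=0.25)

    def test_haplotype_origin_is_a_fair_coin(self):
        cfg = SimConfig(seed=12, contig_lengths={"c": 100_000}, n_snv=0, n_indel=0,
                        n_enriched=0, background_depth=0.2)
        ref = gen_reference(cfg)
        reads = simulate_reads(ref, ref, [], cfg)
        frac = (reads["true_hap"] == "hap1").mean()
        sd = np.sqrt(0.25 / len(reads))
        assert abs(frac - 0.5) < 3 * sd

    def test_read_longer_than_contig_rejected(self):
        cfg = SimConfig(seed=13, contig_lengths={"c": 30}, n_snv=0, n_indel=0,
                        n_enriched=0)
        ref = gen_reference(cfg)
        with pytest.raises(ValueError, match="read_length"):
            simulate_reads(ref, ref, [], cfg)


def brute_force_align(seq, genome_str, max_mismatches):
    """Exhaustive scan oracle: best gapless position, ties leftmost."""
    L = len(seq)
    best = None
    for p in range(len(genome_str) - L + 1):
        mm = sum(a != b for a, b in zip(seq, genome_str[p : p + L]))
        if best is None or mm < best[1]:
            best = (p, mm)
    if best is None or best[1] > max_mismatches:
        return None
    return best


@pytest.fixture(scope="module")
def genome_5kb():
    cfg = SimConfig(seed=14, contig_lengths={"g": 5000}, n_snv=0, n_indel=0,
                    n_enriched=0)
    return gen_reference(cfg)


class TestToyAlign:

    def _reads(self, seqs):
        return pd.DataFrame(
            {"name": [f"r{i}" for i in range(len(seqs))], "seq": seqs,
             "strand": ["+"] * len(seqs)}
        )

    def test_verbatim_read_maps_at_origin(self, genome_5kb):
        g = genome_5kb["g"]
        reads = self._reads([g[1000:1036]])
        out = toy_align(reads, genome_5kb, 0)
        assert out.loc[0, "start"] == 1000

    def test_matches_exhaustive_scan(self, genome_5kb):
        """Best position and mismatch count agree with the brute-force scan
        for reads carrying 0-3 substitutions."""
        g = genome_5kb["g"]
        rng = np.random.default_rng(15)
        seqs, expected = [], []
        for _ in range(40):
            p = int(rng.integers(0, 5000 - 36))
            s = list(g[p : p + 36])
            for _ in range(int(rng.integers(0, 4))):
                i = int(rng.integers(0, 36))
                s[i] = "ACGT"["ACGT".index(s[i]) - 1]
            seqs.append("".join(s))
        out = toy_align(self._reads(seqs), genome_5kb, 2)
        placed = {r.name: (r.start, r.score) for r in out.itertuples()}
        for i, seq in enumerate(seqs):
            oracle = brute_force_align(seq, g, 2)
            got = placed.get(f"r{i}")
            assert got == oracle

    def test_deletion_read_rescued_by_matching_haplotype(self, genome_5kb):
        """A read spanning a 4 bp haplotype-specific deletion is unmapped
        against the reference even with 2 mismatches allowed, but maps to the
        haplotype carrying the deletion."""
        from apfind import PhasedVariant, apply_phased_variants

        g = genome_5kb["g"]
        pos = 2500
        v = PhasedVariant("g", pos, g[pos - 1 : pos + 4], g[pos - 1], "hap1")
        hap1, _, _, _ = apply_phased_variants(genome_5kb, [v])
        h = hap1["g"]
        read = h[pos - 18 : pos - 18 + 36]  # spans the deletion junction
        reads = self._reads([read])
        vs_ref = toy_align(reads, genome_5kb, 2)
        vs_hap = toy_align(reads, hap1, 2)
        assert len(vs_ref) == 0  # oracle: scan confirms > 2 mismatches
        assert brute_force_align(read, g, 2) is None
        assert len(vs_hap) == 1 and vs_hap.loc[0, "start"] == pos - 18

    def test_duplicates_collapse_to_one_record(self, genome_5kb):
        g = genome_5kb["g"]
        reads = self._reads([g[100:136], g[100:136]])
        out = toy_align(reads, genome_5kb, 0)
        assert len(out) == 1

    def test_opposite_strands_not_collapsed(self, genome_5kb):
        g = genome_5kb["g"]
        reads = pd.DataFrame(
            {"name": ["a", "b"], "seq": [g[100:136]] * 2, "strand": ["+", "-"]}
        )
        out = toy_align(reads, genome_5kb, 0)
        assert len(out) == 2

    def test_empty_read_set(self, genome_5kb):
        out = toy_align(self._reads([]), genome_5kb, 0)
        assert len(out) == 0


class TestToyPeakCall:
    def _uniform_track(self, n, G, seed, L=36):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.integers(0, G - L, size=n))
        return pd.DataFrame(
            {"chrom": "c", "start": starts, "end": starts + L,
             "name": [f"r{i}" for i in range(n)], "score": 0, "strand": "+"}
        )

    def test_null_uniform_reads_controls_false_calls(self):
        """Uniform reads at 5% FDR: the called fraction of the genome stays
        far below the nominal rate (the caller is conservative by design)."""
        called_bp = 0
        for seed in range(3):
            track = self._uniform_track(5000, 100_000, seed)
            peaks = toy_peak_call(track, 100_000, fdr=0.05)
            called_bp += int((peaks["end"] - peaks["start"]).sum())
        assert called_bp / (3 * 100_000) <= 0.05

    def test_planted_cluster_is_called_with_poisson_tail_qvalue(self):
        """A dense read cluster is called; its -log10 q reflects the Poisson
        upper tail of the window count."""
        track = self._uniform_track(2000, 100_000, seed=3)
        cluster = pd.DataFrame(
            {"chrom": "c", "start": np.arange(50_000, 50_200, 2),
             "end": np.arange(50_000, 50_200, 2) + 36,
             "name": [f"x{i}" for i in range(100)], "score": 0, "strand": "+"}
        )
        both = pd.concat([track, cluster], ignore_index=True).sort_values("start")
        peaks = toy_peak_call(both, 100_000, fdr=0.05)
        hit = peaks[(peaks.start < 50_250) & (peaks.end > 50_000)]
        assert len(hit) == 1
        assert hit.iloc[0]["neg_log10_q"] > 10
        assert hit.iloc[0]["score"] == round(10 * hit.iloc[0]["neg_log10_q"])

    def test_zero_reads_no_peaks(self):
        empty = self._uniform_track(0, 1000, 0)
        assert len(toy_peak_call(empty, 1000)) == 0


class TestDegradeAssembly:
    def test_zero_dropout_is_identity(self):
        cfg = SimConfig(seed=16, contig_lengths={"c": 50_000}, n_snv=0, n_indel=0,
                        n_enriched=0, dropout_fraction=0.0)
        ref = gen_reference(cfg)
        degraded, chains = degrade_assembly(ref, cfg)
        assert degraded == ref
        assert chains[0].blocks.tolist() == [[0, 50_000, 0, 50_000]]

    def test_dropout_length_and_per_base_round_trip(self):
        cfg = SimConfig(seed=17, contig_lengths={"c": 100_000}, n_snv=0, n_indel=0,
                        n_enriched=0, dropout_fraction=0.1)
        ref = gen_reference(cfg)
        degraded, chains = degrade_assembly(ref, cfg)
        lost = 100_000 - len(degraded["c"])
        assert abs(lost - 10_000) < 3 * cfg.dropout_segment_mean
        # every surviving base round-trips through the chain
        seq, dseq = ref["c"], degraded["c"]
        ch = chains[0]
        rng = np.random.default_rng(0)
        for s0, s1, t0, _ in ch.blocks:
            for x in rng.integers(s0, s1, size=min(10, s1 - s0)):
                assert seq[int(x)] == dseq[int(x) - s0 + t0]

    def test_interval_inside_dropped_segment_fails_to_lift(self):
        cfg = SimConfig(seed=18, contig_lengths={"c": 100_000}, n_snv=0, n_indel=0,
                        n_enriched=0, dropout_fraction=0.2)
        ref = gen_reference(cfg)
        degraded, chains = degrade_assembly(ref, cfg)
        b = chains[0].blocks
        gaps = [(int(b[i, 1]), int(b[i + 1, 0])) for i in range(len(b) - 1)
                if b[i + 1, 0] - b[i, 1] > 10]
        assert gaps, "expected at least one dropped segment"
        g0, g1 = gaps[0]
        t = pd.DataFrame({"chrom": ["c"], "start": [g0 + 1], "end": [g1 - 1]})
        lifted, unlifted = lift_intervals(t, chains, LiftConfig(min_match=0.95))
        assert len(lifted) == 0 and len(unlifted) == 1


class TestDeterminism:
    def test_full_generation_is_bit_reproducible(self):
        cfg = SimConfig(seed=19, contig_lengths={"c": 60_000}, n_snv=60, n_indel=10,
                        n_enriched=8)
        outs = []
        for _ in range(2):
            ref = gen_reference(cfg)
            vs = gen_variants(ref, cfg)
            regions = gen_enriched_regions(ref, vs, cfg)
            reads = simulate_reads(ref, ref, regions, cfg)
            outs.append((ref["c"], vs, [(r.start, r.end, r.fold) for r in regions],
                         reads["seq"].tolist()))
        assert outs[0] == outs[1]
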