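"""End-to-end synthetic study: simulate -> forge -> align -> call -> lift ->
compare -> skew -> characterize.

The personal analysis follows one haplotype (hap1), like analysing the
paternal haploid of a modified personal genome; in "dpg" mode hap1 is first
degraded (random segment dropout) to emulate an incomplete de novo assembly
and lifting runs at the permissive 0.85 minMatch through the composed
degraded-to-reference chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import characterize as chz
from . import compare as cmp
from . import forge, simulate, skew
from .liftover import LiftConfig, compose_chains, invert_chain, lift_intervals, lift_reads
from .types import Chain, ChangedMappingSummary, GenomeSequence, PhasedVariant, TruthRegion


@dataclass
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    genome_mode: str = "mpg"  # mpg | dpg
    max_mismatches: int = 1
    fdr: float = 0.05
    ref_fdr: float | None = None  # lax-reference sensitivity mode when set
    lift: LiftConfig = field(default_factory=LiftConfig)

    def __post_init__(self):
        if self.genome_mode not in ("mpg", "dpg"):
            raise ValueError("genome_mode must be 'mpg' or 'dpg'")


@dataclass
class PipelineResult:
    config: PipelineConfig
    ref: GenomeSequence
    variants: list[PhasedVariant]
    regions: list[TruthRegion]
    hap1: GenomeSequence
    hap2: GenomeSequence
    chains_ref_to_hap1: list[Chain]
    chains_ref_to_personal: list[Chain]
    personal_genome: GenomeSequence
    reads: pd.DataFrame
    ref_read_track: pd.DataFrame
    personal_read_track: pd.DataFrame
    ref_reads_personal_coords: pd.DataFrame
    ref_peaks: pd.DataFrame
    personal_peaks: pd.DataFrame
    ref_peaks_personal_coords: pd.DataFrame
    n_unlifted_peaks: int
    common: pd.DataFrame
    personal_only: pd.DataFrame
    ref_only: pd.DataFrame
    peaks_annotated: pd.DataFrame
    skew_per_peak: pd.DataFrame
    skew_summary: pd.DataFrame
    combo_stats: pd.DataFrame
    changed_mapping: ChangedMappingSummary

    def summary(self) -> dict:
        n_common = len(self.common)
        n_po = len(self.personal_only)
        n_ro = len(self.ref_only)
        out = {
            "n_reads": int(len(self.reads)),
            "n_mapped_ref": int(len(self.ref_read_track)),
            "n_mapped_personal": int(len(self.personal_read_track)),
            "n_ref_peaks": int(len(self.ref_peaks)),
            "n_personal_peaks": int(len(self.personal_peaks)),
            "n_unlifted_peaks": int(self.n_unlifted_peaks),
            "n_common": n_common,
            "n_personal_only": n_po,
            "n_ref_only": n_ro,
            "changed_mapping_fraction": self.changed_mapping.changed_fraction,
        }
        if n_common + n_po:
            out["personal_only_pct"] = cmp.ap_fraction(n_po, n_common)
        if n_common + n_ro:
            out["ref_only_pct"] = cmp.ap_fraction(n_ro, n_common)
        return out


def _annotate_all(
    peaks: pd.DataFrame,
    snv_track: pd.DataFrame,
    indel_track: pd.DataFrame,
    ref_reads: pd.DataFrame,
    personal_reads: pd.DataFrame,
    variant_margin: int = 0,
) -> pd.DataFrame:
    """Annotate read counts on the exact peak interval and variant counts on
    the interval padded by ``variant_margin`` — a fragment-length margin,
    since a variant can alter a call through reads whose spans reach beyond
    the called window run."""
    if variant_margin:
        padded = peaks.copy()
        padded["start"] = (padded["start"] - variant_margin).clip(lower=0)
        padded["end"] = padded["end"] + variant_margin
    else:
        padded = peaks
    out = peaks.copy()
    out["n_snv"] = cmp.annotate_counts(padded, snv_track, "n_snv")["n_snv"].to_numpy()
    out["n_indel"] = cmp.annotate_counts(padded, indel_track, "n_indel")[
        "n_indel"
    ].to_numpy()
    out = cmp.annotate_counts(out, ref_reads, "n_reads_ref")
    out = cmp.annotate_counts(out, personal_reads, "n_reads_personal")
    return out


def pooled_ap_study(
    base_config: PipelineConfig, base_seed: int, n_replicates: int = 8
) -> dict:
    """Run the end-to-end pipeline over replicate simulations and pool the
    altered-peak statistics.

    Per-replicate altered-peak counts are small (a few peaks per megabase at
    the default study conditions), so the variant-combination probabilities
    are estimated over replicate studies that differ only in seed. Replicate
    seeds are derived from ``base_seed``; results are deterministic given
    (config, base_seed, n_replicates).
    """
    counts = {c: {"n_total": 0, "n_altered": 0} for c in ("none", "snv_only",
                                                          "indel_only", "both")}
    n_po = n_ro = 0
    recovered = total_regions = 0
    pooled_peaks: list[pd.DataFrame] = []
    for rep in range(n_replicates):
        sim = replace_seed(base_config.sim, (base_seed * 1000 + rep) % 2**31)
        cfg = PipelineConfig(
            sim=sim,
            genome_mode=base_config.genome_mode,
            max_mismatches=base_config.max_mismatches,
            fdr=base_config.fdr,
            ref_fdr=base_config.ref_fdr,
            lift=base_config.lift,
        )
        res = run_pipeline(cfg)
        pooled_peaks.append(res.peaks_annotated.assign(replicate=rep))
        n_po += len(res.personal_only)
        n_ro += len(res.ref_only)
        for row in res.combo_stats.itertuples():
            counts[row.combo]["n_total"] += row.n_total
            counts[row.combo]["n_altered"] += row.n_altered
        pp = res.personal_peaks
        for contig, s, e, _fold in simulate._lift_regions(
            res.regions, res.chains_ref_to_personal
        ):
            total_regions += 1
            if ((pp["chrom"] == contig) & (pp["start"] < e) & (pp["end"] > s)).any():
                recovered += 1

    def prob(cats):
        n = sum(counts[c]["n_total"] for c in cats)
        a = sum(counts[c]["n_altered"] for c in cats)
        return a / n if n else float("nan")

    return {
        "n_replicates": n_replicates,
        "n_personal_only": n_po,
        "n_ref_only": n_ro,
        "p_altered_indel": prob(["indel_only", "both"]),
        "p_altered_snv_only": prob(["snv_only"]),
        "p_altered_none": prob(["none"]),
        "region_recovery": recovered / total_regions if total_regions else float("nan"),
        "combo_counts": counts,
        "peaks_annotated": pd.concat(pooled_peaks, ignore_index=True),
    }


def replace_seed(sim: simulate.SimConfig, seed: int) -> simulate.SimConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    sim_cfg = config.sim

    # --- simulate the study ---
    ref = simulate.gen_reference(sim_cfg)
    variants = simulate.gen_variants(ref, sim_cfg)
    regions = simulate.gen_enriched_regions(ref, variants, sim_cfg)
    hap1, hap2, ch1, ch2 = forge.apply_phased_variants(ref, variants)
    reads = simulate.simulate_reads(hap1, hap2, regions, sim_cfg, chain1=ch1, chain2=ch2)

    # --- personal genome under study ---
    if config.genome_mode == "dpg":
        personal, drop_chains = simulate.degrade_assembly(hap1, sim_cfg)
        chains_ref_to_personal = compose_chains(ch1, drop_chains)
        lift_cfg = LiftConfig(min_match=config.lift.alt_min_match)
    else:
        personal = hap1
        chains_ref_to_personal = ch1
        lift_cfg = config.lift

    # --- align and call on both genomes ---
    read_cols = ["name", "seq", "strand"]
    ref_track = simulate.toy_align(reads[read_cols], ref, config.max_mismatches)
    personal_track = simulate.toy_align(reads[read_cols], personal, config.max_mismatches)
    ref_fdr = config.ref_fdr if config.ref_fdr is not None else config.fdr
    # one library, two assemblies: hold the global background rate fixed
    # across both calls so altered calls reflect local read redistribution
    shared_total = int(round((len(ref_track) + len(personal_track)) / 2))
    ref_peaks = simulate.toy_peak_call(
        ref_track, ref.lengths(), ref_fdr,
        read_length=sim_cfg.read_length, background_total=shared_total,
    )
    personal_peaks = simulate.toy_peak_call(
        personal_track, personal.lengths(), config.fdr,
        read_length=sim_cfg.read_length, background_total=shared_total,
    )

    # --- lift reference-frame annotations into the personal frame (the MPG
    # convention: peak, coverage and variant tracks move to the personalized
    # haplotype; personal-genome calls stay native) ---
    lifted_ref_peaks, unlifted_peaks = lift_intervals(
        ref_peaks, chains_ref_to_personal, lift_cfg
    )
    lifted_ref_peaks = cmp.merge_intervals(
        lifted_ref_peaks.sort_values(["chrom", "start"])
    )
    ref_reads_personal, _ = lift_reads(ref_track, chains_ref_to_personal, lift_cfg)

    # --- categorize and annotate in personal coordinates ---
    common, personal_only, ref_only = cmp.categorize_peaks(
        personal_peaks, lifted_ref_peaks
    )
    tracks = forge.variants_to_tracks(variants)
    # variant intervals lift on any mapped base: the chains are exact, and a
    # deletion's own reference footprint survives only through its anchor
    permissive = LiftConfig(min_match=1e-9)
    snv_track, _ = lift_intervals(
        forge.hap_track(tracks, "SNV", "hap1"), chains_ref_to_personal, permissive
    )
    indel_track, _ = lift_intervals(
        forge.hap_track(tracks, "indel", "hap1"), chains_ref_to_personal, permissive
    )
    all_peaks = pd.concat([common, personal_only, ref_only], ignore_index=True)
    annotated = _annotate_all(
        all_peaks, snv_track, indel_track, ref_reads_personal, personal_track,
        variant_margin=2 * sim_cfg.read_length,
    )

    # --- skew and combo characterization ---
    per_peak, skew_summary = skew.classify_skew(
        annotated, lib_ref=max(len(ref_track), 1), lib_personal=max(len(personal_track), 1)
    )
    combo = chz.variant_combo_stats(annotated) if len(annotated) else pd.DataFrame()

    changed = cmp.compare_mappings(
        ref_track, personal_track, chains_ref_to_personal, lift_config=lift_cfg
    )

    return PipelineResult(
        config=config,
        ref=ref,
        variants=variants,
        regions=regions,
        hap1=hap1,
        hap2=hap2,
        chains_ref_to_hap1=ch1,
        chains_ref_to_personal=chains_ref_to_personal,
        personal_genome=personal,
        reads=reads,
        ref_read_track=ref_track,
        personal_read_track=personal_track,
        ref_reads_personal_coords=ref_reads_personal,
        ref_peaks=ref_peaks,
        personal_peaks=personal_peaks,
        ref_peaks_personal_coords=lifted_ref_peaks,
        n_unlifted_peaks=len(unlifted_peaks),
        common=common,
        personal_only=personal_only,
        ref_only=ref_only,
        peaks_annotated=annotated,
        skew_per_peak=per_peak,
        skew_summary=skew_summary,
        combo_stats=combo,
        changed_mapping=changed,
    )
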