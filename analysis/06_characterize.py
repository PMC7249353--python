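#!/usr/bin/env python
"""Characterize what drives altered peaks.

Pools replicate studies for the variant-combination probabilities, fits the
regularized logistic model of altered-peak odds on width and variant counts,
measures altered-peak replication between the MPG- and DPG-mode studies
against a resampling null, and profiles altered peaks against synthetic gene
and repeat annotations. Writes results/06_*.tsv.
"""

import numpy as np
import pandas as pd

from apfind import (
    confident_filter,
    fit_ap_model,
    gene_distance_profile,
    q_rank_curves,
    repeat_enrichment,
    replication_fraction,
    replication_null,
    replication_overlap,
)
from apfind.pipeline import pooled_ap_study
from common import RESULTS, SEED, dpg_config, mpg_config, run


def synthetic_gene_track(rng, genome_bp, n=30):
    starts = np.sort(rng.choice(genome_bp // 20_000, n, replace=False)) * 20_000
    widths = rng.integers(2_000, 15_000, n)
    return pd.DataFrame({"chrom": "chrS", "start": starts,
                         "end": np.minimum(starts + widths, genome_bp)})


def synthetic_repeat_track(rng, genome_bp, n=4000):
    fams = rng.choice(["Alu", "L", "MIR", "LTR"], size=n, p=[0.4, 0.3, 0.2, 0.1])
    starts = rng.integers(0, genome_bp - 400, n)
    return pd.DataFrame({"chrom": "chrS", "start": starts,
                         "end": starts + rng.integers(100, 400, n),
                         "name": [f"{f}-{i}" for i, f in enumerate(fams)]})


def main():
    # pooled variant-combination probabilities (replicate studies)
    study = pooled_ap_study(mpg_config(), base_seed=SEED, n_replicates=6)
    combos = pd.DataFrame(
        [
            {"combo": c, **v, "p_altered": v["n_altered"] / v["n_total"] if v["n_total"] else float("nan")}
            for c, v in study["combo_counts"].items()
        ]
    )
    combos.to_csv(RESULTS / "06_combo_probabilities.tsv", sep="\t", index=False)
    print("pooled variant-combination alteration probabilities:")
    print(combos.to_string(index=False))

    # logistic model on the pooled per-peak table of the replicate studies
    res_mpg = run(mpg_config())
    fit = fit_ap_model(study["peaks_annotated"], n_runs=50, seed=SEED)
    model = pd.DataFrame(
        [
            ("beta_width_per_100bp", fit.beta_width),
            ("beta_per_snv", fit.beta_snv),
            ("beta_per_indel", fit.beta_indel),
            ("intercept", fit.intercept),
        ],
        columns=["coefficient", "median_value"],
    )
    model.to_csv(RESULTS / "06_logistic_model.tsv", sep="\t", index=False)
    print("\nlogistic model of altered-peak odds (median over refits):")
    print(model.to_string(index=False))

    # replication of personal-only calls between the MPG and DPG studies
    res_dpg = run(dpg_config())
    a = res_mpg.personal_only
    b = res_dpg.personal_only
    obs = replication_overlap(a, b)
    rows = [("observed_overlap", obs),
            ("replication_pct", replication_fraction(obs, len(a)) if len(a) else 0.0)]
    if len(a) and len(b):
        null = replication_null(
            res_mpg.personal_peaks, res_dpg.personal_peaks, len(a), len(b),
            observed_overlap=obs, n_iter=1000, seed=SEED,
        )
        rows += [("null_mean", null.null_mean), ("null_sd", null.null_sd),
                 ("empirical_p", null.empirical_p)]
    repl = pd.DataFrame(rows, columns=["quantity", "value"])
    repl.to_csv(RESULTS / "06_replication.tsv", sep="\t", index=False)
    print("\naltered-peak replication between studies:")
    print(repl.to_string(index=False))

    # genomic context of altered peaks vs common peaks
    rng = np.random.default_rng(SEED)
    genes = synthetic_gene_track(rng, res_mpg.personal_genome.total_length)
    aps = pd.concat([res_mpg.personal_only, res_mpg.ref_only], ignore_index=True)
    profile = pd.DataFrame(
        {
            "altered": gene_distance_profile(aps, genes),
            "common": gene_distance_profile(res_mpg.common, genes),
        }
    )
    profile.to_csv(RESULTS / "06_gene_distance_profile.tsv", sep="\t")
    print("\ngene-relative position fractions:")
    print(profile.to_string())

    # repeat-family enrichment around altered peaks
    reps = synthetic_repeat_track(rng, res_mpg.personal_genome.total_length)
    if len(aps):
        enr = repeat_enrichment(aps, reps, res_mpg.personal_genome.lengths(), seed=SEED)
        enr.to_csv(RESULTS / "06_repeat_enrichment.tsv", sep="\t", index=False)
        print("\nrepeat-family enrichment (AP peaks vs width-matched controls):")
        print(enr.round(3).to_string(index=False))

    # confident-peak filter and q-rank curves
    confident = confident_filter(res_mpg.peaks_annotated)
    curves = q_rank_curves({
        "mpg_personal_only": res_mpg.personal_only,
        "dpg_personal_only": res_dpg.personal_only,
    })
    curves.to_csv(RESULTS / "06_q_rank_curves.tsv", sep="\t", index=False)
    print(f"\nconfident peaks (ln score >= 4): {len(confident)} of "
          f"{len(res_mpg.peaks_annotated)}")


if __name__ == "__main__":
    main()
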