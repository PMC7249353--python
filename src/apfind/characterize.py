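"""Quantify what drives altered peaks (APs).

Covers the probability that each variant combination (SNVs only, indels
only, both, none) alters a peak; a regularized logistic model of AP odds on
peak width and variant counts; replication of AP calls between genome
implementations with an empirical resampling null; gene-relative position
profiles; repeat-family enrichment against width-matched random controls;
confident-peak filtering; and q-value rank curves.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV

from .compare import _overlaps_any, annotate_counts
from .types import APModelFit, ReplicationNull

COMBOS = ("none", "snv_only", "indel_only", "both")


def assign_combo(n_snv: np.ndarray, n_indel: np.ndarray) -> np.ndarray:
    """Mutually exclusive variant-content category per peak."""
    s = np.asarray(n_snv) > 0
    i = np.asarray(n_indel) > 0
    out = np.where(
        s & i, "both", np.where(s, "snv_only", np.where(i, "indel_only", "none"))
    )
    return out


def variant_combo_stats(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-combination alteration probabilities and mean widths.

    ``peaks`` carries ``n_snv``, ``n_indel`` and ``category`` for the pooled
    common + personal-only + ref-only set. For each combination the
    probability that a peak of that content is personal-only (and, separately,
    ref-only, and either) is the altered count divided by the total peak
    count of that combination; empty combinations are reported absent.
    """
    df = peaks.copy()
    df["combo"] = assign_combo(df["n_snv"].to_numpy(), df["n_indel"].to_numpy())
    rows = []
    for combo in COMBOS:
        sub = df[df["combo"] == combo]
        if len(sub) == 0:
            continue
        n_total = len(sub)
        n_personal = int((sub["category"] == "personal_only").sum())
        n_ref = int((sub["category"] == "ref_only").sum())
        rows.append(
            {
                "combo": combo,
                "n_total": n_total,
                "n_personal_only": n_personal,
                "n_ref_only": n_ref,
                "n_altered": n_personal + n_ref,
                "p_personal_only": n_personal / n_total,
                "p_ref_only": n_ref / n_total,
                "p_altered": (n_personal + n_ref) / n_total,
                "mean_width": float((sub["end"] - sub["start"]).mean()),
            }
        )
    return pd.DataFrame(rows)


def fit_ap_model(
    peaks: pd.DataFrame,
    n_runs: int = 1000,
    seed: int = 0,
    cv: int = 5,
    n_penalties: int = 10,
) -> APModelFit:
    """L1-regularized logistic regression of AP status on peak covariates.

    Response: altered (personal-only or ref-only) = 1, common = 0.
    Covariates: peak width scaled to 100 bp units, SNV count, indel count.
    Each run downsamples the common class to the AP count (balancing the
    classes), standardizes covariates, fits an L1 path with cross-validated
    deviance to pick the penalty, and unscales the coefficients; medians over
    ``n_runs`` runs are reported, as cv.glmnet-style refitting would do.
    """
    y_all = (peaks["category"] != "common").to_numpy(dtype=int)
    X_all = np.column_stack(
        [
            (peaks["end"] - peaks["start"]).to_numpy(float) / 100.0,
            peaks["n_snv"].to_numpy(float),
            peaks["n_indel"].to_numpy(float),
        ]
    )
    ap_idx = np.flatnonzero(y_all == 1)
    common_idx = np.flatnonzero(y_all == 0)
    if len(ap_idx) < 2 or len(common_idx) < 2:
        raise ValueError("need >= 2 peaks in each class to fit the AP model")
    n_ap = len(ap_idx)
    cv = max(2, min(cv, n_ap))  # tiny AP sets cannot support 5 folds
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_runs, 3))
    intercepts = np.empty(n_runs)
    for run in range(n_runs):
        take = rng.choice(common_idx, size=min(n_ap, len(common_idx)), replace=False)
        idx = np.concatenate([ap_idx, take])
        X = X_all[idx]
        y = y_all[idx]
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        model = LogisticRegressionCV(
            Cs=n_penalties,
            cv=cv,
            l1_ratios=(1.0,),  # pure lasso; penalty picked at CV-min deviance
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=3000,
            random_state=int(rng.integers(0, 2**31 - 1)),
            use_legacy_attributes=False,
        )
        model.fit(Xs, y)
        beta_std = model.coef_[0]
        beta = beta_std / sd
        coefs[run] = beta
        intercepts[run] = model.intercept_[0] - float(beta @ mu)
    med = np.median(coefs, axis=0)
    return APModelFit(
        beta_width=float(med[0]),
        beta_snv=float(med[1]),
        beta_indel=float(med[2]),
        intercept=float(np.median(intercepts)),
        n_runs=n_runs,
    )


def replication_overlap(ap_track_a: pd.DataFrame, ap_track_b: pd.DataFrame) -> int:
    """Number of A peaks overlapping >= 1 B peak (same coordinate system)."""
    if len(ap_track_a) == 0 or len(ap_track_b) == 0:
        return 0
    b = ap_track_b.sort_values(["chrom", "start"])
    from .compare import merge_intervals

    hits = _overlaps_any(
        ap_track_a.reset_index(drop=True), merge_intervals(b[["chrom", "start", "end"]])
    )
    return int(hits.sum())


def replication_fraction(n_overlap: int, n_total: int) -> float:
    """Replication percentage to one decimal (e.g. 234 of 3068 -> 7.6)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return round(100.0 * n_overlap / n_total, 1)


def _overlap_count_subset(adj_indptr, adj_indices, a_sel: np.ndarray, b_mask: np.ndarray) -> int:
    n = 0
    for a in a_sel:
        lo, hi = adj_indptr[a], adj_indptr[a + 1]
        if b_mask[adj_indices[lo:hi]].any():
            n += 1
    return n


def replication_null(
    total_track_a: pd.DataFrame,
    total_track_b: pd.DataFrame,
    n_a: int,
    n_b: int,
    observed_overlap: int = 0,
    n_iter: int = 1000,
    seed: int = 0,
) -> ReplicationNull:
    """Empirical null for AP replication between two genomes.

    Each iteration draws ``n_a`` peaks uniformly without replacement from
    genome A's full peak track and ``n_b`` from genome B's, and counts the
    A-sampled peaks that overlap >= 1 B-sampled peak. The empirical p-value
    is the add-one-smoothed upper tail of the observed overlap.
    """
    NA, NB = len(total_track_a), len(total_track_b)
    if n_a > NA or n_b > NB:
        raise ValueError("sample size exceeds track size")
    # adjacency: for each A peak, indices of B peaks it overlaps
    a = total_track_a.reset_index(drop=True)
    b = total_track_b.reset_index(drop=True)
    indptr = [0]
    indices: list[int] = []
    b_by_contig = {c: g for c, g in b.groupby("chrom")}
    for row in a.itertuples(index=False):
        g = b_by_contig.get(row.chrom)
        if g is not None:
            hit = (g["start"].to_numpy() < row.end) & (g["end"].to_numpy() > row.start)
            indices.extend(g.index.to_numpy()[hit])
        indptr.append(len(indices))
    indptr = np.array(indptr)
    indices = np.array(indices, dtype=np.int64)

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        a_sel = rng.choice(NA, size=n_a, replace=False)
        b_mask = np.zeros(NB, dtype=bool)
        b_mask[rng.choice(NB, size=n_b, replace=False)] = True
        null[it] = _overlap_count_subset(indptr, indices, a_sel, b_mask)
    degenerate = n_iter < 2
    if degenerate:
        warnings.warn("replication_null with n_iter < 2: null sd undefined")
    emp_p = float((1 + np.sum(null >= observed_overlap)) / (n_iter + 1))
    return ReplicationNull(
        observed_overlap=int(observed_overlap),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if not degenerate else 0.0,
        n_iterations=n_iter,
        empirical_p=emp_p,
        degenerate=degenerate,
    )


def gene_distance_profile(peaks: pd.DataFrame, gene_track: pd.DataFrame) -> pd.Series:
    """Fraction of peaks overlapping a gene, within 10 kb, 10-100 kb, or
    further than 100 kb of the nearest gene (boundary-to-boundary distance,
    strand-agnostic). Fractions sum to 1 over non-empty input."""
    bins = ["overlapping", "<=10kb", "10-100kb", ">100kb"]
    if len(peaks) == 0:
        return pd.Series(dtype=float, index=pd.Index(bins))
    if len(gene_track) == 0:
        warnings.warn("empty gene track: all peaks assigned to >100kb")
        return pd.Series([0.0, 0.0, 0.0, 1.0], index=bins)
    dist = np.full(len(peaks), np.inf)
    genes = {
        c: (np.sort(g["start"].to_numpy()), np.sort(g["end"].to_numpy()))
        for c, g in gene_track.groupby("chrom")
    }
    p = peaks.reset_index(drop=True)
    for contig, g in p.groupby("chrom"):
        if contig not in genes:
            continue
        gs, ge = genes[contig]
        qs = g["start"].to_numpy()
        qe = g["end"].to_numpy()
        # gap to the nearest gene on the right and on the left
        i_r = np.searchsorted(gs, qe, side="left")
        right = np.where(i_r < len(gs), gs[np.minimum(i_r, len(gs) - 1)] - qe, np.inf)
        i_l = np.searchsorted(ge, qs, side="right") - 1
        left = np.where(i_l >= 0, qs - ge[np.maximum(i_l, 0)], np.inf)
        d = np.maximum(np.minimum(right, left), 0)
        overlap = _overlaps_any(
            g.reset_index(drop=True),
            pd.DataFrame({"chrom": contig, "start": gs, "end": ge}),
        )
        d[overlap] = 0.0
        near = np.where(overlap, -1.0, d)  # -1 marks overlap
        dist[g.index.to_numpy()] = near
    labels = np.where(
        dist < 0,
        "overlapping",
        np.where(dist <= 10_000, "<=10kb", np.where(dist <= 100_000, "10-100kb", ">100kb")),
    )
    frac = pd.Series(labels).value_counts(normalize=True)
    return frac.reindex(bins, fill_value=0.0)


def repeat_family(name: str) -> str:
    """Family = leading alphabetic run of the repeat name (Alu-12 -> Alu)."""
    out = []
    for ch in name:
        if ch.isalpha():
            out.append(ch)
        else:
            break
    return "".join(out) or "other"


def _random_controls(
    widths: np.ndarray, genome_sizes: dict[str, int], n_controls: int, rng
) -> pd.DataFrame:
    """Random genomic intervals whose width distribution replicates the AP
    widths exactly (tiled, then truncated/shuffled)."""
    reps = int(np.ceil(n_controls / len(widths)))
    w = np.tile(widths, reps)[:n_controls]
    rng.shuffle(w)
    contigs = list(genome_sizes)
    sizes = np.array([genome_sizes[c] for c in contigs], dtype=float)
    probs = sizes / sizes.sum()
    ci = rng.choice(len(contigs), size=n_controls, p=probs)
    starts = np.array(
        [rng.integers(0, max(1, genome_sizes[contigs[c]] - wi)) for c, wi in zip(ci, w)]
    )
    return pd.DataFrame(
        {
            "chrom": [contigs[c] for c in ci],
            "start": starts,
            "end": starts + w,
        }
    ).sort_values(["chrom", "start"]).reset_index(drop=True)


def repeat_enrichment(
    ap_peaks: pd.DataFrame,
    repeat_track: pd.DataFrame,
    genome_sizes: dict[str, int],
    n_controls: int | None = None,
    seed: int = 0,
    min_family_share: float = 0.05,
) -> pd.DataFrame:
    """Repeat-family enrichment in AP peaks versus width-matched controls.

    Families (grouped by repeat name prefix) whose share of AP-overlapping
    repeats is below ``min_family_share`` are merged into "other". Enrichment
    is the family's frequency among repeats overlapping AP peaks divided by
    its frequency among repeats overlapping random control intervals drawn
    with the same width distribution.
    """
    if len(ap_peaks) == 0:
        raise ValueError("repeat_enrichment requires a non-empty AP track")
    rng = np.random.default_rng(seed)
    widths = (ap_peaks["end"] - ap_peaks["start"]).to_numpy()
    if n_controls is None:
        n_controls = 10 * len(ap_peaks)
    controls = _random_controls(widths, genome_sizes, n_controls, rng)

    from .compare import merge_intervals

    rep = repeat_track.reset_index(drop=True).copy()
    rep["family"] = [repeat_family(n) for n in rep["name"]]
    ap_merged = merge_intervals(
        ap_peaks[["chrom", "start", "end"]].sort_values(["chrom", "start"])
    )
    ctl_merged = merge_intervals(controls[["chrom", "start", "end"]])
    in_ap = _overlaps_any(rep, ap_merged)
    in_ctl = _overlaps_any(rep, ctl_merged)

    ap_counts = rep.loc[in_ap, "family"].value_counts()
    ctl_counts = rep.loc[in_ctl, "family"].value_counts()
    if ap_counts.sum() == 0 or ctl_counts.sum() == 0:
        raise ValueError("no repeats overlap the AP peaks or the controls")
    share = ap_counts / ap_counts.sum()
    major = share[share >= min_family_share].index

    def collapse(counts):
        grouped = {}
        for fam, c in counts.items():
            key = fam if fam in major else "other"
            grouped[key] = grouped.get(key, 0) + c
        return pd.Series(grouped, dtype=float)

    ap_g = collapse(ap_counts)
    ctl_g = collapse(ctl_counts)
    fams = sorted(set(ap_g.index) | set(ctl_g.index))
    ap_f = ap_g.reindex(fams, fill_value=0.0) / ap_g.sum()
    ctl_f = ctl_g.reindex(fams, fill_value=0.0) / ctl_g.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(ctl_f > 0, ap_f / ctl_f, np.inf)
    return pd.DataFrame(
        {
            "family": fams,
            "freq_ap": ap_f.to_numpy(),
            "freq_control": ctl_f.to_numpy(),
            "enrichment": enr,
        }
    )


def confident_filter(peaks: pd.DataFrame, threshold: float = 4.0) -> pd.DataFrame:
    """Keep peaks whose natural-log score reaches ``threshold`` (default 4.0,
    i.e. score >= ~55); non-positive scores are dropped with a warning."""
    score = peaks["score"].to_numpy(float)
    bad = score <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} peaks with non-positive score")
    keep = np.zeros(len(peaks), dtype=bool)
    ok = ~bad
    keep[ok] = np.log(score[ok]) >= threshold
    return peaks.reset_index(drop=True).loc[keep].reset_index(drop=True)


def q_rank_curves(ap_tracks: dict[str, pd.DataFrame], step: int = 5) -> pd.DataFrame:
    """Cumulative top-n q-value curves per AP track.

    Each track's peaks are ranked by descending -log10(q); for n = step,
    2*step, ... the mean and minimum -log10(q) of the top n peaks are
    reported. The minimum column is non-increasing in n by construction.
    """
    rows = []
    for track_name, df in ap_tracks.items():
        q = np.sort(df["neg_log10_q"].to_numpy(float))[::-1]
        if len(q) == 0:
            continue
        ns = list(range(step, len(q) + 1, step))
        if not ns or ns[-1] != len(q):
            ns.append(len(q))
        for n in ns:
            top = q[:n]
            rows.append(
                {
                    "track": track_name,
                    "n": n,
                    "min_neg_log10_q": float(top.min()),
                    "mean_neg_log10_q": float(top.mean()),
                }
            )
    return pd.DataFrame(rows)
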