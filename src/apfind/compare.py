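"""Classify peaks as common / personal-only / ref-only, annotate them with
variant and read counts, and compare read alignments between genomes.

All tracks are BED-like DataFrames in a shared coordinate system (peaks
lifted or surjected beforehand). Overlap means >= 1 bp: any partial overlap
of a personal peak with a reference peak makes it common, regardless of read
depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .liftover import LiftConfig, lift_reads
from .types import Chain, ChangedMappingSummary

CATEGORIES = ("common", "personal_only", "ref_only")


def _validate_track(df: pd.DataFrame, label: str) -> None:
    for contig, sub in df.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if np.any(np.diff(s) < 0):
            raise ValueError(f"{label} track is not position-sorted on {contig}")
        if np.any(e[:-1] > s[1:]):
            raise ValueError(f"{label} track has overlapping peaks on {contig}")


def _overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: overlaps >= 1 bp with any subject interval.
    Subject intervals must be non-overlapping and sorted per contig."""
    out = np.zeros(len(query), dtype=bool)
    subj = {c: (g["start"].to_numpy(), g["end"].to_numpy()) for c, g in subject.groupby("chrom")}
    for contig, g in query.groupby("chrom"):
        if contig not in subj:
            continue
        ss, se = subj[contig]
        qs = g["start"].to_numpy()
        qe = g["end"].to_numpy()
        # a sorted non-overlapping subject interval overlaps [qs,qe) iff the
        # last interval starting before qe ends after qs
        i = np.searchsorted(ss, qe, side="left") - 1
        hit = (i >= 0) & (se[np.maximum(i, 0)] > qs)
        out[g.index.to_numpy()] = hit
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended intervals per contig (bedtools merge)."""
    rows = []
    for contig, g in df.sort_values(["chrom", "start"]).groupby("chrom"):
        cur_s = cur_e = None
        extra = {}
        for r in g.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, extra = r.start, r.end, r._asdict()
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                extra.update(start=cur_s, end=cur_e)
                rows.append(dict(extra))
                cur_s, cur_e, extra = r.start, r.end, r._asdict()
        if cur_s is not None:
            extra.update(start=cur_s, end=cur_e)
            rows.append(dict(extra))
    if not rows:
        return df.copy()
    return pd.DataFrame(rows)[df.columns]


def categorize_peaks(
    personal_track: pd.DataFrame, ref_track: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split two peak tracks into (common, personal_only, ref_only).

    A personal peak with any >= 1 bp overlap of a reference peak is common
    (counted once, from the personal side, even if it overlaps several
    reference peaks); zero-overlap personal peaks are personal-only and
    zero-overlap reference peaks are ref-only. Read depth plays no role.
    """
    _validate_track(personal_track, "personal")
    _validate_track(ref_track, "reference")
    p_hit = _overlaps_any(personal_track.reset_index(drop=True), ref_track)
    r_hit = _overlaps_any(ref_track.reset_index(drop=True), personal_track)
    common = personal_track.reset_index(drop=True).loc[p_hit].copy()
    personal_only = personal_track.reset_index(drop=True).loc[~p_hit].copy()
    ref_only = ref_track.reset_index(drop=True).loc[~r_hit].copy()
    common["category"] = "common"
    personal_only["category"] = "personal_only"
    ref_only["category"] = "ref_only"
    return (
        common.reset_index(drop=True),
        personal_only.reset_index(drop=True),
        ref_only.reset_index(drop=True),
    )


def annotate_counts(
    peaks: pd.DataFrame, feature_track: pd.DataFrame, column: str
) -> pd.DataFrame:
    """bedtools intersect -c: count features overlapping each peak by >= 1 bp,
    stored in ``column``. Features may overlap one another."""
    out = peaks.copy()
    counts = np.zeros(len(peaks), dtype=np.int64)
    if len(feature_track):
        feats = {
            c: (np.sort(g["start"].to_numpy()), np.sort(g["end"].to_numpy()))
            for c, g in feature_track.groupby("chrom")
        }
        idx = np.arange(len(out))
        for contig, g in out.reset_index(drop=True).groupby("chrom"):
            if contig not in feats:
                continue
            fs, fe = feats[contig]
            qs = g["start"].to_numpy()
            qe = g["end"].to_numpy()
            started_before_end = np.searchsorted(fs, qe, side="left")
            ended_before_start = np.searchsorted(fe, qs, side="right")
            counts[g.index.to_numpy()] = started_before_end - ended_before_start
    out[column] = counts
    return out


def ap_fraction(n_category: int, n_common: int) -> float:
    """Altered-peak percentage: 100 x n_category / (n_common + n_category),
    one decimal — the same-genome-total denominator convention."""
    if n_category < 0 or n_common < 0:
        raise ValueError("counts must be >= 0")
    if n_category + n_common == 0:
        raise ValueError("ap_fraction undefined for zero peaks")
    return round(100.0 * n_category / (n_common + n_category), 1)


def compare_mappings(
    reads_a: pd.DataFrame,
    reads_b: pd.DataFrame,
    chains: list[Chain],
    distance_threshold: int = 100,
    lift_config: LiftConfig | None = None,
) -> ChangedMappingSummary:
    """Proportion of reads whose mapping changes between two genomes.

    ``chains`` map genome A coordinates to genome B (identity chains when
    the genomes share coordinates). Per read id: present in only one track ->
    one-build-only; A-position fails to lift -> lift-fail; lifted positions
    more than ``distance_threshold`` bp apart -> far; else unchanged. The
    changed fraction is the sum of the three changed classes over all reads.
    """
    for df, label in ((reads_a, "A"), (reads_b, "B")):
        if df["name"].duplicated().any():
            raise ValueError(f"duplicate read ids in track {label}")
    names_a = set(reads_a["name"])
    names_b = set(reads_b["name"])
    n_total = len(names_a | names_b)
    n_one_build = len(names_a ^ names_b)

    shared = names_a & names_b
    a_shared = reads_a[reads_a["name"].isin(shared)]
    lifted, unlifted = lift_reads(a_shared, chains, lift_config)
    n_lift_fail = len(unlifted)

    b_pos = reads_b.set_index("name")[["chrom", "start"]]
    merged = lifted.merge(b_pos, left_on="name", right_index=True, suffixes=("", "_b"))
    far = (merged["chrom"] != merged["chrom_b"]) | (
        (merged["start"] - merged["start_b"]).abs() > distance_threshold
    )
    return ChangedMappingSummary(
        n_total=n_total,
        n_far=int(far.sum()),
        n_one_build_only=n_one_build,
        n_lift_fail=n_lift_fail,
    )
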