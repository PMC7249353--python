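"""Chi-square test for peaks with coverage skewed between two alignments.

One read set aligned to two assemblies gives paired counts per peak; because
there is only one library, overdispersion across experiments does not apply
and a plain two-cell goodness-of-fit chi-square (1 df) against library-size-
proportional expectations is appropriate. Peaks with zero coverage in one
alignment are assigned one read so the test is defined. No multiple-testing
correction is applied across peaks by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import SkewResult

VERDICTS = ("ref_skewed", "personal_skewed", "no_skew")


def chi2_skew(
    c_ref: int,
    c_personal: int,
    lib_ref: int,
    lib_personal: int,
    alpha: float = 0.05,
    peak_id: str = "",
) -> SkewResult:
    """Test one peak's read counts for skew between the two alignments.

    Expected counts split the observed total proportionally to the library
    totals (equal halves for equal libraries). Significant peaks are
    ref-skewed when the library-normalized reference count is higher,
    personal-skewed when lower.
    """
    if c_ref < 0 or c_personal < 0:
        raise ValueError("read counts must be >= 0")
    if lib_ref <= 0 or lib_personal <= 0:
        raise ValueError("library totals must be > 0")
    cr = max(int(c_ref), 1)  # pseudocount for null coverage
    cp = max(int(c_personal), 1)
    total = cr + cp
    f_ref = lib_ref / (lib_ref + lib_personal)
    expected = np.array([total * f_ref, total * (1.0 - f_ref)])
    observed = np.array([cr, cp], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    if p > alpha:
        verdict = "no_skew"
    elif cr / lib_ref > cp / lib_personal:
        verdict = "ref_skewed"
    else:
        verdict = "personal_skewed"
    return SkewResult(
        peak_id=peak_id,
        c_ref=cr,
        c_personal=cp,
        chi2_stat=chi2,
        p_value=p,
        verdict=verdict,
        alpha=alpha,
    )


def chi2_skew_vectorized(
    c_ref: np.ndarray,
    c_personal: np.ndarray,
    lib_ref: int,
    lib_personal: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized :func:`chi2_skew` over arrays of per-peak counts."""
    cr = np.maximum(np.asarray(c_ref, dtype=np.int64), 1)
    cp = np.maximum(np.asarray(c_personal, dtype=np.int64), 1)
    total = cr + cp
    f_ref = lib_ref / (lib_ref + lib_personal)
    e_ref = total * f_ref
    e_per = total * (1.0 - f_ref)
    chi2 = (cr - e_ref) ** 2 / e_ref + (cp - e_per) ** 2 / e_per
    p = stats.chi2.sf(chi2, df=1)
    verdict = np.where(
        p > alpha,
        "no_skew",
        np.where(cr / lib_ref > cp / lib_personal, "ref_skewed", "personal_skewed"),
    )
    return pd.DataFrame(
        {"c_ref": cr, "c_personal": cp, "chi2_stat": chi2, "p_value": p, "verdict": verdict}
    )


def classify_skew(
    peaks: pd.DataFrame,
    lib_ref: int,
    lib_personal: int,
    alpha: float = 0.05,
    correct_fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the skew test to annotated peaks and tally verdicts per category.

    ``peaks`` must carry ``n_reads_ref``, ``n_reads_personal`` and
    ``category`` columns. Returns ``(per_peak, summary)`` where the summary
    counts ref_skewed / personal_skewed / no_skew within each of common /
    personal_only / ref_only. By default each peak is tested at raw alpha
    (no correction across peaks); ``correct_fdr`` switches to comparing
    Benjamini-Hochberg q-values against alpha instead.
    """
    if len(peaks) == 0:
        empty = pd.DataFrame(columns=["category", *VERDICTS])
        return peaks.copy(), empty
    res = chi2_skew_vectorized(
        peaks["n_reads_ref"].to_numpy(),
        peaks["n_reads_personal"].to_numpy(),
        lib_ref,
        lib_personal,
        alpha,
    )
    if correct_fdr:
        p = res["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.clip(q_sorted, 0, 1)
        res["q_value"] = q
        res["verdict"] = np.where(
            q > alpha,
            "no_skew",
            np.where(
                res["c_ref"] / lib_ref > res["c_personal"] / lib_personal,
                "ref_skewed",
                "personal_skewed",
            ),
        )
    per_peak = peaks.reset_index(drop=True).join(
        res[["chi2_stat", "p_value", "verdict"]]
    )
    summary = (
        per_peak.groupby(["category", "verdict"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(VERDICTS), fill_value=0)
        .reset_index()
    )
    summary.columns.name = None
    return per_peak, summary
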