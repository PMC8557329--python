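"""Section- and subject-level aggregation of per-fiber records.

A section summary carries the unweighted mean of per-fiber ring intensities,
the percent of positive fibers, the four coverage-bin fractions with per-bin
mean intensities, and ECDFs of intensity and coverage.  A subject record
averages exactly two replicate serial sections (mean ± sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dysquant.fiberquant import BIN_NAMES


class SummaryError(ValueError):
    pass


def ecdf(values) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted values and cumulative fractions
    ending at 1."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise SummaryError("ecdf of empty sample")
    fractions = np.arange(1, arr.size + 1) / arr.size
    return arr, fractions


@dataclass
class SectionSummary:
    n_fibers: int
    mean_intensity: float
    pct_positive: float
    bin_fractions: np.ndarray  # 4 fractions summing to 1
    bin_mean_intensity: np.ndarray  # 4 AU values, NaN for empty bins
    ecdf_intensity: tuple[np.ndarray, np.ndarray]
    ecdf_coverage: tuple[np.ndarray, np.ndarray]
    metadata: dict = field(default_factory=dict)


@dataclass
class SubjectRecord:
    subject_id: str
    phenotype: str
    replicates: tuple[SectionSummary, SectionSummary]
    mean_intensity: float
    mean_intensity_sd: float
    pct_positive: float
    pct_positive_sd: float


def summarize_section(records: pd.DataFrame, metadata: dict | None = None) -> SectionSummary:
    """Aggregate a per-fiber record table into one SectionSummary.

    The section intensity is the unweighted mean over fibers (not a
    pixel-weighted whole-section mean), matching per-fiber reporting
    granularity.
    """
    if len(records) == 0:
        raise SummaryError("cannot summarize an empty record list")
    n = len(records)
    bin_counts = records["bin"].value_counts()
    fractions = np.array([bin_counts.get(b, 0) / n for b in BIN_NAMES])
    bin_means = np.array(
        [
            float(records.loc[records["bin"] == b, "mean_intensity_au"].mean())
            if bin_counts.get(b, 0) > 0
            else float("nan")
            for b in BIN_NAMES
        ]
    )
    return SectionSummary(
        n_fibers=n,
        mean_intensity=float(records["mean_intensity_au"].mean()),
        pct_positive=100.0 * float(records["positive"].mean()),
        bin_fractions=fractions,
        bin_mean_intensity=bin_means,
        ecdf_intensity=ecdf(records["mean_intensity_au"]),
        ecdf_coverage=ecdf(records["coverage_pct"]),
        metadata=dict(metadata or {}),
    )


def _mean_sd(a: float, b: float) -> tuple[float, float]:
    # sample SD over two replicate values: |a - b| / sqrt(2)
    return (a + b) / 2.0, abs(a - b) / np.sqrt(2.0)


def summarize_subject(
    rep1: SectionSummary,
    rep2: SectionSummary,
    subject_id: str = "",
    phenotype: str = "",
    *more: SectionSummary,
) -> SubjectRecord:
    """Mean ± sample SD over exactly two replicate serial sections."""
    if more:
        raise SummaryError(
            f"subject {subject_id or '?'}: expected exactly 2 replicate "
            f"sections, got {2 + len(more)}"
        )
    mi, mi_sd = _mean_sd(rep1.mean_intensity, rep2.mean_intensity)
    pp, pp_sd = _mean_sd(rep1.pct_positive, rep2.pct_positive)
    return SubjectRecord(
        subject_id=subject_id,
        phenotype=phenotype,
        replicates=(rep1, rep2),
        mean_intensity=mi,
        mean_intensity_sd=mi_sd,
        pct_positive=pp,
        pct_positive_sd=pp_sd,
    )


def section_summary_frame(summary: SectionSummary) -> pd.DataFrame:
    """One-row DataFrame view of a SectionSummary for CSV export."""
    row = {
        "n_fibers": summary.n_fibers,
        "mean_intensity_au": summary.mean_intensity,
        "pct_positive": summary.pct_positive,
    }
    for name, frac, bmean in zip(
        BIN_NAMES, summary.bin_fractions, summary.bin_mean_intensity
    ):
        row[f"frac_{name}"] = frac
        row[f"mean_intensity_{name}"] = bmean
    return pd.DataFrame([row])


def subject_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table: one row per subject, mean ± SD over the 2 replicates."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "phenotype": s.phenotype,
                "mean_intensity_au": s.mean_intensity,
                "mean_intensity_sd": s.mean_intensity_sd,
                "pct_positive": s.pct_positive,
                "pct_positive_sd": s.pct_positive_sd,
            }
            for s in subjects
        ]
    )
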