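"""Scoring of pooled CRISPR 3'UTR dissection experiments.

A dissection library is a pool of cells each carrying one deletion in a
3'UTR amplicon; the RNA/gDNA amplicon read ratio of a deletion reads out
the cis-regulatory activity of the deleted span (ratio > 1: the span was
destabilising).  This module filters mutants, forms median-normalised
RNA/gDNA ratios, and converts the per-mutant table into per-nucleotide
effect and significance tracks:

    effect[i] = log2( median ratio of deletions spanning i
                      / median ratio of all retained deletions )

with a Welch two-sample t-test (spanning vs non-spanning deletions)
providing an unadjusted -log10 p per nucleotide.

Filters: 20 < deletion length < 250 nt (strict); >= 10 reads in both
RNA and gDNA amplicons; median-normalised ratio <= 10 (larger values are
outliers).  Counts are library-size normalised within each experiment
before ratios are formed, and the median is the usual even-n convention
(mean of the two middle values).

Mutant tables are plain pandas DataFrames with columns
``mut_id, experiment, start, end, rna_reads, dna_reads`` (the TSV layout
read by :func:`read_mutant_table`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "MUTANT_COLUMNS",
    "DissectionResult",
    "read_mutant_table",
    "normalize_ratios",
    "filter_mutants",
    "welch_ttest",
    "per_nucleotide_effect",
    "per_nucleotide_test",
    "dissect",
]

MUTANT_COLUMNS = ["mut_id", "experiment", "start", "end", "rna_reads", "dna_reads"]


@dataclass
class DissectionResult:
    """Per-nucleotide tracks plus the audited per-mutant table."""

    amplicon_length: int
    effect: np.ndarray
    neglog10_p: np.ndarray
    n_spanning: np.ndarray
    mutants: pd.DataFrame
    n_retained: int
    n_filtered_length: int
    n_filtered_reads: int
    n_filtered_outlier: int


def read_mutant_table(path: str) -> pd.DataFrame:
    """Read a mutant TSV (mut_id, experiment, start, end, rna_reads,
    dna_reads); a header line is detected and honoured."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:6]) != MUTANT_COLUMNS:
        df = pd.read_csv(path, sep="\t", header=None, names=MUTANT_COLUMNS)
    df = df[MUTANT_COLUMNS].copy()
    for col in ("start", "end", "rna_reads", "dna_reads"):
        df[col] = df[col].astype(np.int64)
    return df


def normalize_ratios(muts: pd.DataFrame) -> pd.Series:
    """Median-normalised RNA/gDNA ratio for each mutant.

    Counts are first normalised to library size within the given table
    (ratio_m = (rna_m / sum RNA) / (dna_m / sum DNA)), then divided by
    the median ratio.  The caller passes the mutants of one experiment
    that already survived the length and read filters; sums and median
    are taken over exactly those rows.
    """
    rna = muts["rna_reads"].to_numpy(dtype=float)
    dna = muts["dna_reads"].to_numpy(dtype=float)
    if dna.sum() == 0:
        raise ValueError("all-zero gDNA counts: ratios undefined")
    if rna.sum() == 0:
        raise ValueError("all-zero RNA counts: ratios undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (rna / rna.sum()) / (dna / dna.sum())
    med = float(np.median(ratio))
    if med == 0 or not np.isfinite(med):
        raise ValueError("median ratio degenerate; cannot normalise")
    return pd.Series(ratio / med, index=muts.index, name="norm_ratio")


def filter_mutants(
    muts: pd.DataFrame,
    min_len: int = 20,
    max_len: int = 250,
    min_reads: int = 10,
    max_ratio: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three mutant filters and annotate normalised ratios.

    Retained iff min_len < length < max_len (strict), rna and dna reads
    each >= min_reads, and median-normalised ratio <= max_ratio.
    Normalisation is computed once per experiment over the length/read-
    filtered rows and is not recomputed after outlier removal.  Filter
    counts are attributed in the order length -> reads -> outlier.

    Returns the table with added ``norm_ratio``, ``retained`` and
    ``filter_reason`` columns, plus the per-rule counts.
    """
    df = muts.copy()
    if (df["start"] >= df["end"]).any():
        raise ValueError("mutant with start >= end")
    length = df["end"] - df["start"]
    len_ok = (length > min_len) & (length < max_len)
    reads_ok = (df["rna_reads"] >= min_reads) & (df["dna_reads"] >= min_reads)
    base = len_ok & reads_ok

    df["norm_ratio"] = np.nan
    for _, idx in df[base].groupby("experiment").groups.items():
        df.loc[idx, "norm_ratio"] = normalize_ratios(df.loc[idx])

    outlier = base & (df["norm_ratio"] > max_ratio)
    df["retained"] = base & ~outlier
    df["filter_reason"] = ""
    df.loc[~len_ok, "filter_reason"] = "length"
    df.loc[len_ok & ~reads_ok, "filter_reason"] = "reads"
    df.loc[outlier, "filter_reason"] = "outlier"

    counts = {
        "length": int((~len_ok).sum()),
        "reads": int((len_ok & ~reads_ok).sum()),
        "outlier": int(outlier.sum()),
    }
    return df, counts


def welch_ttest(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns (t, df, p).  Each group needs >= 2 observations, else all
    NaN.  When both groups have zero variance: equal means -> p = 1
    (t = 0); unequal means -> p = 0 (t = +/-inf).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return (np.nan, np.nan, np.nan)
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / len(x) + v2 / len(y)
    if se2 == 0:
        if m1 == m2:
            return (0.0, np.nan, 1.0)
        return (np.inf if m1 > m2 else -np.inf, np.nan, 0.0)
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / len(x)) ** 2 / (len(x) - 1) + (v2 / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return (float(t), float(df), min(p, 1.0))


def _span_matrix(starts, ends, amplicon_length: int) -> np.ndarray:
    """Boolean (n_mutants, amplicon_length): mutant m deletes base i iff
    start_m <= i < end_m."""
    pos = np.arange(amplicon_length)
    return (starts[:, None] <= pos[None, :]) & (pos[None, :] < ends[:, None])


def per_nucleotide_effect(
    retained: pd.DataFrame,
    amplicon_length: int,
) -> np.ndarray:
    """log2 of the spanning-median over the global-median ratio, per
    nucleotide; NaN where no retained deletion spans the base."""
    if len(retained) == 0:
        raise ValueError("no retained mutants")
    ratios = retained["norm_ratio"].to_numpy(dtype=float)
    spans = _span_matrix(
        retained["start"].to_numpy(), retained["end"].to_numpy(), amplicon_length
    )
    global_med = float(np.median(ratios))
    effect = np.full(amplicon_length, np.nan)
    for i in range(amplicon_length):
        sel = spans[:, i]
        if sel.any():
            effect[i] = np.log2(np.median(ratios[sel]) / global_med)
    return effect


def per_nucleotide_test(
    retained: pd.DataFrame,
    amplicon_length: int,
) -> np.ndarray:
    """Unadjusted -log10 p from Welch's t-test of spanning vs
    non-spanning normalised ratios, per nucleotide; NaN where either
    group has fewer than two mutants."""
    ratios = retained["norm_ratio"].to_numpy(dtype=float)
    spans = _span_matrix(
        retained["start"].to_numpy(), retained["end"].to_numpy(), amplicon_length
    )
    out = np.full(amplicon_length, np.nan)
    for i in range(amplicon_length):
        sel = spans[:, i]
        _, _, p = welch_ttest(ratios[sel], ratios[~sel])
        if np.isfinite(p) and p > 0:
            out[i] = -np.log10(p)
        elif p == 0:
            out[i] = np.inf
    return out


def dissect(
    muts: pd.DataFrame,
    amplicon_length: int,
    pool_experiments: bool = True,
) -> DissectionResult:
    """Full dissection scoring: filter, normalise, per-nucleotide effect
    and significance tracks.

    With ``pool_experiments`` (the default) the replicate experiments'
    self-normalised ratios are concatenated before the per-nucleotide
    statistics; otherwise only the first experiment is scored.
    """
    audited, counts = filter_mutants(muts)
    retained = audited[audited["retained"]]
    if not pool_experiments:
        first = audited["experiment"].iloc[0]
        retained = retained[retained["experiment"] == first]
    if len(retained) == 0:
        raise ValueError("no mutants retained after filtering")
    spans = _span_matrix(
        retained["start"].to_numpy(), retained["end"].to_numpy(), amplicon_length
    )
    return DissectionResult(
        amplicon_length=amplicon_length,
        effect=per_nucleotide_effect(retained, amplicon_length),
        neglog10_p=per_nucleotide_test(retained, amplicon_length),
        n_spanning=spans.sum(axis=0),
        mutants=audited,
        n_retained=int(len(retained)),
        n_filtered_length=counts["length"],
        n_filtered_reads=counts["reads"],
        n_filtered_outlier=counts["outlier"],
    )
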