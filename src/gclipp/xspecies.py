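"""Biochemically shared peaks on pairwise-aligned 3'UTRs.

Occupancy tracks from two species (e.g. human Jurkat and primary mouse
T cells) are projected onto the columns of a pairwise UTR alignment.
Read density is normalised within each UTR to the fraction of its
maximal depth, and each alignment column is scored by the sum of three
Spearman rank correlations over the window centred on it:

    score = rho(norm_a, norm_b) + rho(norm_a, template) + rho(norm_b, template)

where the template is a Gaussian centred on the column.  The first term
rewards concordant occupancy across species; the template terms favour
columns sitting on a clear local peak in each species.  Shared peaks are
local maxima of this score that pass high-stringency filters:
cross-species rho > 0.75, normalised density > 0.5 in one species and
> 0.2 in the other, and > 10 reads at the column in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coverage import CoverageTrack, UTRAnnotation
from .peakcall import gaussian_template, local_maxima

__all__ = [
    "StringencyParams",
    "AlignedUTRPair",
    "SharedPeak",
    "load_alignment",
    "shared_score_profile",
    "passes_stringency",
    "call_shared_peaks",
    "shared_peaks_table",
]

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class StringencyParams:
    """Window geometry and high-stringency filters for shared peaks.

    All three filter thresholds are strict (>): a candidate with
    cross-species rho exactly 0.75, or exactly 10 reads, is rejected.
    """

    min_rho_ab: float = 0.75
    min_norm_major: float = 0.5
    min_norm_minor: float = 0.2
    min_raw: int = 10
    window: int = 71
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 5")

    @property
    def sigma_(self) -> float:
        return self.window / 6.0 if self.sigma is None else self.sigma


@dataclass
class AlignedUTRPair:
    """Alignment columns carrying both species' densities.

    ``pos_a[c]`` / ``pos_b[c]`` give the ungapped (transcript) offset of
    column c in each species, or -1 where that species is gapped.  Gap
    columns carry raw and normalised density 0: absent sequence cannot
    be occupied.
    """

    utr_id_a: str
    utr_id_b: str
    seq_a: str
    seq_b: str
    raw_a: np.ndarray
    raw_b: np.ndarray
    norm_a: np.ndarray
    norm_b: np.ndarray
    pos_a: np.ndarray
    pos_b: np.ndarray
    utr_a: UTRAnnotation | None = None
    utr_b: UTRAnnotation | None = None

    def __len__(self) -> int:
        return len(self.seq_a)

    def swapped(self) -> "AlignedUTRPair":
        """The same alignment with species a and b exchanged."""
        return AlignedUTRPair(
            self.utr_id_b, self.utr_id_a, self.seq_b, self.seq_a,
            self.raw_b, self.raw_a, self.norm_b, self.norm_a,
            self.pos_b, self.pos_a, self.utr_b, self.utr_a,
        )


@dataclass(frozen=True)
class SharedPeak:
    """One biochemically shared peak at an alignment column."""

    column: int
    score: float
    rho_ab: float
    rho_a_tmpl: float
    rho_b_tmpl: float
    norm_a: float
    norm_b: float
    raw_a: int
    raw_b: int
    utr_id_a: str = ""
    utr_id_b: str = ""
    genomic_pos_a: int | None = None
    genomic_pos_b: int | None = None


def _project(seq: str, depth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project an ungapped track onto gapped-alignment columns."""
    raw = np.zeros(len(seq), dtype=float)
    pos = np.full(len(seq), -1, dtype=np.int64)
    k = 0
    for c, base in enumerate(seq):
        if base not in GAP_CHARS:
            raw[c] = depth[k]
            pos[c] = k
            k += 1
    return raw, pos


def load_alignment(
    fasta_path: str,
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    utr_a: UTRAnnotation | None = None,
    utr_b: UTRAnnotation | None = None,
) -> AlignedUTRPair:
    """Load a two-record gapped FASTA and project both coverage tracks
    onto its columns.

    The records' ungapped lengths must match the track lengths; gap
    columns get density 0 for the gapped species.  Normalised density is
    depth / max depth within the UTR (0 if the UTR maximum is 0).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"{fasta_path}: expected exactly 2 aligned records, got {len(records)}"
        )
    seq_a, seq_b = str(records[0].seq).upper(), str(records[1].seq).upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"{fasta_path}: gapped lengths differ")
    for rec, seq, track in ((records[0], seq_a, track_a), (records[1], seq_b, track_b)):
        ungapped = sum(1 for b in seq if b not in GAP_CHARS)
        if ungapped != len(track):
            raise ValueError(
                f"{fasta_path}: record {rec.id!r} has {ungapped} ungapped "
                f"bases but track {track.utr_id!r} has length {len(track)}"
            )

    raw_a, pos_a = _project(seq_a, np.asarray(track_a.depth, dtype=float))
    raw_b, pos_b = _project(seq_b, np.asarray(track_b.depth, dtype=float))
    max_a = np.asarray(track_a.depth).max() if len(track_a) else 0
    max_b = np.asarray(track_b.depth).max() if len(track_b) else 0
    norm_a = raw_a / max_a if max_a > 0 else np.zeros_like(raw_a)
    norm_b = raw_b / max_b if max_b > 0 else np.zeros_like(raw_b)
    return AlignedUTRPair(
        track_a.utr_id, track_b.utr_id, seq_a, seq_b,
        raw_a, raw_b, norm_a, norm_b, pos_a, pos_b, utr_a, utr_b,
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties; NaN if either side is
    constant (rank correlation undefined)."""
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float((rxc @ ryc) / np.sqrt((rxc**2).sum() * (ryc**2).sum()))


def shared_score_profile(
    pair: AlignedUTRPair,
    params: StringencyParams = StringencyParams(),
) -> pd.DataFrame:
    """Per-column three-Spearman score with its components.

    For each column, over the window centred on it (truncated at the
    alignment ends, minimum window // 2 columns): the cross-species
    Spearman of normalised densities plus each species' Spearman against
    the Gaussian template.  Columns whose window is constant in any
    input get NaN for the affected terms and a NaN total score.
    """
    n = len(pair)
    w = params.window
    flank = w // 2
    min_pts = w // 2
    tmpl = gaussian_template(w, params.sigma_)

    cols = {
        "rho_ab": np.full(n, np.nan),
        "rho_a_tmpl": np.full(n, np.nan),
        "rho_b_tmpl": np.full(n, np.nan),
    }
    for i in range(n):
        lo, hi = max(0, i - flank), min(n, i + flank + 1)
        if hi - lo < min_pts:
            continue
        wa = pair.norm_a[lo:hi]
        wb = pair.norm_b[lo:hi]
        wt = tmpl[lo - (i - flank) : hi - (i - flank)]
        cols["rho_ab"][i] = _spearman(wa, wb)
        cols["rho_a_tmpl"][i] = _spearman(wa, wt)
        cols["rho_b_tmpl"][i] = _spearman(wb, wt)
    df = pd.DataFrame(cols)
    df["score"] = df["rho_ab"] + df["rho_a_tmpl"] + df["rho_b_tmpl"]
    return df


def passes_stringency(
    rho_ab: float,
    norm_a: float,
    norm_b: float,
    raw_a: float,
    raw_b: float,
    params: StringencyParams = StringencyParams(),
) -> bool:
    """The high-stringency filter applied to each candidate column.

    All comparisons are strict: rho_ab > min_rho_ab; the larger
    normalised density > min_norm_major and the smaller > min_norm_minor
    (species-symmetric by construction); raw depth > min_raw in both.
    """
    if not rho_ab > params.min_rho_ab:
        return False
    if not (max(norm_a, norm_b) > params.min_norm_major
            and min(norm_a, norm_b) > params.min_norm_minor):
        return False
    return raw_a > params.min_raw and raw_b > params.min_raw


def call_shared_peaks(
    pair: AlignedUTRPair,
    params: StringencyParams = StringencyParams(),
) -> list[SharedPeak]:
    """Local maxima of the three-Spearman score passing all stringency
    filters, sorted by column.

    Filters, evaluated at the peak column itself: rho_ab > min_rho_ab;
    max(norm_a, norm_b) > min_norm_major and min(norm_a, norm_b) >
    min_norm_minor; raw depth > min_raw in both species.  Genomic
    coordinates are reported for each species where the column is not a
    gap and a UTR annotation is attached.
    """
    profile = shared_score_profile(pair, params)
    score = profile["score"].to_numpy()
    peaks = []
    for c in local_maxima(score):
        na, nb = float(pair.norm_a[c]), float(pair.norm_b[c])
        ra, rb = float(pair.raw_a[c]), float(pair.raw_b[c])
        rho_ab = float(profile["rho_ab"].iloc[c])
        if np.isnan(rho_ab) or not passes_stringency(rho_ab, na, nb, ra, rb, params):
            continue
        gpos_a = gpos_b = None
        if pair.utr_a is not None and pair.pos_a[c] >= 0:
            gpos_a = pair.utr_a.to_genomic(int(pair.pos_a[c]))
        if pair.utr_b is not None and pair.pos_b[c] >= 0:
            gpos_b = pair.utr_b.to_genomic(int(pair.pos_b[c]))
        peaks.append(
            SharedPeak(
                column=c,
                score=float(score[c]),
                rho_ab=rho_ab,
                rho_a_tmpl=float(profile["rho_a_tmpl"].iloc[c]),
                rho_b_tmpl=float(profile["rho_b_tmpl"].iloc[c]),
                norm_a=na, norm_b=nb, raw_a=int(ra), raw_b=int(rb),
                utr_id_a=pair.utr_id_a, utr_id_b=pair.utr_id_b,
                genomic_pos_a=gpos_a, genomic_pos_b=gpos_b,
            )
        )
    return peaks


def shared_peaks_table(peaks: list[SharedPeak]) -> pd.DataFrame:
    """Shared peaks as a tidy DataFrame (one row per peak)."""
    return pd.DataFrame([p.__dict__ for p in peaks])
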