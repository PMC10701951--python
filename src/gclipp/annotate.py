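"""Peak annotation: conservation metaprofiles, motif-window enrichment,
variant-in-peak intersection and distance-to-stop-codon CDFs.

These are the downstream characterisations of a called peak set:

* ``conservation_profile`` — mean per-offset conservation (e.g. PhyloP)
  in windows centred on peaks, standardised across offsets to mean 0 /
  sd 1 so profiles from different assays are comparable.
* ``motif_enrichment`` — IUPAC consensus motif occurrence in short
  windows centred on sites, against the background frequency over the
  full 3'UTR set, with a one-sided binomial enrichment p-value.
* ``variants_in_peaks`` — SNPs falling inside peak intervals inside
  annotated UTRs.
* ``distance_to_stop_cdf`` — empirical CDF of region distances from the
  translation stop codon (the 5' end of the 3'UTR).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom

from .coverage import UTRAnnotation

__all__ = [
    "ConservationProfile",
    "conservation_profile",
    "iupac_regex",
    "motif_enrichment",
    "variants_in_peaks",
    "distance_to_stop_cdf",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass
class ConservationProfile:
    """Peak-centred conservation metaprofile.

    ``offsets`` run -half_width..+half_width; ``normalized`` is the
    per-offset mean standardised across offsets (mean 0, sample sd 1).
    """

    offsets: np.ndarray
    mean_score: np.ndarray
    normalized: np.ndarray
    n_peaks: int


def conservation_profile(
    peak_centers: list[tuple[str, int]],
    cons_track: dict[str, np.ndarray],
    half_width: int = 100,
) -> ConservationProfile:
    """Average conservation around peak centres, standardised across
    offsets.

    ``peak_centers`` are (chrom, position) pairs; ``cons_track`` maps a
    chromosome to its per-base score vector.  Windows truncated by track
    ends contribute only their defined offsets.  If the per-offset means
    are constant the normalised profile is all zeros (with a warning).
    """
    offsets = np.arange(-half_width, half_width + 1)
    sums = np.zeros(len(offsets))
    counts = np.zeros(len(offsets), dtype=np.int64)
    n_used = 0
    for chrom, center in peak_centers:
        track = cons_track.get(chrom)
        if track is None:
            continue
        pos = center + offsets
        ok = (pos >= 0) & (pos < len(track))
        if not ok.any():
            continue
        sums[ok] += track[pos[ok]]
        counts[ok] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no peak overlaps the conservation track")
    with np.errstate(invalid="ignore"):
        mean_score = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    defined = np.isfinite(mean_score)
    mu = mean_score[defined].mean()
    sd = mean_score[defined].std(ddof=1) if defined.sum() > 1 else 0.0
    if sd == 0:
        warnings.warn("degenerate conservation profile (sd = 0); zeros returned",
                      stacklevel=2)
        normalized = np.where(defined, 0.0, np.nan)
    else:
        normalized = (mean_score - mu) / sd
    return ConservationProfile(offsets, mean_score, normalized, n_used)


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC consensus (DNA or RNA alphabet) to a regex over
    DNA; matching is done with a lookahead so overlapping hits count."""
    try:
        body = "".join(IUPAC[ch] for ch in motif.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in {motif!r}") from None
    return re.compile(f"(?=({body}))")


def _window_contains(seq: str, pattern: re.Pattern, motif_len: int,
                     window: int) -> np.ndarray:
    """Boolean per window start: does seq[i : i + window] contain a
    match?  A window contains a match iff some match starts within
    [i, i + window - motif_len]."""
    n_windows = len(seq) - window + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=bool)
    starts = np.zeros(len(seq), dtype=bool)
    for m in pattern.finditer(seq):
        starts[m.start()] = True
    span = window - motif_len + 1
    if span <= 0:
        return np.zeros(n_windows, dtype=bool)
    # window i contains a match start in [i, i+span)
    csum = np.concatenate([[0], np.cumsum(starts)])
    return (csum[np.arange(n_windows) + span] - csum[:n_windows]) > 0


def motif_enrichment(
    sites: list[tuple[str, int]],
    utr_sequences: dict[str, str],
    motifs: list[str],
    window: int = 8,
) -> pd.DataFrame:
    """Motif occurrence in windows centred on sites versus the full
    3'UTR background.

    ``sites`` are (utr_id, position) pairs; the window around a site is
    seq[pos - window//2 : pos + window//2] (even widths put the site at
    index window//2), truncated at sequence ends.  The background rate
    is the fraction of all window-length substrings of the background
    UTR set containing >= 1 match.  p is the one-sided binomial tail
    P(X >= site_hits | n_sites, background_rate).

    Returns one row per motif: motif, n_sites, site_hits, site_rate,
    background_rate, fold, p.  fold is +inf when only the background is
    empty of the motif, and NaN when both rates are 0.
    """
    half = window // 2
    seqs = {k: v.upper().replace("U", "T") for k, v in utr_sequences.items()}
    rows = []
    for motif in motifs:
        pattern = iupac_regex(motif)
        mlen = len(motif)
        site_hits = 0
        n_sites = 0
        for utr_id, pos in sites:
            seq = seqs.get(utr_id)
            if seq is None:
                continue
            lo, hi = max(0, pos - half), min(len(seq), pos + window - half)
            n_sites += 1
            if pattern.search(seq[lo:hi]):
                site_hits += 1
        bg_hits = 0
        bg_total = 0
        for seq in seqs.values():
            contains = _window_contains(seq, pattern, mlen, window)
            bg_hits += int(contains.sum())
            bg_total += len(contains)
        site_rate = site_hits / n_sites if n_sites else np.nan
        bg_rate = bg_hits / bg_total if bg_total else np.nan
        if bg_rate and bg_rate > 0:
            fold = site_rate / bg_rate
            p = float(binom.sf(site_hits - 1, n_sites, bg_rate)) if n_sites else np.nan
        elif site_hits > 0:
            fold, p = np.inf, 0.0
        else:
            fold, p = np.nan, 1.0
        rows.append(
            dict(motif=motif, n_sites=n_sites, site_hits=site_hits,
                 site_rate=site_rate, background_rate=bg_rate, fold=fold, p=p)
        )
    return pd.DataFrame(rows)


def variants_in_peaks(
    variants: list[tuple[str, int, str]],
    peaks,
    utrs: list[UTRAnnotation],
) -> pd.DataFrame:
    """Variants whose position falls inside a peak interval inside an
    annotated 3'UTR; one row per (variant, peak) pair.

    ``variants`` are (chrom, 0-based position, id) triples; ``peaks``
    need chrom/start/end (``interval`` coordinates must already be
    genomic, e.g. the BED intervals written by the peak caller).
    Half-open convention: a variant at the peak start is inside, at the
    end it is not.
    """
    utr_trees: dict[str, IntervalTree] = {}
    for u in utrs:
        utr_trees.setdefault(u.chrom, IntervalTree()).addi(u.start, u.end, u)
    peak_trees: dict[str, IntervalTree] = {}
    for k, p in enumerate(peaks):
        peak_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, (k, p))
    rows = []
    for chrom, pos, vid in variants:
        utr_hits = utr_trees.get(chrom, IntervalTree()).at(pos)
        if not utr_hits:
            continue
        for iv in sorted(peak_trees.get(chrom, IntervalTree()).at(pos)):
            k, p = iv.data
            for uh in sorted(utr_hits, key=lambda h: h.data.utr_id):
                u = uh.data
                rows.append(
                    dict(variant=vid, chrom=chrom, pos=pos,
                         peak=getattr(p, "name", "") or f"peak{k}",
                         peak_start=p.start, peak_end=p.end,
                         utr_id=u.utr_id, gene=u.gene)
                )
    return pd.DataFrame(
        rows, columns=["variant", "chrom", "pos", "peak", "peak_start",
                       "peak_end", "utr_id", "gene"]
    )


def distance_to_stop_cdf(
    regions,
    utrs: list[UTRAnnotation],
) -> pd.DataFrame:
    """Empirical CDF of region distances from the stop codon.

    The stop codon abuts the 5' end of the 3'UTR, so the distance is the
    region start's transcript offset: genomic start minus UTR start on
    '+' UTRs, UTR end minus genomic end on '-' UTRs.  Regions outside
    their UTR are excluded with a warning.  Returns sorted distances
    with cumulative fractions.
    """
    by_id = {u.utr_id: u for u in utrs}
    trees: dict[str, IntervalTree] = {}
    for u in utrs:
        trees.setdefault(u.chrom, IntervalTree()).addi(u.start, u.end, u)
    distances = []
    n_excluded = 0
    for r in regions:
        u = by_id.get(getattr(r, "name", ""))
        if u is None:
            hits = [iv.data for iv in trees.get(r.chrom, IntervalTree())
                    .overlap(r.start, r.end)
                    if iv.data.start <= r.start and r.end <= iv.data.end]
            u = min(hits, key=lambda h: h.utr_id) if hits else None
        if u is None or r.start < u.start or r.end > u.end:
            n_excluded += 1
            continue
        if u.strand == "+":
            distances.append(r.start - u.start)
        else:
            distances.append(u.end - r.end)
    if n_excluded:
        warnings.warn(f"{n_excluded} region(s) outside all UTRs excluded",
                      stacklevel=2)
    distances.sort()
    n = len(distances)
    return pd.DataFrame(
        {"distance": distances,
         "cum_frac": [(k + 1) / n for k in range(n)] if n else []}
    )
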