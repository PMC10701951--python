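"""Seeded synthetic data emulating GCLiPP-style inputs, with ground truth.

Every generator is a pure function of its parameters and seed, producing
the same standard in-memory objects (and, via the CLI, the same text
formats) that the analysis modules consume:

* coverage tracks with planted Gaussian occupancy bumps over a Poisson
  background;
* pairwise-aligned species pairs sharing a subset of planted peaks;
* pooled deletion libraries with a planted cis-regulatory element whose
  removal multiplies the expected RNA/gDNA ratio;
* reference/query peak-set pairs with controlled overlap.

Defaults mirror the scale of real 3'UTR occupancy data: UTRs a few
hundred to ~1.5 kb long, ~10-nt-sigma occupancy footprints with peak
amplitude tens of deduplicated reads over a background of ~2 reads per
base, deletion spans of 21-249 nt with negative-binomially dispersed
amplicon counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, UTRAnnotation
from .overlapstat import GenomicInterval
from .xspecies import AlignedUTRPair, load_alignment

__all__ = [
    "SimTruth",
    "sim_coverage",
    "sim_species_pair",
    "sim_deletion_library",
    "sim_peak_sets",
    "write_alignment_fasta",
]


@dataclass
class SimTruth:
    """Machine-readable ground truth for one simulated dataset."""

    seed: int
    planted_peaks: list[tuple] = field(default_factory=list)
    shared_flags: list[bool] = field(default_factory=list)
    planted_element: tuple | None = None


def _bump(length: int, center: int, amplitude: float, sigma: float) -> np.ndarray:
    pos = np.arange(length, dtype=float)
    return amplitude * np.exp(-((pos - center) ** 2) / (2.0 * sigma**2))


def _pick_centers(rng, length: int, n: int, margin: int, min_sep: int) -> list[int]:
    """Rejection-sample ``n`` centers within [margin, length - margin)
    separated by at least ``min_sep``."""
    for _ in range(200):  # restart when early picks block all slots
        centers: list[int] = []
        for _ in range(50 * max(n, 1)):
            if len(centers) == n:
                return sorted(centers)
            c = int(rng.integers(margin, length - margin))
            if all(abs(c - o) >= min_sep for o in centers):
                centers.append(c)
        if len(centers) == n:
            return sorted(centers)
    raise ValueError(f"could not place {n} peaks in UTR of length {length}")


def sim_coverage(
    n_utrs: int = 50,
    utr_len_range: tuple[int, int] = (300, 1500),
    peaks_per_utr: int = 1,
    amplitude: float = 50.0,
    sigma: float = 10.0,
    noise_mean: float = 2.0,
    seed: int = 0,
) -> tuple[list[CoverageTrack], list[UTRAnnotation], SimTruth]:
    """Coverage tracks with planted Gaussian occupancy bumps.

    depth = round(sum of bumps) + Poisson(noise_mean) per nucleotide.
    Each UTR is placed on its own synthetic chromosome on the '+'
    strand, so transcript and genomic offsets coincide.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    tracks, utrs = [], []
    truth = SimTruth(seed=seed)
    margin = max(int(3 * sigma), 30)
    for k in range(n_utrs):
        length = int(rng.integers(utr_len_range[0], utr_len_range[1] + 1))
        utr_id = f"utr{k:04d}"
        centers = _pick_centers(rng, length, peaks_per_utr, margin,
                                min_sep=max(120, 4 * int(sigma)))
        signal = np.zeros(length)
        for c in centers:
            signal += _bump(length, c, amplitude, sigma)
            truth.planted_peaks.append((utr_id, c, amplitude, sigma))
        depth = np.round(signal).astype(np.int64) + rng.poisson(noise_mean, length)
        tracks.append(CoverageTrack(utr_id, depth, total_reads=int(depth.sum())))
        utrs.append(UTRAnnotation(utr_id, f"chr_{utr_id}", 0, length, "+",
                                  gene=f"gene{k:04d}"))
    return tracks, utrs, truth


def write_alignment_fasta(path: str, id_a: str, seq_a: str, id_b: str,
                          seq_b: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{id_a}\n{seq_a}\n>{id_b}\n{seq_b}\n")


def sim_species_pair(
    utr_len: int = 900,
    n_peaks: int = 4,
    shared_frac: float = 0.5,
    indel_rate: float = 0.05,
    amplitude: float = 50.0,
    sigma: float = 10.0,
    noise_mean: float = 2.0,
    seed: int = 0,
) -> tuple[AlignedUTRPair, SimTruth]:
    """An aligned UTR pair sharing a subset of planted peaks.

    An ancestral UTR of ``utr_len`` columns is drawn; each column is
    independently gapped in one species with probability ``indel_rate``
    (split evenly), giving a gapped pairwise alignment without running
    an aligner.  Peaks are planted at ungapped columns: with probability
    ``shared_frac`` in both species, otherwise in one species chosen at
    random.  Truth records the alignment column of each peak and its
    shared flag.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    anc = rng.integers(0, 4, utr_len)
    gap_a = rng.random(utr_len) < indel_rate / 2.0
    gap_b = (rng.random(utr_len) < indel_rate / 2.0) & ~gap_a
    seq_a = "".join("-" if g else bases[b] for b, g in zip(anc, gap_a))
    seq_b = "".join("-" if g else bases[b] for b, g in zip(anc, gap_b))
    # ungapped offset of each alignment column, per species
    pos_a = np.where(~gap_a, np.cumsum(~gap_a) - 1, -1)
    pos_b = np.where(~gap_b, np.cumsum(~gap_b) - 1, -1)
    len_a, len_b = int((~gap_a).sum()), int((~gap_b).sum())

    margin = max(int(3 * sigma), 40)
    ok_cols = [c for c in range(margin, utr_len - margin)
               if not gap_a[c] and not gap_b[c]]
    min_sep = max(150, 5 * int(sigma))
    centers = []
    for _ in range(200):  # restart when early picks block all slots
        centers = []
        for _ in range(50 * max(n_peaks, 1)):
            if len(centers) == n_peaks:
                break
            c = ok_cols[int(rng.integers(len(ok_cols)))]
            if all(abs(c - o) >= min_sep for o in centers):
                centers.append(c)
        if len(centers) == n_peaks:
            break
    if len(centers) < n_peaks:
        raise ValueError("could not place the requested peaks")
    centers.sort()

    sig_a = np.zeros(len_a)
    sig_b = np.zeros(len_b)
    truth = SimTruth(seed=seed)
    for c in centers:
        shared = bool(rng.random() < shared_frac)
        in_a = in_b = shared
        if not shared:
            if rng.random() < 0.5:
                in_a = True
            else:
                in_b = True
        if in_a:
            sig_a += _bump(len_a, int(pos_a[c]), amplitude, sigma)
        if in_b:
            sig_b += _bump(len_b, int(pos_b[c]), amplitude, sigma)
        truth.planted_peaks.append(("pair", c, amplitude, sigma))
        truth.shared_flags.append(shared)

    depth_a = np.round(sig_a).astype(np.int64) + rng.poisson(noise_mean, len_a)
    depth_b = np.round(sig_b).astype(np.int64) + rng.poisson(noise_mean, len_b)
    track_a = CoverageTrack("utrA", depth_a, total_reads=int(depth_a.sum()))
    track_b = CoverageTrack("utrB", depth_b, total_reads=int(depth_b.sum()))

    # round-trip through the FASTA loader so projection logic is shared
    import os
    import tempfile

    tmp = tempfile.NamedTemporaryFile("w", suffix=".afa", delete=False)
    try:
        tmp.write(f">utrA\n{seq_a}\n>utrB\n{seq_b}\n")
        tmp.close()
        pair = load_alignment(tmp.name, track_a, track_b)
    finally:
        os.unlink(tmp.name)
    return pair, truth


def sim_deletion_library(
    amplicon_len: int = 1200,
    n_muts: int = 60,
    element: tuple[int, int] = (500, 550),
    multiplier: float = 2.0,
    depth: float = 200.0,
    dispersion: float = 10.0,
    n_experiments: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """A pooled deletion library with one planted cis-element.

    Deletion spans have uniform lengths 21-249 nt and uniform starts
    within the amplicon.  A deletion that removes the element entirely
    has expected RNA/gDNA ratio ``multiplier`` (destabilising element
    for multiplier > 1); all others have expected ratio 1.  RNA and gDNA
    counts are negative-binomial around ``depth`` (gamma-Poisson with
    shape ``dispersion``).
    """
    rng = np.random.default_rng(seed)
    e_start, e_end = element
    rows = []
    k = 0
    for exp in range(1, n_experiments + 1):
        for _ in range(n_muts):
            length = int(rng.integers(21, 250))
            length = min(length, amplicon_len)
            start = int(rng.integers(0, amplicon_len - length + 1))
            end = start + length
            ratio = multiplier if (start <= e_start and end >= e_end) else 1.0
            dna = int(rng.negative_binomial(
                dispersion, dispersion / (dispersion + depth)))
            mu = depth * ratio
            rna = int(rng.negative_binomial(
                dispersion, dispersion / (dispersion + mu)))
            rows.append(dict(mut_id=f"mut{k:04d}", experiment=f"exp{exp}",
                             start=start, end=end, rna_reads=rna,
                             dna_reads=dna))
            k += 1
    truth = SimTruth(seed=seed, planted_element=(e_start, e_end, multiplier))
    return pd.DataFrame(rows), truth


def sim_peak_sets(
    utrs: list[UTRAnnotation],
    n_ref: int = 50,
    n_query: int = 50,
    peak_len: int = 10,
    overlap_frac: float = 0.5,
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval], SimTruth]:
    """Reference and query peak sets with a controlled overlap fraction.

    Reference peaks are placed uniformly within random UTRs.  A fraction
    ``overlap_frac`` of query peaks is centred on a reference peak; the
    rest are placed uniformly, re-drawn (up to 200 attempts) to avoid
    the reference set where feasible.
    """
    rng = np.random.default_rng(seed)
    eligible = [u for u in utrs if u.length >= peak_len]
    if not eligible:
        raise ValueError("no UTR long enough for the requested peak length")

    def place(u: UTRAnnotation) -> GenomicInterval:
        s = int(rng.integers(u.start, u.end - peak_len + 1))
        return GenomicInterval(u.chrom, s, s + peak_len)

    ref = []
    ref_by_utr: dict[str, list[GenomicInterval]] = {}
    for i in range(n_ref):
        u = eligible[int(rng.integers(len(eligible)))]
        iv = place(u)
        ref.append(GenomicInterval(iv.chrom, iv.start, iv.end, f"ref{i:03d}"))
        ref_by_utr.setdefault(u.utr_id, []).append(iv)

    query = []
    flags = []
    ref_utrs = [u for u in eligible if u.utr_id in ref_by_utr]
    for i in range(n_query):
        want_overlap = bool(rng.random() < overlap_frac)
        if want_overlap and ref_utrs:
            u = ref_utrs[int(rng.integers(len(ref_utrs)))]
            target = ref_by_utr[u.utr_id][
                int(rng.integers(len(ref_by_utr[u.utr_id])))]
            c = (target.start + target.end) // 2
            s = int(np.clip(c - peak_len // 2, u.start, u.end - peak_len))
            iv = GenomicInterval(u.chrom, s, s + peak_len, f"q{i:03d}")
        else:
            u = eligible[int(rng.integers(len(eligible)))]
            iv = place(u)
            for _ in range(200):
                clashes = any(iv.start < r.end and r.start < iv.end
                              for r in ref_by_utr.get(u.utr_id, []))
                if not clashes:
                    break
                iv = place(u)
            iv = GenomicInterval(iv.chrom, iv.start, iv.end, f"q{i:03d}")
        query.append(iv)
        flags.append(want_overlap)
    truth = SimTruth(seed=seed, shared_flags=flags)
    return ref, query, truth
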