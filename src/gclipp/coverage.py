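"""Per-nucleotide 3'UTR coverage tracks from deduplicated aligned reads.

Reads arrive as BED6 records whose name field carries the 2-nt random
linker sequence used for PCR de-duplication (``readid#UMI``), or as BAM
records with a UMI tag.  Coverage is accumulated per annotated 3'UTR and
stored transcript-oriented (index 0 = 5'-most transcript position), so
every downstream window computation is strand-agnostic.

Coordinates are 0-based half-open throughout, matching BED/bedGraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AlignedRead",
    "UTRAnnotation",
    "CoverageTrack",
    "dedup_reads",
    "build_coverage",
    "read_bed_reads",
    "read_bam_reads",
    "read_bed_utrs",
    "read_bedgraph",
    "write_bedgraph",
    "read_genomic_bedgraph",
    "write_tracks_tsv",
]


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequencing read with its random-linker UMI.

    The (umi, chrom, start, end, strand) tuple is the de-duplication key:
    reads sharing all five fields are PCR copies of one captured fragment.
    """

    chrom: str
    start: int
    end: int
    strand: str
    umi: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple:
        return (self.umi, self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class UTRAnnotation:
    """An annotated 3'UTR, optionally spliced (BED12 blocks).

    ``blocks`` are genomic (start, end) exon pairs in ascending genomic
    order; for unspliced UTRs there is a single block spanning the whole
    record.  Transcript offsets run 5'->3', i.e. from the genomic start on
    '+' UTRs and from the genomic end on '-' UTRs.
    """

    utr_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene: str = ""
    blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.utr_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.utr_id}: bad strand {self.strand!r}")
        if not self.blocks:
            object.__setattr__(self, "blocks", ((self.start, self.end),))
        for s, e in self.blocks:
            if s >= e or s < self.start or e > self.end:
                raise ValueError(f"{self.utr_id}: bad block ({s}, {e})")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of each transcript offset, 5'->3'."""
        pos = np.concatenate([np.arange(s, e) for s, e in self.blocks])
        return pos[::-1] if self.strand == "-" else pos

    def to_genomic(self, offset: int) -> int:
        """Map a transcript offset to its genomic coordinate."""
        if not 0 <= offset < self.length:
            raise IndexError(f"offset {offset} outside {self.utr_id}")
        return int(self.genomic_positions()[offset])


@dataclass
class CoverageTrack:
    """Per-nucleotide read depth over one 3'UTR, transcript-oriented."""

    utr_id: str
    depth: np.ndarray
    total_reads: int = 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if len(self.depth) and self.depth.min() < 0:
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


def dedup_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse PCR duplicates: keep one read per (umi, chrom, start, end,
    strand) key, in first-occurrence order.

    Records with start >= end are rejected with a warning and skipped.
    """
    seen: set[tuple] = set()
    out: list[AlignedRead] = []
    for read in reads:
        if read.start >= read.end:
            warnings.warn(
                f"rejecting read {read.name or read.key}: start >= end",
                stacklevel=2,
            )
            continue
        if read.key not in seen:
            seen.add(read.key)
            out.append(read)
    return out


def build_coverage(
    reads: Iterable[AlignedRead],
    utrs: Iterable[UTRAnnotation],
) -> list[CoverageTrack]:
    """Count, per UTR nucleotide, the reads covering it.

    A read is assigned to a UTR iff it overlaps at least one exonic base on
    the same strand; only its in-UTR bases contribute.  A read overlapping
    two annotated UTRs is counted in both.  The depth vector is returned
    transcript-oriented.  UTRs with no overlapping reads get all-zero
    tracks.
    """
    by_key: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in reads:
        by_key.setdefault((r.chrom, r.strand), []).append(r)

    tracks = []
    for utr in utrs:
        depth = np.zeros(utr.length, dtype=np.int64)
        n_reads = 0
        candidates = by_key.get((utr.chrom, utr.strand), ())
        offset = 0
        # accumulate per genomic block, then orient afterwards
        hit_ids: set[int] = set()
        for bs, be in utr.blocks:
            for r in candidates:
                lo, hi = max(r.start, bs), min(r.end, be)
                if lo < hi:
                    depth[offset + lo - bs : offset + hi - bs] += 1
                    hit_ids.add(id(r))
            offset += be - bs
        n_reads = len(hit_ids)
        if utr.strand == "-":
            depth = depth[::-1]
        tracks.append(CoverageTrack(utr.utr_id, depth, total_reads=n_reads))
    return tracks


# ---------------------------------------------------------------------------
# I/O


def read_bed_reads(path: str, umi_sep: str = "#") -> list[AlignedRead]:
    """Read aligned reads from BED6; the name field is ``readid#UMI``.

    A name without the separator yields an empty UMI (every such read is
    then deduplicated on coordinates alone).
    """
    reads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected BED6, got {len(f)} fields")
            name = f[3]
            rid, _, umi = name.rpartition(umi_sep)
            if not rid:
                rid, umi = umi, ""
            reads.append(
                AlignedRead(f[0], int(f[1]), int(f[2]), f[5], umi=umi, name=rid)
            )
    return reads


def read_bam_reads(path: str, umi_tag: str = "RX") -> list[AlignedRead]:
    """Read aligned reads from BAM, taking the UMI from ``umi_tag`` when
    present (else from a trailing ``#UMI`` in the query name)."""
    import pysam  # deferred: BAM support is optional

    reads = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag(umi_tag):
                umi = str(aln.get_tag(umi_tag))
            else:
                _, _, umi = (aln.query_name or "").rpartition("#")
            reads.append(
                AlignedRead(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    umi=umi,
                    name=aln.query_name or "",
                )
            )
    return reads


def read_bed_utrs(path: str) -> list[UTRAnnotation]:
    """Read UTR annotations from BED6 (one block) or BED12 (spliced)."""
    utrs = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 fields")
            utr_id = f[3]
            if utr_id in seen:
                raise ValueError(f"{path}:{ln}: duplicate utr_id {utr_id!r}")
            seen.add(utr_id)
            start, end = int(f[1]), int(f[2])
            blocks: tuple[tuple[int, int], ...] = ()
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                blocks = tuple(
                    (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
                )
            utrs.append(
                UTRAnnotation(utr_id, f[0], start, end, f[5], blocks=blocks)
            )
    return utrs


def _runs(depth: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Yield (start, end, value) maximal runs of equal depth."""
    n = len(depth)
    i = 0
    while i < n:
        j = i + 1
        while j < n and depth[j] == depth[i]:
            j += 1
        yield i, j, int(depth[i])
        i = j


def write_bedgraph(tracks: Sequence[CoverageTrack], path: str) -> None:
    """Write tracks as transcript-space bedGraph: the first column is the
    utr_id and coordinates are transcript offsets.  Zero runs are written
    so a track round-trips exactly; adjacent equal-depth runs are merged.
    """
    with open(path, "w") as fh:
        for t in tracks:
            for s, e, v in _runs(np.asarray(t.depth)):
                fh.write(f"{t.utr_id}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str) -> list[CoverageTrack]:
    """Read transcript-space bedGraph back into coverage tracks.

    Intervals for one utr_id must be non-overlapping; gaps are filled with
    zero depth.  Track length is the maximum end seen for that utr_id.
    """
    intervals: dict[str, list[tuple[int, int, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph fields")
            uid, s, e, v = f[0], int(f[1]), int(f[2]), int(float(f[3]))
            if s >= e:
                raise ValueError(f"{path}:{ln}: start >= end")
            if v < 0:
                raise ValueError(f"{path}:{ln}: negative depth")
            if uid not in intervals:
                order.append(uid)
            intervals.setdefault(uid, []).append((s, e, v, ln))

    tracks = []
    for uid in order:
        ivs = sorted(intervals[uid])
        prev_end = 0
        for s, e, v, ln in ivs:
            if s < prev_end:
                raise ValueError(f"{path}:{ln}: overlapping interval for {uid!r}")
            prev_end = e
        depth = np.zeros(ivs[-1][1], dtype=np.int64)
        for s, e, v, _ in ivs:
            depth[s:e] = v
        tracks.append(CoverageTrack(uid, depth, total_reads=0))
    return tracks


def read_genomic_bedgraph(path: str) -> dict[str, np.ndarray]:
    """Read a genomic bedGraph (e.g. a conservation track) into one float
    vector per chromosome, zero-filled outside covered intervals.

    Intended for desk-scale tracks; vectors are allocated up to the
    maximum end coordinate seen per chromosome.
    """
    raw: dict[str, list[tuple[int, int, float, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph fields")
            s, e = int(f[1]), int(f[2])
            if s >= e:
                raise ValueError(f"{path}:{ln}: start >= end")
            raw.setdefault(f[0], []).append((s, e, float(f[3]), ln))
    out = {}
    for chrom, ivs in raw.items():
        ivs.sort()
        prev_end = 0
        for s, e, v, ln in ivs:
            if s < prev_end:
                raise ValueError(f"{path}:{ln}: overlapping interval on {chrom}")
            prev_end = e
        vec = np.zeros(ivs[-1][1], dtype=float)
        for s, e, v, _ in ivs:
            vec[s:e] = v
        out[chrom] = vec
    return out


def write_tracks_tsv(tracks: Sequence[CoverageTrack], path: str) -> None:
    """Dump tracks as TSV (utr_id, offset, depth), one row per nucleotide."""
    with open(path, "w") as fh:
        fh.write("utr_id\toffset\tdepth\n")
        for t in tracks:
            for i, d in enumerate(t.depth):
                fh.write(f"{t.utr_id}\t{i}\t{int(d)}\n")
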