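"""Gaussian-template goodness-of-fit peak calling on 3'UTR coverage.

Every UTR nucleotide is scored by the Pearson correlation between the
coverage window centred on it and a Gaussian template of the same width:
a high score means the local read distribution looks like a clean,
unimodal occupancy peak.  Peaks are local maxima of this profile that
additionally clear a depth threshold of max(min_frac x UTR maximum,
min_depth) reads at the candidate nucleotide.

Pearson correlation is location/scale invariant, so neither the coverage
amplitude nor the template amplitude affects the profile; only the depth
filters see absolute read counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "PeakCallParams",
    "Peak",
    "gaussian_template",
    "gof_profile",
    "call_peaks",
    "local_maxima",
]


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning knobs of the goodness-of-fit peak caller.

    window
        Odd window width in nucleotides scanned around each position.
        Default 71 (+-35 nt), the ~70-nt scale of RNase-protected
        occupancy footprints plus symmetric flanks.
    sigma
        Spread of the Gaussian template; default window/6 so +-3 sigma
        spans the window.
    min_frac
        Candidate depth must reach this fraction of the UTR's maximum
        depth (default 0.2).
    min_depth
        Absolute depth floor in deduplicated reads (default 10).
    min_sep
        Minimum spacing between reported peaks; among conflicting
        candidates the higher-scoring one wins (default window // 2).
    flank
        Half-width of the interval attached to each point peak for
        overlap analyses (default 100 nt, i.e. 200-nt resized peaks).
    """

    window: int = 71
    sigma: float | None = None
    min_frac: float = 0.2
    min_depth: int = 10
    min_sep: int | None = None
    flank: int = 100

    def __post_init__(self) -> None:
        if self.window < 5:
            raise ValueError("window must be >= 5")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must be in [0, 1]")

    @property
    def sigma_(self) -> float:
        return self.window / 6.0 if self.sigma is None else self.sigma

    @property
    def min_sep_(self) -> int:
        return self.window // 2 if self.min_sep is None else self.min_sep


@dataclass(frozen=True)
class Peak:
    """One called occupancy peak (a point plus an attached interval)."""

    utr_id: str
    center: int
    score: float
    center_depth: int
    interval: tuple[int, int]
    chrom: str | None = None
    genomic_pos: int | None = None


def gaussian_template(window: int, sigma: float) -> np.ndarray:
    """Unnormalised Gaussian of width ``window`` centred at window // 2.

    g[i] = exp(-(i - c)^2 / (2 sigma^2)).  The absolute amplitude is
    irrelevant to Pearson scoring; unit peak height is used.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    i = np.arange(window, dtype=float)
    c = window // 2
    return np.exp(-((i - c) ** 2) / (2.0 * sigma**2))


def _pearson_rows(rows: np.ndarray, tmpl: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between ``rows`` and a fixed template.

    Rows with zero variance get NaN (undefined correlation).
    """
    x = rows - rows.mean(axis=1, keepdims=True)
    t = tmpl - tmpl.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    st = np.sqrt((t**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ t) / (sx * st)
    r[sx == 0] = np.nan
    return r


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float((xc @ yc) / (sx * sy))


def gof_profile(track, params: PeakCallParams = PeakCallParams()) -> np.ndarray:
    """Per-nucleotide Pearson goodness of fit to the Gaussian template.

    Windows are truncated at the UTR ends; a position is scored whenever
    at least window // 2 positions remain.  Constant windows (including
    all-zero coverage) yield NaN.  Tracks shorter than window // 2 return
    an empty profile with a warning.
    """
    depth = np.asarray(track.depth, dtype=float)
    n = len(depth)
    w = params.window
    flank = w // 2
    min_pts = w // 2
    if n < min_pts:
        warnings.warn(
            f"track {track.utr_id!r} shorter than window/2; empty profile",
            stacklevel=2,
        )
        return np.empty(0)

    tmpl = gaussian_template(w, params.sigma_)
    r = np.full(n, np.nan)

    if n >= w:
        # full windows, batched
        r[flank : n - flank] = _pearson_rows(sliding_window_view(depth, w), tmpl)
    edge_idx = [i for i in range(n) if i < flank or i > n - flank - 1]
    for i in edge_idx:
        lo, hi = max(0, i - flank), min(n, i + flank + 1)
        if hi - lo < min_pts:
            continue
        r[i] = _pearson(depth[lo:hi], tmpl[lo - (i - flank) : hi - (i - flank)])
    return r


def local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima, NaN treated as -inf.

    A plateau (run of equal values) counts once, at its midpoint; for
    even-length plateaus the leftmost of the two middle indices is taken.
    Runs touching a boundary qualify if their one interior neighbour is
    strictly lower.
    """
    v = np.where(np.isnan(values), -np.inf, np.asarray(values, dtype=float))
    n = len(v)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if np.isfinite(v[i]):
            left_ok = i == 0 or v[i - 1] < v[i]
            right_ok = j == n - 1 or v[j + 1] < v[i]
            if left_ok and right_ok:
                out.append((i + j) // 2)
        i = j + 1
    return out


def call_peaks(
    track,
    params: PeakCallParams = PeakCallParams(),
    utr=None,
) -> list[Peak]:
    """Report thresholded local maxima of the goodness-of-fit profile.

    A candidate centre i is kept iff (a) it is a local maximum of the
    profile, (b) depth[i] >= max(min_frac x max depth, min_depth), and
    (c) no retained candidate with a higher score lies within min_sep
    (ties resolved leftmost).  Output is sorted by centre.  When ``utr``
    is given, each peak also carries its genomic coordinate.
    """
    depth = np.asarray(track.depth)
    r = gof_profile(track, params)
    if len(r) == 0 or len(depth) == 0:
        return []
    max_depth = int(depth.max())
    threshold = max(params.min_frac * max_depth, params.min_depth)

    candidates = [i for i in local_maxima(r) if depth[i] >= threshold]
    # greedy exclusion: best score first, leftmost on ties
    candidates.sort(key=lambda i: (-r[i], i))
    kept: list[int] = []
    for i in candidates:
        if all(abs(i - k) >= params.min_sep_ for k in kept):
            kept.append(i)
    kept.sort()

    gpos = utr.genomic_positions() if utr is not None else None
    peaks = []
    for i in kept:
        peaks.append(
            Peak(
                utr_id=track.utr_id,
                center=i,
                score=float(r[i]),
                center_depth=int(depth[i]),
                interval=(max(0, i - params.flank), min(len(depth), i + params.flank)),
                chrom=utr.chrom if utr is not None else None,
                genomic_pos=int(gpos[i]) if gpos is not None else None,
            )
        )
    return peaks
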