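"""Insulation-score TAD analysis.

Sliding-square insulation scores, boundary calling at insulation
valleys, TAD construction, intra/inter TAD score, TAD length statistics,
and aggregate TAD analysis (ATA) pileups on O/E signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import DegenerateInputError, ParameterError
from .hic import ContactMatrix, observed_over_expected
from .io import GenomeBins

__all__ = [
    "InsulationProfile",
    "TadSet",
    "insulation_score",
    "call_boundaries",
    "tads_from_boundaries",
    "tad_score",
    "aggregate_tads",
    "tad_length_stats",
]


@dataclass
class InsulationProfile:
    """Per-bin insulation score (log2 units) with its delta vector.

    The raw score of bin i is the mean balanced contact in the square
    window spanning bins [i-w, i) x [i, i+w); the reported score is
    log2(raw / chromosome mean of raw). Bins where the window does not
    fit are NaN.
    """

    bins: GenomeBins
    score: np.ndarray       # log2 units, NaN at edges/masked
    window_bins: int
    delta: np.ndarray | None = None
    boundaries: np.ndarray | None = None        # bin indices
    boundary_strength: np.ndarray | None = None


@dataclass
class TadSet:
    """Non-overlapping sorted TAD intervals, half-open in bp."""

    intervals: np.ndarray   # (n, 2) start/end bp
    bin_size: int

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size and (np.any(iv[:, 1] <= iv[:, 0])
                        or np.any(iv[1:, 0] < iv[:-1, 1])):
            raise ParameterError("TADs must be sorted and non-overlapping")
        self.intervals = iv

    @property
    def sizes(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def bin_intervals(self) -> np.ndarray:
        return self.intervals // self.bin_size

    def boundaries_bins(self) -> np.ndarray:
        """Internal boundaries (bin indices shared by adjacent TADs)."""
        iv = self.bin_intervals()
        return np.asarray([iv[k + 1, 0] for k in range(len(iv) - 1)
                           if iv[k, 1] == iv[k + 1, 0]], dtype=int)


def insulation_score(m: ContactMatrix, window: int = 500_000,
                     min_coverage: float = 0.5) -> InsulationProfile:
    """Sliding-square insulation score at the matrix's bin size.

    Windows with masked bins are averaged over their valid pixels as long
    as at least ``min_coverage`` of the window is valid; sparser windows
    yield NaN, as do edge bins where the window does not fit.
    """
    n = m.n_bins
    bs = m.bin_size
    if window % bs != 0:
        raise ParameterError("window must be a multiple of bin_size")
    w = window // bs
    if w < 1 or 2 * w > n:
        raise ParameterError("window too large for this chromosome")
    b = m.balanced()
    valid = m.valid_bins
    raw = np.full(n, np.nan)
    for i in range(w, n - w + 1):
        rows = slice(i - w, i)
        cols = slice(i, i + w)
        ok = np.outer(valid[rows], valid[cols])
        if ok.mean() < min_coverage:
            continue
        raw[i] = b[rows, cols][ok].mean()
    ok = ~np.isnan(raw) & (raw > 0)
    if not ok.any():
        raise DegenerateInputError("no bin admits an insulation window")
    mean_raw = raw[ok].mean()
    score = np.full(n, np.nan)
    score[ok] = np.log2(raw[ok] / mean_raw)
    return InsulationProfile(bins=m.bins, score=score, window_bins=w)


def call_boundaries(profile: InsulationProfile, delta_window: int = 100_000,
                    min_strength: float = 0.1) -> InsulationProfile:
    """Call TAD boundaries at insulation-score valleys.

    The delta vector at bin i is the mean score over ``delta_window`` to
    the left minus the mean to the right; valleys are downward zero
    crossings of delta whose swing (max delta on the left flank minus min
    delta on the right flank) reaches ``min_strength``. Returns a new
    profile with ``boundaries`` and ``boundary_strength`` set.
    """
    score = profile.score
    n = len(score)
    bs = profile.bins.bin_size
    if delta_window % bs != 0:
        raise ParameterError("delta_window must be a multiple of bin_size")
    d = max(delta_window // bs, 1)
    delta = np.full(n, np.nan)
    for i in range(n):
        left = score[max(i - d, 0):i]
        right = score[i + 1:i + 1 + d]
        lv, rv = left[~np.isnan(left)], right[~np.isnan(right)]
        if lv.size and rv.size:
            delta[i] = lv.mean() - rv.mean()

    boundaries, strengths = [], []
    for i in range(n - 1):
        if np.isnan(delta[i]) or np.isnan(delta[i + 1]):
            continue
        if not (delta[i] > 0 >= delta[i + 1]):  # + -> - crossing = valley
            continue
        lo, hi = max(i - d, 0), min(i + d + 2, n)
        window = score[lo:hi]
        if np.all(np.isnan(window)):
            continue
        bin_at = lo + int(np.nanargmin(window))
        left_flank = delta[max(i - d, 0):i + 1]
        right_flank = delta[i + 1:min(i + 1 + d, n)]
        swing = (np.nanmax(left_flank) - np.nanmin(right_flank))
        if swing >= min_strength:
            if boundaries and bin_at == boundaries[-1]:
                continue
            boundaries.append(bin_at)
            strengths.append(float(swing))
    return InsulationProfile(
        bins=profile.bins, score=score, window_bins=profile.window_bins,
        delta=delta, boundaries=np.asarray(boundaries, dtype=int),
        boundary_strength=np.asarray(strengths))


def tads_from_boundaries(boundaries: np.ndarray, bins: GenomeBins) -> TadSet:
    """Tile the chromosome into TADs between consecutive boundaries."""
    b = np.asarray(boundaries, dtype=int)
    if np.any(np.diff(b) <= 0):
        raise ParameterError("boundaries must be strictly increasing")
    n = bins.n_bins
    edges = [0, *[int(x) for x in b if 0 < x < n], n]
    bs = bins.bin_size
    span = int(bins.ends[-1])
    intervals = []
    for s, t in zip(edges[:-1], edges[1:]):
        intervals.append((s * bs, min(t * bs, span)))
    return TadSet(intervals=np.asarray(intervals), bin_size=bs)


def tad_score(m: ContactMatrix, tads: TadSet, min_bins: int = 3
              ) -> pd.DataFrame:
    """Per-TAD intra/inter contact ratio.

    intra = mean balanced contact over within-TAD bin pairs (diagonal
    excluded); inter = mean balanced contact between the TAD's bins and
    the bins of its adjacent TADs; score = intra / inter. TADs smaller
    than ``min_bins`` bins are skipped; a zero inter mean masks the score.
    """
    b = m.balanced()
    valid = m.valid_bins
    iv = tads.bin_intervals()
    rows = []
    for k, (s, t) in enumerate(iv):
        s, t = int(s), int(min(t, m.n_bins))
        if t - s < min_bins:
            rows.append((k, s, t, np.nan, np.nan, np.nan, "too_small"))
            continue
        sel = np.arange(s, t)[valid[s:t]]
        if len(sel) < 2:
            rows.append((k, s, t, np.nan, np.nan, np.nan, "masked"))
            continue
        intra_block = b[np.ix_(sel, sel)].copy()
        np.fill_diagonal(intra_block, np.nan)
        intra = np.nanmean(intra_block)
        neigh: list[np.ndarray] = []
        for kk in (k - 1, k + 1):
            if 0 <= kk < len(iv):
                ns, nt = int(iv[kk, 0]), int(min(iv[kk, 1], m.n_bins))
                nsel = np.arange(ns, nt)[valid[ns:nt]]
                if len(nsel):
                    neigh.append(b[np.ix_(sel, nsel)].ravel())
        if not neigh:
            rows.append((k, s, t, intra, np.nan, np.nan, "no_neighbor"))
            continue
        inter_vals = np.concatenate(neigh)
        inter = np.nanmean(inter_vals)
        score = intra / inter if inter > 0 else np.nan
        note = "" if inter > 0 else "zero_inter"
        rows.append((k, s, t, intra, inter, score, note))
    return pd.DataFrame(rows, columns=["tad", "start_bin", "end_bin",
                                       "intra", "inter", "score", "note"])


def aggregate_tads(m: ContactMatrix, tads: TadSet, min_size: int = 200_000,
                   out_pixels: int = 90, flank_fraction: float = 0.5
                   ) -> tuple[np.ndarray, int]:
    """Aggregate TAD analysis: average of size-rescaled O/E windows.

    Each TAD at least ``min_size`` bp long contributes the O/E window
    spanning the TAD extended by ``flank_fraction`` of its size on both
    sides, rescaled by bilinear interpolation to ``out_pixels`` square.
    Returns (grid, number of TADs aggregated).
    """
    oe = observed_over_expected(m)
    n = m.n_bins
    bs = m.bin_size
    acc = np.zeros((out_pixels, out_pixels))
    wsum = np.zeros((out_pixels, out_pixels))
    n_used = 0
    for s_bp, t_bp in tads.intervals:
        if t_bp - s_bp < min_size:
            continue
        s, t = int(s_bp // bs), int(t_bp // bs)
        size = t - s
        flank = int(round(flank_fraction * size))
        lo, hi = s - flank, t + flank
        if lo < 0 or hi > n or size < 2:
            continue
        window = oe[lo:hi, lo:hi]
        filled = np.nan_to_num(window, nan=0.0)
        weight = (~np.isnan(window)).astype(float)
        rs = resize(filled, (out_pixels, out_pixels), order=1, mode="edge",
                    anti_aliasing=False)
        rw = resize(weight, (out_pixels, out_pixels), order=1, mode="edge",
                    anti_aliasing=False)
        acc += rs
        wsum += rw
        n_used += 1
    if n_used == 0:
        raise DegenerateInputError("no TAD passes the size filter")
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = np.where(wsum > 0, acc / wsum, np.nan)
    return grid, n_used


def tad_length_stats(tads: TadSet, long_threshold: int = 500_000) -> dict:
    """Counts of long/short TADs and the length distribution summary."""
    sizes = tads.sizes
    return {
        "n_tads": int(len(sizes)),
        "n_long": int((sizes > long_threshold).sum()),
        "n_short": int((sizes < long_threshold).sum()),
        "median_length": float(np.median(sizes)) if len(sizes) else np.nan,
        "lengths": sizes.astype(float),
    }
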