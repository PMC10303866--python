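"""Core contact-matrix processing.

ICE balancing, total-count normalization, distance-expected profiles and
observed-over-expected transforms, contact-probability P(s) curves,
trans-contact fraction, and differential maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateInputError,
    DimensionError,
    ParameterError,
    ValidationError,
)
from .io import GenomeBins

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "PsCurve",
    "ice_balance",
    "normalize_total",
    "expected_by_distance",
    "observed_over_expected",
    "contact_probability",
    "ps_slope",
    "trans_ratio",
    "differential_matrix",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts with bin table and optional weights.

    ``weights`` are multiplicative per-bin balancing factors; masked bins
    carry NaN weights and are excluded from all statistics.
    """

    counts: np.ndarray
    bins: GenomeBins
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise DimensionError(
                f"matrix is {self.counts.shape}, bin table has {n} bins")
        if not np.allclose(self.counts, self.counts.T, rtol=0, atol=1e-9,
                           equal_nan=True):
            raise ValidationError("contact matrix must be symmetric")
        if np.any(self.counts < 0):
            raise ValidationError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def bin_size(self) -> int:
        return self.bins.bin_size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def valid_bins(self) -> np.ndarray:
        """Boolean mask of bins that enter statistics."""
        if self.weights is None:
            return np.ones(self.n_bins, dtype=bool)
        return ~np.isnan(self.weights)

    def balanced(self) -> np.ndarray:
        """Balanced matrix ``w_i * counts[i,j] * w_j``; masked bins NaN.

        Returns the raw counts (with NaN rows/cols only where weights are
        masked) when the matrix has not been balanced.
        """
        if self.weights is None:
            return self.counts.copy()
        w = self.weights
        return w[:, None] * self.counts * w[None, :]

    def cis_block(self, chrom: str) -> "ContactMatrix":
        """Extract one chromosome's cis sub-matrix."""
        sl = self.bins.chrom_slice(chrom)
        sub_bins = GenomeBins(self.bins.chroms[sl], self.bins.starts[sl],
                              self.bins.ends[sl], self.bins.bin_size)
        w = None if self.weights is None else self.weights[sl]
        return ContactMatrix(self.counts[sl, sl], sub_bins, w)


@dataclass
class ExpectedProfile:
    """Mean balanced contact per genomic distance (in bins)."""

    distances: np.ndarray  # bins
    means: np.ndarray      # NaN where no valid pair exists


@dataclass
class PsCurve:
    """Contact probability versus genomic separation, geometric bins."""

    centers_bp: np.ndarray       # geometric-mean distance per bin, bp
    centers_bins: np.ndarray     # same in bins
    probabilities: np.ndarray    # normalized to sum 1 over the curve
    pair_counts: np.ndarray      # number of (i, j) pairs per distance bin


# ---------------------------------------------------------------------------
# balancing and normalization


def ice_balance(m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200,
                min_coverage_mad: float = 3.0) -> ContactMatrix:
    """Iterative correction (ICE) of a contact matrix.

    Bins with zero coverage or raw marginal below
    ``median - min_coverage_mad * MAD`` are masked first. Iteration stops
    when the coefficient of variation of unmasked marginals drops below
    ``tol``. The balanced matrix is scaled so the mean over valid pixels
    is 1; weights are stored on the returned matrix (NaN where masked).
    Non-convergence is reported via the ``converged`` attribute.
    """
    counts = m.counts
    marg = counts.sum(axis=1)
    mask = marg > 0
    if mask.sum() >= 2 and min_coverage_mad > 0:
        med = np.median(marg[mask])
        mad = np.median(np.abs(marg[mask] - med))
        # a bin is a coverage dropout only if it is both a MAD outlier and
        # clearly below typical coverage; the second clause keeps nearly
        # uniform marginals (MAD ~ 0) from masking half the bins
        dropout = (marg < med - min_coverage_mad * mad) & (marg < 0.5 * med)
        mask &= ~dropout
    if mask.sum() < 2:
        raise DegenerateInputError("fewer than 2 unmasked bins")

    w = np.ones(mask.sum())
    sub = counts[np.ix_(mask, mask)]
    converged = False
    for _ in range(max_iter):
        b = w[:, None] * sub * w[None, :]
        s = b.sum(axis=1)
        mu = s.mean()
        if mu <= 0:
            raise DegenerateInputError("zero marginals during balancing")
        cv = s.std() / mu
        if cv < tol:
            converged = True
            break
        w = w / np.sqrt(s / mu)

    # scale so the mean balanced value over valid pixels is 1
    b = w[:, None] * sub * w[None, :]
    scale = 1.0 / np.sqrt(b.mean())
    w = w * scale

    weights = np.full(m.n_bins, np.nan)
    weights[mask] = w
    out = ContactMatrix(counts=m.counts.copy(), bins=m.bins, weights=weights)
    out.converged = converged  # type: ignore[attr-defined]
    return out


def normalize_total(m: ContactMatrix, target_total: float) -> ContactMatrix:
    """Scale counts so the matrix total equals ``target_total``."""
    tot = m.total
    if tot <= 0:
        raise DegenerateInputError("matrix total is zero")
    out = ContactMatrix(counts=m.counts * (target_total / tot), bins=m.bins,
                        weights=None if m.weights is None
                        else m.weights.copy())
    return out


# ---------------------------------------------------------------------------
# expected / observed-over-expected


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean balanced contact over valid pairs at each |i-j| distance."""
    b = m.balanced()
    valid = m.valid_bins
    n = m.n_bins
    means = np.full(n, np.nan)
    vv = np.outer(valid, valid)
    for d in range(n):
        vals = np.diagonal(b, offset=d)
        ok = np.diagonal(vv, offset=d)
        if ok.any():
            means[d] = vals[ok].mean()
    return ExpectedProfile(distances=np.arange(n), means=means)


def observed_over_expected(m: ContactMatrix,
                           expected: ExpectedProfile | None = None
                           ) -> np.ndarray:
    """O/E matrix: balanced counts divided by the distance expectation.

    Masked bins and distances without a defined expectation are NaN.
    """
    if expected is None:
        expected = expected_by_distance(m)
    b = m.balanced()
    n = m.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    exp = expected.means[dist]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, b / exp, np.nan)
    invalid = ~m.valid_bins
    oe[invalid, :] = np.nan
    oe[:, invalid] = np.nan
    return oe


# ---------------------------------------------------------------------------
# P(s) contact-probability curve


def contact_probability(m: ContactMatrix, geometric_factor: float = 1.12
                        ) -> PsCurve:
    """Mean contact per logarithmically increasing genomic-distance bin.

    The first diagonal (s = 0) is excluded; distance bins grow by
    ``geometric_factor``; the curve is normalized to sum 1.
    """
    if geometric_factor <= 1:
        raise ParameterError("geometric_factor must exceed 1")
    n = m.n_bins
    if n < 3:
        raise ParameterError("matrix too small for a P(s) curve")
    b = m.balanced()
    valid = m.valid_bins
    # per-distance mean over valid pairs
    mean_d = np.full(n, np.nan)
    npairs = np.zeros(n)
    vv = np.outer(valid, valid)
    for d in range(1, n):
        ok = np.diagonal(vv, offset=d)
        if ok.any():
            mean_d[d] = np.diagonal(b, offset=d)[ok].mean()
            npairs[d] = ok.sum()

    edges = [1.0]
    while edges[-1] < n:
        edges.append(max(edges[-1] * geometric_factor, edges[-1] + 1))
    edges = np.asarray(edges)
    if len(edges) < 3:
        raise ParameterError("matrix spans fewer than 2 distance bins")

    centers_bins, probs, counts = [], [], []
    d = np.arange(n)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d >= lo) & (d < hi) & ~np.isnan(mean_d)
        if not sel.any():
            continue
        w = npairs[sel]
        centers_bins.append(np.exp(np.average(np.log(d[sel]), weights=w)))
        probs.append(np.average(mean_d[sel], weights=w))
        counts.append(w.sum())
    centers_bins = np.asarray(centers_bins)
    probs = np.asarray(probs)
    total = probs.sum()
    if total <= 0:
        raise DegenerateInputError("empty P(s) curve")
    return PsCurve(centers_bp=centers_bins * m.bin_size,
                   centers_bins=centers_bins,
                   probabilities=probs / total,
                   pair_counts=np.asarray(counts))


def ps_slope(curve: PsCurve, s_min: float, s_max: float,
             offset: float = 1.0) -> float:
    """Least-squares log-log slope of P(s) over ``[s_min, s_max]`` bins.

    ``offset`` is added to the distance before taking logs, matching the
    generator's regularized ``(s+1)**(-alpha)`` decay so the fitted slope
    of an expected-value simulation equals ``-alpha`` exactly.
    """
    sel = ((curve.centers_bins >= s_min) & (curve.centers_bins <= s_max)
           & (curve.probabilities > 0))
    if sel.sum() < 2:
        raise ParameterError("fewer than 2 curve points in slope range")
    x = np.log(curve.centers_bins[sel] + offset)
    y = np.log(curve.probabilities[sel])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# trans fraction and differential maps


def trans_ratio(m: ContactMatrix) -> float:
    """Fraction of contacts between different chromosomes."""
    chroms = m.bins.chroms
    if len(set(map(str, chroms))) < 2:
        raise ParameterError("trans ratio requires >= 2 chromosomes")
    tot = m.total
    if tot <= 0:
        raise DegenerateInputError("matrix total is zero")
    same = chroms[:, None] == chroms[None, :]
    cis = m.counts[same].sum()
    return float((tot - cis) / tot)


def differential_matrix(a: ContactMatrix, b: ContactMatrix) -> np.ndarray:
    """Entrywise ``a - b`` on commonly valid bins; masked elsewhere (NaN).

    Inputs must share bins and should be normalized to the same total.
    """
    if (a.n_bins != b.n_bins
            or np.any(a.bins.chroms != b.bins.chroms)
            or np.any(a.bins.starts != b.bins.starts)):
        raise AlignmentError("bin tables differ between the two matrices")
    diff = a.counts - b.counts
    invalid = ~(a.valid_bins & b.valid_bins)
    diff[invalid, :] = np.nan
    diff[:, invalid] = np.nan
    return diff
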