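"""A/B compartment analysis.

PC1 of the O/E Pearson-correlation matrix, A/B classification by sign,
compartment-switch accounting between two conditions, the AB/(AA+BB)
mixing ratio, and saddle enrichment grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionError, ParameterError
from .hic import ContactMatrix, expected_by_distance, observed_over_expected
from .io import GenomeBins

__all__ = [
    "CompartmentProfile",
    "SwitchSummary",
    "compute_pc1",
    "compartment_switches",
    "mixing_ratio",
    "saddle",
]


@dataclass
class CompartmentProfile:
    """Per-bin PC1 values with A/B labels.

    Label is ``A`` iff PC1 > 0, ``B`` iff PC1 < 0, and undetermined
    (NaN PC1) for masked bins or exact zeros.
    """

    bins: GenomeBins
    pc1: np.ndarray                 # NaN where undetermined
    degenerate: bool = False        # leading eigenvalue not separated
    oriented: bool = True           # sign fixed by an orientation track

    @property
    def labels(self) -> np.ndarray:
        """Per-bin label: +1 (A), -1 (B), 0 (undetermined)."""
        lab = np.zeros(len(self.pc1), dtype=int)
        lab[self.pc1 > 0] = 1
        lab[self.pc1 < 0] = -1
        return lab

    @property
    def determined(self) -> np.ndarray:
        return self.labels != 0


@dataclass
class SwitchSummary:
    """Fractions of co-determined bins by compartment fate."""

    stable_a: float
    stable_b: float
    a_to_b: float
    b_to_a: float
    n_co_determined: int
    n_excluded: int

    def as_dict(self) -> dict:
        return {"stable_A": self.stable_a, "stable_B": self.stable_b,
                "A_to_B": self.a_to_b, "B_to_A": self.b_to_a,
                "n_co_determined": self.n_co_determined,
                "n_excluded": self.n_excluded}


def compute_pc1(m: ContactMatrix, orientation_track: np.ndarray | None = None
                ) -> CompartmentProfile:
    """Leading eigenvector of the O/E Pearson-correlation matrix.

    Computed per (single-chromosome) matrix. The sign is chosen so PC1
    correlates positively with ``orientation_track`` (a gene-density-like
    proxy); without a track the result is unsigned and ``oriented`` is
    False. A degenerate leading eigenpair (relative gap <= 1e-8, e.g. no
    plaid at all) is flagged rather than raised.
    """
    oe = observed_over_expected(m)
    valid = m.valid_bins & ~np.all(np.isnan(oe), axis=1)
    n = m.n_bins
    pc1 = np.full(n, np.nan)
    if valid.sum() < 3:
        raise DegenerateInputError("fewer than 3 valid bins for PC1")
    sub = oe[np.ix_(valid, valid)]
    # rows with (numerically) zero variance -- flat O/E, no plaid -- carry
    # no compartment signal; correlating their rounding noise is meaningless
    row_std = np.nanstd(sub, axis=1)
    row_scale = np.maximum(np.abs(np.nanmean(sub, axis=1)), 1e-300)
    flat = row_std <= 1e-10 * row_scale
    if flat.all():
        pc1[valid] = 0.0
        return CompartmentProfile(bins=m.bins, pc1=pc1, degenerate=True,
                                  oriented=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    evals, evecs = np.linalg.eigh(corr)
    lead, second = evals[-1], evals[-2]
    degenerate = not (abs(lead) > 1e-12
                      and (lead - second) / max(abs(lead), 1e-300) > 1e-8)
    vec = evecs[:, -1]
    pc1[valid] = vec

    oriented = False
    if orientation_track is not None:
        track = np.asarray(orientation_track, dtype=float)
        if track.shape != (n,):
            raise DimensionError("orientation track length != n_bins")
        ok = valid & ~np.isnan(track)
        if ok.sum() >= 2 and np.nanstd(track[ok]) > 0:
            r = np.corrcoef(pc1[ok], track[ok])[0, 1]
            if r < 0:
                pc1 = -pc1
            oriented = True
    return CompartmentProfile(bins=m.bins, pc1=pc1, degenerate=degenerate,
                              oriented=oriented)


def compartment_switches(p1: CompartmentProfile, p2: CompartmentProfile
                         ) -> SwitchSummary:
    """Fractions of co-determined bins that are stable or switch A<->B.

    Uses zero as the PC1 cutoff; bins undetermined in either profile are
    excluded and counted.
    """
    if len(p1.pc1) != len(p2.pc1):
        raise DimensionError("profiles have different bin counts")
    l1, l2 = p1.labels, p2.labels
    co = (l1 != 0) & (l2 != 0)
    n_co = int(co.sum())
    if n_co == 0:
        raise DegenerateInputError("no co-determined bins")
    a1, a2 = l1[co] == 1, l2[co] == 1
    return SwitchSummary(
        stable_a=float((a1 & a2).sum() / n_co),
        stable_b=float((~a1 & ~a2).sum() / n_co),
        a_to_b=float((a1 & ~a2).sum() / n_co),
        b_to_a=float((~a1 & a2).sum() / n_co),
        n_co_determined=n_co,
        n_excluded=int((~co).sum()),
    )


def mixing_ratio(m: ContactMatrix, profile: CompartmentProfile) -> float:
    """AB / (AA + BB) ratio of balanced contact sums, diagonal excluded.

    AB sums balanced contacts over unordered A-B bin pairs; AA and BB sum
    over same-class pairs. Requires at least 2 determined bins per class.
    """
    lab = profile.labels
    b = m.balanced()
    det = (lab != 0) & m.valid_bins
    for cls, name in ((1, "A"), (-1, "B")):
        if (lab[det] == cls).sum() < 2:
            raise DegenerateInputError(f"fewer than 2 {name}-class bins")
    idx = np.flatnonzero(det)
    sub = b[np.ix_(idx, idx)]
    sub_lab = lab[idx]
    same = sub_lab[:, None] == sub_lab[None, :]
    iu, ju = np.triu_indices(len(idx), k=1)  # unordered pairs, no diagonal
    vals = sub[iu, ju]
    same_pairs = same[iu, ju]
    ok = ~np.isnan(vals)
    ab = vals[ok & ~same_pairs].sum()
    aabb = vals[ok & same_pairs].sum()
    if aabb <= 0:
        raise DegenerateInputError("zero intra-compartment contact sum")
    return float(ab / aabb)


def saddle(oe: np.ndarray, profile: CompartmentProfile, n_quantiles: int = 5
           ) -> np.ndarray:
    """Mean O/E grid over PC1-quantile bin pairs (symmetric, q x q).

    Determined bins are ranked by PC1 into ``n_quantiles`` equal-count
    groups (group 1 = most B-like, group q = most A-like); cell (a, b) is
    the mean O/E over all pairs with one bin in each group, diagonal
    excluded.
    """
    if n_quantiles < 2:
        raise ParameterError("n_quantiles must be >= 2")
    det = profile.determined & ~np.all(np.isnan(oe), axis=1)
    if det.sum() < n_quantiles:
        raise DegenerateInputError("fewer determined bins than quantiles")
    idx = np.flatnonzero(det)
    order = idx[np.argsort(profile.pc1[idx], kind="stable")]
    groups = np.array_split(order, n_quantiles)
    grid = np.full((n_quantiles, n_quantiles), np.nan)
    for a in range(n_quantiles):
        for b in range(a, n_quantiles):
            block = oe[np.ix_(groups[a], groups[b])].astype(float).copy()
            if a == b:
                np.fill_diagonal(block, np.nan)
            v = block[~np.isnan(block)]
            if v.size:
                grid[a, b] = grid[b, a] = v.mean()
    return grid
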