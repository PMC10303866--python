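"""File I/O for the pipeline's standard formats.

Coordinate convention is 0-based half-open everywhere internally;
BED/bedGraph already use that convention so conversion is the identity.
Sparse triplet contact files store the upper triangle only and symmetry
is materialized on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    BoundsError,
    DimensionError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "GenomeBins",
    "NucleusImage",
    "FluorTrace",
    "make_bins",
    "read_bins",
    "write_bins",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_track",
    "write_track",
    "read_bed",
    "write_bed",
    "read_image",
    "write_image",
    "read_trace",
    "write_trace",
]


@dataclass(frozen=True)
class GenomeBins:
    """Dense table of uniform genomic bins, 0-based half-open.

    Within a chromosome bins are contiguous, sorted and non-overlapping;
    the bin index is dense ``0..n-1`` across the whole table.
    """

    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray  # bp, inclusive
    ends: np.ndarray    # bp, exclusive
    bin_size: int       # nominal uniform size (last bin per chrom may be short)

    def __post_init__(self) -> None:
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == n):
            raise DimensionError("bin table columns have unequal lengths")
        if np.any(self.ends <= self.starts):
            raise ValidationError("bins must satisfy start < end")
        for chrom in self.chrom_names:
            sel = self.chroms == chrom
            s, e = self.starts[sel], self.ends[sel]
            if np.any(s[1:] != e[:-1]):
                raise ValidationError(f"bins on {chrom} are not contiguous")

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    @property
    def chrom_names(self) -> list[str]:
        # preserve first-appearance order
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(str(c), None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice of one chromosome's bins (bins are grouped by chrom)."""
        idx = np.flatnonzero(self.chroms == chrom)
        if idx.size == 0:
            raise BoundsError(f"unknown chromosome {chrom!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chroms, "start": self.starts, "end": self.ends,
             "bin": np.arange(self.n_bins)}
        )


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> GenomeBins:
    """Tile chromosomes with uniform bins (last bin may be short)."""
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom, size in chrom_sizes.items():
        edges = list(range(0, size, bin_size)) + [size]
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    return GenomeBins(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        bin_size,
    )


def write_bins(bins: GenomeBins, path: str | Path) -> None:
    bins.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bins(path: str | Path, bin_size: int | None = None) -> GenomeBins:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "bin"])
    if bin_size is None:
        bin_size = int((df["end"] - df["start"]).max())
    return GenomeBins(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(dtype=np.int64),
        df["end"].to_numpy(dtype=np.int64),
        bin_size,
    )


# ---------------------------------------------------------------------------
# contact matrices


def read_contact_matrix(path: str | Path, bins: GenomeBins,
                        dialect: str = "triplet"):
    """Read a binned contact matrix as a :class:`~vermicelli.hic.ContactMatrix`.

    ``dialect="dense-tsv"`` expects an n x n tab-separated matrix;
    ``dialect="triplet"`` expects whitespace rows ``bin_i bin_j count``
    covering the upper triangle (i <= j); symmetry is materialized.
    """
    from .hic import ContactMatrix  # deferred: hic imports io types

    n = bins.n_bins
    path = Path(path)
    if dialect == "dense-tsv":
        m = np.loadtxt(path, dtype=float, ndmin=2)
        if m.shape != (n, n):
            raise DimensionError(
                f"dense matrix is {m.shape}, bin table has {n} bins")
        if not np.allclose(m, m.T):
            raise ValidationError("dense matrix is not symmetric")
    elif dialect == "triplet":
        m = np.zeros((n, n), dtype=float)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 fields, "
                                     f"got {len(parts)}")
                try:
                    i, j = int(parts[0]), int(parts[1])
                    c = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if not (0 <= i < n and 0 <= j < n):
                    raise BoundsError(
                        f"{path}:{lineno}: bin pair ({i},{j}) out of range "
                        f"for {n} bins")
                if c < 0:
                    raise ValidationError(
                        f"{path}:{lineno}: negative count {c}")
                m[i, j] += c
                if i != j:
                    m[j, i] += c
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if np.any(m < 0):
        raise ValidationError("contact matrix has negative counts")
    return ContactMatrix(counts=m, bins=bins)


def write_contact_matrix(matrix, path: str | Path,
                         dialect: str = "triplet") -> None:
    """Write a contact matrix (upper triangle only for triplet files)."""
    path = Path(path)
    m = matrix.counts
    if dialect == "dense-tsv":
        np.savetxt(path, m, delimiter="\t", fmt="%.10g")
    elif dialect == "triplet":
        iu, ju = np.triu_indices(m.shape[0])
        keep = m[iu, ju] != 0
        with open(path, "w") as fh:
            for i, j, c in zip(iu[keep], ju[keep], m[iu, ju][keep]):
                fh.write(f"{i} {j} {c:.10g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tracks / intervals


def write_track(values: np.ndarray, bins: GenomeBins, path: str | Path) -> None:
    """Write one value per bin as bedGraph; NaN values become absent rows."""
    values = np.asarray(values, dtype=float)
    if values.shape != (bins.n_bins,):
        raise DimensionError(
            f"{values.shape[0]} values for {bins.n_bins} bins")
    with open(path, "w") as fh:
        for chrom, s, e, v in zip(bins.chroms, bins.starts, bins.ends, values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")


def read_track(path: str | Path, bins: GenomeBins) -> np.ndarray:
    """Read a bedGraph back onto the bin grid; absent bins become NaN."""
    values = np.full(bins.n_bins, np.nan)
    key = {(str(c), int(s)): k for k, (c, s) in
           enumerate(zip(bins.chroms, bins.starts))}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"],
                     float_precision="round_trip")
    for row in df.itertuples(index=False):
        k = key.get((str(row.chrom), int(row.start)))
        if k is None:
            raise BoundsError(
                f"bedGraph interval {row.chrom}:{row.start} not on bin grid")
        values[k] = row.value
    return values


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write chrom/start/end(/name/score) intervals as BED (0-based half-open)."""
    cols = [c for c in ("chrom", "start", "end", "name", "score")
            if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df.columns = names
    return df


# ---------------------------------------------------------------------------
# images


@dataclass
class NucleusImage:
    """2D intensity grid with nucleus and exclusion (nucleolus) masks.

    ``exclusion`` marks pixels whose intensity is forced to zero before
    box analysis (nucleoli and extranuclear regions).
    """

    intensity: np.ndarray
    pixel_size: float  # um / pixel
    nucleus_mask: np.ndarray | None = None
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim not in (2, 3):
            raise ValidationError("image must be 2D or 3D")
        if np.any(self.intensity < 0):
            raise ValidationError("image intensities must be non-negative")
        if self.nucleus_mask is None:
            self.nucleus_mask = np.ones(self.intensity.shape, dtype=bool)
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros(self.intensity.shape, dtype=bool)
        for m in (self.nucleus_mask, self.exclusion_mask):
            if m.shape != self.intensity.shape:
                raise DimensionError("mask shape differs from image shape")

    @property
    def analysis_mask(self) -> np.ndarray:
        """Pixels that enter statistics: nucleus minus exclusions."""
        return self.nucleus_mask & ~self.exclusion_mask


def read_image(path: str | Path, pixel_size: float = 1.0) -> NucleusImage:
    arr = tifffile.imread(path)
    if arr.ndim not in (2, 3):
        raise ValidationError(f"TIFF has {arr.ndim} dimensions, expected 2 or 3")
    if np.any(arr < 0):
        raise ValidationError("TIFF contains negative intensities")
    return NucleusImage(intensity=np.asarray(arr, dtype=float),
                        pixel_size=pixel_size)


def write_image(img: NucleusImage | np.ndarray, path: str | Path) -> None:
    arr = img.intensity if isinstance(img, NucleusImage) else np.asarray(img)
    tifffile.imwrite(path, arr.astype(np.float32))


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class FluorTrace:
    """Time series of bleached-ROI and reference-ROI intensities.

    The first ``pre_bleach_count`` frames precede the bleach pulse.
    """

    times: np.ndarray      # seconds
    bleached: np.ndarray   # arbitrary units
    reference: np.ndarray  # arbitrary units
    pre_bleach_count: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.times)
        if not (len(self.bleached) == len(self.reference) == n):
            raise DimensionError("trace columns have unequal lengths")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if self.pre_bleach_count < 1:
            raise ValidationError("pre_bleach_count must be >= 1")
        if self.pre_bleach_count >= n:
            raise ValidationError("trace has no post-bleach frames")


def write_trace(trace: FluorTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pre_bleach_count: {trace.pre_bleach_count}\n")
        fh.write("time,bleached,reference\n")
        for t, b, r in zip(trace.times, trace.bleached, trace.reference):
            fh.write(f"{t:.10g},{b:.10g},{r:.10g}\n")


def read_trace(path: str | Path) -> FluorTrace:
    path = Path(path)
    pre = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "pre_bleach_count" in first:
        pre = int(first.split(":")[1])
    df = pd.read_csv(path, comment="#")
    for col in ("time", "bleached", "reference"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if pre is None:
        raise SchemaError(f"{path}: missing '# pre_bleach_count:' header")
    return FluorTrace(
        times=df["time"].to_numpy(),
        bleached=df["bleached"].to_numpy(),
        reference=df["reference"].to_numpy(),
        pre_bleach_count=pre,
    )
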