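"""Synthetic-data generators with known ground truth.

Every analysis stage in the pipeline is testable against these
generators: contact maps with power-law distance decay, checkerboard
compartments, TAD blocks and corner peaks under Poisson counting noise;
nucleus images with fibrous bead patterns under Poisson+Gaussian camera
noise; double-exponential FRAP recovery traces with acquisition
photobleaching; and 3D voxel clouds for radius-of-gyration calibration.

All generators are pure functions of their parameter object, including
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError
from .io import FluorTrace, GenomeBins, NucleusImage, make_bins

__all__ = [
    "HiCSimParams",
    "ImageSimParams",
    "FrapSimParams",
    "TerritorySimParams",
    "simulate_contact_map",
    "simulate_nucleus_image",
    "simulate_frap_trace",
    "simulate_ifrap_trace",
    "simulate_territory",
    "control_preset",
    "oe_preset",
]


# ---------------------------------------------------------------------------
# Hi-C contact maps


@dataclass(frozen=True)
class HiCSimParams:
    """Parameters of the synthetic Hi-C contact-map model.

    The expected matrix is
    ``E[i,j] = scale * (|i-j|+1)**(-alpha) * c_ij * t_ij * g_ij`` where
    ``c_ij = 1+epsilon`` for same-compartment bin pairs and ``1-epsilon``
    otherwise, ``t_ij = 1+beta`` inside a TAD (``1+inter_tad_boost`` for
    adjacent-TAD pairs), and ``g_ij = 1+gamma`` within ``corner_width``
    bins of a TAD's corner pair. Counts are Poisson(E), symmetrized, with
    ``scale`` set so the expected total equals ``depth``.
    """

    n_bins: int = 400
    bin_size: int = 150_000                    # bp
    alpha: float = 1.0                         # decay exponent
    compartment_labels: np.ndarray | None = None  # +1 (A) / -1 (B) per bin
    block_size: int = 20                       # bins, used when labels absent
    epsilon: float = 0.4                       # compartment strength, [0, 1)
    tad_boundaries: tuple[int, ...] | None = None  # strictly inside (0, n)
    tad_size: int = 25                         # bins, used when boundaries absent
    beta: float = 1.0                          # TAD strength >= 0
    gamma: float = 0.2                         # corner-peak strength >= 0
    corner_width: int = 2                      # bins
    inter_tad_boost: float = 0.0               # adjacent-TAD contact boost >= 0
    depth: float = 2_000_000                   # expected total contacts
    expected_only: bool = False                # skip Poisson sampling
    seed: int = 0

    def labels(self) -> np.ndarray:
        if self.compartment_labels is not None:
            lab = np.asarray(self.compartment_labels)
            if lab.shape != (self.n_bins,):
                raise ParameterError("compartment_labels length != n_bins")
            return lab
        # alternating A/B blocks
        return np.where((np.arange(self.n_bins) // self.block_size) % 2 == 0,
                        1, -1)

    def boundaries(self) -> np.ndarray:
        if self.tad_boundaries is not None:
            b = np.asarray(self.tad_boundaries, dtype=int)
        else:
            b = np.arange(self.tad_size, self.n_bins, self.tad_size)
        if np.any(np.diff(b) <= 0) or (b.size and
                                       (b[0] <= 0 or b[-1] >= self.n_bins)):
            raise ParameterError(
                "tad_boundaries must be strictly increasing inside (0, n_bins)")
        return b


def _tad_intervals(boundaries: np.ndarray, n_bins: int) -> list[tuple[int, int]]:
    edges = [0, *boundaries.tolist(), n_bins]
    return list(zip(edges[:-1], edges[1:]))


def expected_contact_matrix(params: HiCSimParams) -> np.ndarray:
    """Closed-form expected matrix of the generator, scaled to ``depth``."""
    if not (0 <= params.epsilon < 1):
        raise ParameterError("epsilon must lie in [0, 1)")
    if params.beta < 0 or params.gamma < 0 or params.inter_tad_boost < 0:
        raise ParameterError("beta, gamma and inter_tad_boost must be >= 0")
    n = params.n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    e = (dist + 1.0) ** (-params.alpha)

    lab = params.labels()
    same = lab[:, None] == lab[None, :]
    e = e * np.where(same, 1.0 + params.epsilon, 1.0 - params.epsilon)

    tads = _tad_intervals(params.boundaries(), n)
    tad_id = np.empty(n, dtype=int)
    for k, (s, t) in enumerate(tads):
        tad_id[s:t] = k
    same_tad = tad_id[:, None] == tad_id[None, :]
    e = e * np.where(same_tad, 1.0 + params.beta, 1.0)
    if params.inter_tad_boost > 0:
        adjacent = np.abs(tad_id[:, None] - tad_id[None, :]) == 1
        e = e * np.where(adjacent, 1.0 + params.inter_tad_boost, 1.0)

    if params.gamma > 0:
        w = params.corner_width
        g = np.zeros((n, n))
        for s, t in tads:
            lo = slice(s, min(s + w, t))
            hi = slice(max(t - w, s), t)
            g[lo, hi] = params.gamma
            g[hi, lo] = params.gamma
        e = e * (1.0 + g)

    if np.any(e <= 0):
        raise ParameterError("expected matrix must be strictly positive")
    e *= params.depth / e.sum()
    return e


def simulate_contact_map(params: HiCSimParams):
    """Simulate one contact map; returns (matrix, truth dict).

    Truth carries the planted compartment labels (+1/-1), TAD boundaries
    (bin indices) and TAD intervals (half-open in bins).
    """
    from .hic import ContactMatrix

    e = expected_contact_matrix(params)
    n = params.n_bins
    if params.expected_only:
        counts = e
    else:
        rng = np.random.default_rng(params.seed)
        iu, ju = np.triu_indices(n)
        counts = np.zeros((n, n))
        sampled = rng.poisson(e[iu, ju])
        counts[iu, ju] = sampled
        counts[ju, iu] = sampled
    bins = make_bins({"chrS": n * params.bin_size}, params.bin_size)
    truth = {
        "labels": params.labels(),
        "boundaries": params.boundaries(),
        "tads": _tad_intervals(params.boundaries(), n),
    }
    return ContactMatrix(counts=counts, bins=bins), truth


def control_preset(**overrides) -> HiCSimParams:
    """Condition emulating the unperturbed genome: strong compartments,
    moderate corner signal, shallow decay."""
    base = HiCSimParams(alpha=1.0, epsilon=0.4, gamma=0.2,
                        inter_tad_boost=0.0)
    return replace(base, **overrides)


def oe_preset(**overrides) -> HiCSimParams:
    """Condition emulating cohesin-overloaded nuclei: weakened compartments,
    strong TAD-corner accumulation, steeper decay (short-range contacts up,
    long-range down) and boosted adjacent-TAD mixing. TAD boundaries match
    the control preset."""
    base = HiCSimParams(alpha=1.15, epsilon=0.2, gamma=1.0,
                        inter_tad_boost=0.5)
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# nucleus images


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of the synthetic nucleus-image model.

    ``vermicelli`` mode draws smoothed random-walk fibers inside an
    elliptical nucleus and places Gaussian beads along each fiber's arc
    length every ``bead_spacing`` (+/- jitter); ``uniform`` mode is flat
    background inside the nucleus. Camera noise is Poisson or additive
    Gaussian.
    """

    height: int = 256
    width: int = 256
    pixel_size: float = 0.05        # um / pixel
    mode: str = "vermicelli"        # or "uniform"
    n_fibers: int = 4
    bead_spacing: float = 0.34      # um
    spacing_jitter_sd: float = 0.03  # um
    bead_amplitude: float = 200.0   # photons at bead peak
    background: float = 20.0        # photons per pixel inside nucleus
    psf_sigma: float = 0.1          # um
    nucleolus_count: int = 0
    nucleolus_radius: int = 12      # pixels
    fiber_steps: int = 300          # random-walk steps ~ arc length in px
    noise: str = "poisson"          # "poisson", "gaussian", or "none"
    gaussian_sd: float = 0.0
    seed: int = 0


def _nucleus_mask(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = 0.45 * h, 0.45 * w
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _random_fiber(rng: np.random.Generator, mask: np.ndarray,
                  step_px: float = 1.0, curvature: float = 0.05,
                  max_steps: int = 300) -> np.ndarray:
    """Smoothed random walk (y, x) path confined to the mask interior."""
    h, w = mask.shape
    inside = np.argwhere(ndimage.binary_erosion(mask, iterations=8))
    y, x = inside[rng.integers(len(inside))].astype(float)
    theta = rng.uniform(0, 2 * np.pi)
    path = [(y, x)]
    for _ in range(max_steps):
        theta += rng.normal(0, curvature)
        ny, nx = y + step_px * np.sin(theta), x + step_px * np.cos(theta)
        iy, ix = int(round(ny)), int(round(nx))
        if not (0 <= iy < h and 0 <= ix < w and mask[iy, ix]):
            break  # fiber leaves the section at the nucleus margin
        y, x = ny, nx
        path.append((y, x))
    return np.asarray(path)


def _beads_on_path(path: np.ndarray, spacing_px: float, jitter_px: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Place beads along the path's arc length at spacing (+jitter)."""
    seglen = np.hypot(*np.diff(path, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    beads = []
    s = spacing_px / 2
    while s < total:
        k = np.searchsorted(arclen, s) - 1
        k = min(max(k, 0), len(path) - 2)
        frac = (s - arclen[k]) / max(arclen[k + 1] - arclen[k], 1e-12)
        beads.append(path[k] + frac * (path[k + 1] - path[k]))
        step = spacing_px + (rng.normal(0, jitter_px) if jitter_px > 0 else 0.0)
        s += max(step, 0.1 * spacing_px)
    return np.asarray(beads).reshape(-1, 2)


def _render_gaussians(shape: tuple[int, int], centers: np.ndarray,
                      amplitude: float, sigma_px: float) -> np.ndarray:
    img = np.zeros(shape)
    if len(centers) == 0:
        return img
    r = int(np.ceil(4 * sigma_px))
    for cy, cx in centers:
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 2
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 2
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))
    return img


def simulate_nucleus_image(params: ImageSimParams):
    """Simulate one nucleus image; returns (NucleusImage, truth beads, fiber id).

    Truth beads are (y, x) sub-pixel coordinates in pixels, one row per
    planted bead; fiber id assigns each bead to its fiber, in order along
    the fiber's arc length.
    """
    psf_px = params.psf_sigma / params.pixel_size
    spacing_px = params.bead_spacing / params.pixel_size
    if params.mode == "vermicelli" and spacing_px <= 2 * psf_px:
        raise ParameterError(
            "bead_spacing must exceed 2*psf_sigma for resolvable beads")
    h, w = params.height, params.width
    if min(h, w) < 8 * max(psf_px, 1.0):
        raise ParameterError("nucleus smaller than PSF support")
    rng = np.random.default_rng(params.seed)
    nucleus = _nucleus_mask(h, w)

    exclusion = np.zeros((h, w), dtype=bool)
    for _ in range(params.nucleolus_count):
        inside = np.argwhere(ndimage.binary_erosion(
            nucleus, iterations=params.nucleolus_radius + 2))
        cy, cx = inside[rng.integers(len(inside))]
        yy, xx = np.mgrid[0:h, 0:w]
        exclusion |= (yy - cy) ** 2 + (xx - cx) ** 2 <= params.nucleolus_radius ** 2

    beads = np.empty((0, 2))
    fiber_id = np.empty(0, dtype=int)
    img = np.where(nucleus, params.background, 0.0)
    if params.mode == "vermicelli":
        jitter_px = params.spacing_jitter_sd / params.pixel_size
        placeable = nucleus & ~exclusion
        # fibers exclude each other (chromatin fibers do not interpenetrate
        # within a thin optical section), keeping planted beads resolvable
        gap = max(int(np.ceil(2 * psf_px)), 1)
        occupied = np.zeros((h, w), dtype=bool)
        all_beads, all_ids = [], []
        for f in range(params.n_fibers):
            path = _random_fiber(rng, placeable & ~occupied,
                                 max_steps=params.fiber_steps)
            fb = _beads_on_path(path, spacing_px, jitter_px, rng)
            stamp = np.zeros((h, w), dtype=bool)
            iy = np.clip(np.round(path[:, 0]).astype(int), 0, h - 1)
            ix = np.clip(np.round(path[:, 1]).astype(int), 0, w - 1)
            stamp[iy, ix] = True
            occupied |= ndimage.binary_dilation(stamp, iterations=gap)
            if len(fb):
                all_beads.append(fb)
                all_ids.append(np.full(len(fb), f))
        if all_beads:
            beads = np.vstack(all_beads)
            fiber_id = np.concatenate(all_ids)
        img = img + _render_gaussians((h, w), beads, params.bead_amplitude,
                                      psf_px)
    elif params.mode != "uniform":
        raise ParameterError(f"unknown image mode {params.mode!r}")

    img[exclusion] = 0.0
    img[~nucleus] = 0.0
    if params.noise == "poisson":
        img = rng.poisson(img).astype(float)
    elif params.noise == "gaussian":
        img = np.clip(img + rng.normal(0, params.gaussian_sd, img.shape), 0,
                      None)
    elif params.noise != "none":
        raise ParameterError(f"unknown noise model {params.noise!r}")

    nimg = NucleusImage(intensity=img, pixel_size=params.pixel_size,
                        nucleus_mask=nucleus, exclusion_mask=exclusion)
    return nimg, beads, fiber_id


# ---------------------------------------------------------------------------
# FRAP / iFRAP traces


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of the synthetic FRAP / iFRAP trace model.

    FRAP mode inverts the analysis model
    ``F(t) = A(1-exp(-t/tauA)) + B(1-exp(-t/tauB))`` (post-bleach, t=0 at
    the first post-bleach frame); iFRAP mode produces an unbleached-region
    decay ``a*exp(-t/ifrap_tau) + ifrap_plateau``. Both channels decay by
    ``acquisition_bleach_rate`` per acquired frame; Gaussian read noise
    with sd ``noise_sd`` is added.
    """

    A: float = 0.3
    B: float = 0.5
    tauA: float = 2.0               # s
    tauB: float = 30.0              # s
    dt: float = 1.0                 # s
    n_pre: int = 3
    n_post: int = 300
    acquisition_bleach_rate: float = 0.0  # fraction per frame
    noise_sd: float = 0.0
    mode: str = "frap"
    ifrap_tau: float = 600.0        # s
    ifrap_plateau: float = 0.2
    ifrap_amplitude: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A + self.B > 1.0 + 1e-12:
            raise ParameterError("A + B must be <= 1")
        if self.tauA > self.tauB:
            raise ParameterError("tauA must be <= tauB")
        if self.n_pre < 1:
            raise ParameterError("n_pre must be >= 1 (normalization anchor)")


def frap_recovery(t: np.ndarray, A: float, tauA: float, B: float,
                  tauB: float) -> np.ndarray:
    """Double-exponential recovery F(t) = A(1-e^(-t/tauA)) + B(1-e^(-t/tauB))."""
    t = np.asarray(t, dtype=float)
    return A * (1 - np.exp(-t / tauA)) + B * (1 - np.exp(-t / tauB))


def simulate_frap_trace(params: FrapSimParams) -> FluorTrace:
    """Simulate a FRAP trace: pre-bleach frames at 1, then the recovery."""
    if params.mode != "frap":
        raise ParameterError("simulate_frap_trace requires mode='frap'")
    rng = np.random.default_rng(params.seed)
    n = params.n_pre + params.n_post
    frames = np.arange(n)
    times = frames * params.dt
    post_t = (frames[params.n_pre:] - params.n_pre) * params.dt
    signal = np.concatenate([
        np.ones(params.n_pre),
        frap_recovery(post_t, params.A, params.tauA, params.B, params.tauB),
    ])
    decay = (1.0 - params.acquisition_bleach_rate) ** frames
    bleached = signal * decay
    reference = decay.copy()
    if params.noise_sd > 0:
        bleached = bleached + rng.normal(0, params.noise_sd, n)
        reference = reference + rng.normal(0, params.noise_sd, n)
    eps = 1e-6  # keep intensities positive as real photon counts are
    return FluorTrace(times=times, bleached=np.clip(bleached, eps, None),
                      reference=np.clip(reference, eps, None),
                      pre_bleach_count=params.n_pre)


def simulate_ifrap_trace(params: FrapSimParams) -> FluorTrace:
    """Simulate an iFRAP (FLIP) unbleached-region decay trace."""
    if params.mode != "ifrap":
        raise ParameterError("simulate_ifrap_trace requires mode='ifrap'")
    rng = np.random.default_rng(params.seed)
    n = params.n_pre + params.n_post
    frames = np.arange(n)
    times = frames * params.dt
    post_t = (frames[params.n_pre:] - params.n_pre) * params.dt
    signal = np.concatenate([
        np.ones(params.n_pre),
        params.ifrap_amplitude * np.exp(-post_t / params.ifrap_tau)
        + params.ifrap_plateau,
    ])
    decay = (1.0 - params.acquisition_bleach_rate) ** frames
    bleached = signal * decay
    reference = decay.copy()
    if params.noise_sd > 0:
        bleached = bleached + rng.normal(0, params.noise_sd, n)
        reference = reference + rng.normal(0, params.noise_sd, n)
    eps = 1e-6
    return FluorTrace(times=times, bleached=np.clip(bleached, eps, None),
                      reference=np.clip(reference, eps, None),
                      pre_bleach_count=params.n_pre)


# ---------------------------------------------------------------------------
# chromosome-territory voxel clouds


@dataclass(frozen=True)
class TerritorySimParams:
    """Parameters for synthetic 3D chromosome-territory voxel clouds."""

    shape: str = "ball"             # "ball" or "fiber"
    radius: float = 20.0            # voxels (ball) or fiber half-thickness
    fiber_length: int = 200         # voxels along the fiber axis
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # um (z, y, x)
    intensity_model: str = "uniform"  # or "gradient"
    seed: int = 0


def simulate_territory(params: TerritorySimParams):
    """Generate a voxel cloud; returns a :class:`~vermicelli.geometry.VoxelCloud`.

    ``ball`` fills every voxel whose center lies within ``radius`` of the
    ball center; ``fiber`` is a straight tube of the same half-thickness,
    ``fiber_length`` voxels long.
    """
    from .geometry import VoxelCloud

    if params.radius < 1:
        raise ParameterError("radius must be >= 1 voxel")
    r = params.radius
    if params.shape == "ball":
        n = int(np.ceil(r))
        zz, yy, xx = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
        keep = zz ** 2 + yy ** 2 + xx ** 2 <= r ** 2
        coords = np.column_stack([zz[keep], yy[keep], xx[keep]])
    elif params.shape == "fiber":
        n = int(np.ceil(r))
        half = params.fiber_length // 2
        zz, yy, xx = np.mgrid[-n:n + 1, -n:n + 1, -half:half + 1]
        keep = zz ** 2 + yy ** 2 <= r ** 2
        coords = np.column_stack([zz[keep], yy[keep], xx[keep]])
    else:
        raise ParameterError(f"unknown territory shape {params.shape!r}")

    if params.intensity_model == "uniform":
        intens = np.ones(len(coords))
    elif params.intensity_model == "gradient":
        d = np.linalg.norm(coords, axis=1)
        intens = 1.0 + d / max(d.max(), 1.0)
    else:
        raise ParameterError(
            f"unknown intensity model {params.intensity_model!r}")
    return VoxelCloud(coords=coords, intensities=intens,
                      voxel_size=np.asarray(params.voxel_size, dtype=float))
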