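# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Synthetic contact maps

The generator draws a symmetric count matrix from a closed-form
expectation

    E[i,j] = scale · (|i−j|+1)^(−α) · c_ij · t_ij · g_ij

with `c_ij = 1+ε` for same-compartment bin pairs and `1−ε` otherwise
(ε ∈ [0,1), compartments assigned in alternating blocks or from an
explicit ±1 label vector), `t_ij = 1+β` inside a TAD and
`1 + inter_tad_boost` for adjacent-TAD pairs, and `g_ij = 1+γ` within
`corner_width` bins of each TAD's corner pair (left boundary, right
boundary − 1). The `+1` in the decay regularizes s = 0 so the expected
matrix is finite and monotone; `scale` is set so the expected total
equals `depth`. Counts are Poisson-sampled on the upper triangle and
mirrored; an expected-value mode skips sampling so estimator
correctness can be tested separately from counting noise.

Two named presets form a paired study condition:

| parameter | control | OE-like | why |
|---|---|---|---|
| α (decay) | 1.00 | 1.15 | steeper decay moves contact mass to short range, producing the short-up / long-down P(s) contrast with one crossing |
| ε (compartment strength) | 0.4 | 0.2 | weaker checkerboard → higher AB/(AA+BB) mixing ratio, lower saddle corners |
| γ (corner peaks) | 0.2 | 1.0 | accumulated contacts at TAD corners |
| inter_tad_boost | 0.0 | 0.5 | more contact between neighboring TADs → lower TAD score |
| β, TAD boundaries | shared | shared | TAD count and length unchanged between conditions |

Defaults elsewhere: 400 bins, depth 2×10⁶ contacts per map (a
well-covered single-chromosome arm at the chosen binning), corner width
2 bins. The generator does not model coverage bias beyond what Poisson
sampling induces, loop-extrusion dynamics, or replication timing; a
passing contrast therefore shows that the estimators read out the
planted structure, not that real maps are this clean.

In the end-to-end comparison the "short range" band is defined as
distances up to twice the TAD size (where corner peaks and adjacent-TAD
mixing act) and "long range" as beyond four TAD sizes (pure decay
contrast); the single-crossing check counts sign changes of the P(s)
difference restricted to well-sampled distance bins (≥100 pairs) with a
relative difference of at least 5%, which ignores sub-noise wiggles.

## Synthetic nucleus images

Fibers are smoothed random walks (step 1 px, heading diffusion 0.05
rad/step, up to 300 steps) inside an elliptical nucleus; a fiber
terminates at the nucleus margin or when it would enter the dilated
footprint of an earlier fiber — chromatin fibers in a thin optical
section do not interpenetrate, and this keeps every planted bead
resolvable, matching the generator's own precondition
(bead_spacing > 2·psf_sigma). Beads are placed along the arc length
every `bead_spacing` (default 0.34 µm) with Gaussian jitter (sd
0.03 µm), rendered as Gaussian spots (PSF sigma 0.1 µm) of amplitude
200 photons over a background of 20 inside the nucleus (peak SNR ≈ 13
under Poisson noise), at 0.05 µm/pixel over 256×256 px. Uniform mode is
flat background. Optional nucleolus discs are zeroed and excluded.
Sparse fibers (default 4) are the condition for bead-spacing
measurements; the heterogeneity contrast uses a dense condition
(30 fibers) because the fibrous phenotype fills the nucleus. The
generator emulates neither optical aberrations, 3D defocus, nor
deconvolution artifacts; detection performance on real data will be
worse than on these images.

## Heterogeneity level

Excluded pixels are set to zero, the nucleus is rescaled to a common
mean (default 100) so expression level drops out, and 5×5-pixel
non-overlapping box means are collected; a box containing any zero
pixel is discarded (a partially masked box would bias the low mode).
The box-value distribution, histogrammed at Freedman–Diaconis width
(10–200 bins) and density-normalized, is fitted by nonlinear least
squares with w·N(μ₁,σ₁²) + (1−w)·N(μ₂,σ₂²), initialized at the 25th and
75th percentiles, components ordered so μ₁ ≤ μ₂. The statistic is
μ₂ − μ₁. Constant input returns 0; a fit whose separation is under one
pooled standard deviation is flagged `unimodal` rather than rejected.
Tests cross-check the histogram fit against a two-component EM mixture
on the raw values to guard against binning artifacts. Tiling (stride =
box) rather than sliding was chosen because tiles give approximately
independent samples for the mixture fit; stride is configurable.

## Bead detection and spacing

The image is band-passed with a difference of Gaussians at sigmas
(psf/2, psf): the sub-PSF detection scale resolves beads down to about
two PSF sigmas apart, which PSF-scale smoothing would merge. Local
maxima above `threshold` (default 0.3) times the 99th percentile of the
in-mask band response — a bright-bead scale robust to rare extra-bright
fiber crossings; if that percentile is non-positive, e.g. one isolated
spot, the band maximum is used instead — and separated by at least
`min_separation` (default 0.15 µm) are kept and refined to sub-pixel
positions by 1D quadratic interpolation. Fibers are chained by
repeatedly linking mutually nearest neighbors within 2× the expected
spacing, each bead accepting at most two links and cycles rejected;
spacings are Euclidean distances between order-consecutive beads of one
chain, in 2D. Beads from crossing fibers closer than the declared
minimum separation are intrinsically unresolvable and count against
recall; the self-avoiding generator keeps such cases rare.

## FRAP / iFRAP

Photobleaching correction divides the bleached-ROI intensity by the
reference-ROI intensity normalized to its pre-bleach mean; the
pre-bleach reference mean survives as a constant factor that the
subsequent affine normalization (pre-bleach mean → 1, first post-bleach
→ 0) removes. The recovery is fitted by least squares with
F(t) = A(1−e^(−t/τ_A)) + B(1−e^(−t/τ_B)), bounds A, B ∈ [0, 1.5] and
τ ∈ (0, 10⁵ s]. Initialization: τ_B from a log-linear fit to the
recovery deficit over the last third of the trace, τ_A = τ_B/10,
amplitudes from the plateau split; components are reordered so
τ_A ≤ τ_B and the residence time is τ_B. A component amplitude below
10⁻³ marks the fit `degenerate` (effectively single-exponential);
τ_B/τ_A < 2 marks it `poorly_separated` — at that ratio the two
exponentials are barely identifiable and downstream use should see the
flag. Time origin is the first post-bleach frame. Reaction–diffusion
modeling is out of scope; the biexponential is a phenomenological
residence-time readout.

## Radius of gyration

Components are labeled under 26-connectivity by default (6 available).
Rg uses intensity weights and physical per-axis voxel sizes, so
anisotropic z-sampling is corrected before distances; an uncorrected
mode is a matter of passing unit voxel sizes. Raw intensities are used
as weights (no background subtraction) — background inside a segmented
territory is assumed negligible after segmentation.

## Hi-C statistics

*ICE balancing* iterates `w ← w / sqrt(marginal/mean)` until the
coefficient of variation of unmasked marginals drops below `tol`
(default 10⁻⁵, max 200 iterations; non-convergence is flagged, not
raised), then scales the balanced matrix to mean 1 per valid pixel.
Coverage masking removes bins that are both below median − 3·MAD of the
marginals and below half the median: the second clause prevents
near-uniform marginal distributions (MAD ≈ 0, as in balanced or
synthetic matrices) from masking half the bins; for generated maps,
which have no technical dropout, masking can be disabled entirely
(`min_coverage_mad=0`), and the analysis drivers do so.

*Insulation scores* (per 40-kb bin in the standard configuration)
average the balanced matrix over the square [i−w, i) × [i, i+w) (window
500 kb default) and report log2 of that mean over its chromosome-wide
mean. Windows with masked bins are averaged over their valid pixels
down to 50% coverage; sparser windows and edge bins are NaN. Boundaries
are downward zero crossings of the delta vector (mean score over
`delta_window` to the left minus right), placed at the score minimum
within ± delta_window, kept when the delta swing reaches
`min_strength` (default 0.1 log2 units).

*TAD score* is the mean balanced intra-TAD contact (diagonal excluded)
over the mean contact with the two adjacent TADs; the bounded-distance
contrast is robust to P(s) decay, unlike an all-pairs denominator. TADs
under 3 bins are skipped. *ATA* rescales each TAD window (± 50% flanks)
of the O/E matrix to 90×90 px by bilinear interpolation, averaging with
NaN-aware weights; O/E rather than balanced signal prevents TAD-size
confounding. *P(s)* uses geometric distance bins (factor 1.12), excludes
the zero diagonal, and normalizes the curve to sum 1; the log-log slope
is fitted on log(s+1) to match the generator's regularized decay, so an
expected-value simulation with exponent α fits slope −α exactly (the
offset is a parameter).

*PC1* is the leading eigenvector of the Pearson-correlation matrix of
the per-chromosome O/E map (150-kb bins in the standard configuration),
sign-oriented against a gene-density-like track; rows with numerically
zero variance carry no plaid and are zeroed before the eigenproblem,
and a leading eigenvalue separated by less than 10⁻⁸ (relative) flags
the profile degenerate. Whole chromosomes are used (no arm splitting by
default). Bins with PC1 exactly 0 are undetermined — the switch
accounting is a strict sign test over bins determined in both
conditions, reported as bin fractions. The mixing ratio sums balanced
contacts over unordered A–B pairs divided by A–A plus B–B pairs,
diagonal excluded (sums, not means; a mean variant would weight classes
differently when their sizes differ). Saddles use 5 equal-count PC1
quantile groups by default.

## Problem sizes and determinism

Default analysis sizes — 100–400-bin matrices, depth 5×10⁵–2×10⁶,
256×256-px images, 300-frame traces, 20-seed replication, 100 seeds for
FRAP noise statistics — were chosen so each stage's statistical claims
are testable with comfortable margins while the full suite and the
acceptance script each run in well under a minute of compute per stage.
Every stochastic component consumes an explicit integer seed
(`numpy.random.default_rng`); identical configuration and seed
reproduce outputs bit-identically.

## Known limitations

- All image analysis is 2D; bead spacing in 3D would differ for fibers
  tilted out of plane (projected distances underestimate true ones).
- The contact-map generator's marginals are structured, so MAD-based
  coverage masking misreads them as dropouts unless disabled; on real
  matrices the default masking is appropriate.
- The insulation boundary caller assumes point boundaries between
  tiling TADs; nested or overlapping domain structure is out of scope.
- The biexponential FRAP fit reports, but does not resolve, time
  constants closer than 2×.
- Compartment calling on matrices with no plaid (ε = 0) is flagged
  degenerate rather than refused; callers must check the flag.
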