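# vermicelli

Quantitative analysis of cohesin "vermicelli" phenotypes — the
thread-like axial distribution that chromatin-bound cohesin adopts in
nuclei with up-regulated RAD21 — for microscopists and genome biologists
who need the image, kinetic and Hi-C statistics of that state in one
tested pipeline.

When RAD21, the kleisin subunit of cohesin, is over-expressed, loaded
cohesin accumulates on chromatin: the protein redistributes from a
uniform nuclear signal into fibers carrying regularly spaced "beads",
chromatin-bound cohesin stops exchanging (slow iFRAP decay), chromosome
territories elongate, and Hi-C maps show more contacts at TAD corners,
more inter-TAD mixing, and weaker A/B compartment segregation. This
package implements the statistics that quantify each of those readouts,
plus synthetic-data generators with known ground truth so every stage is
testable without any external download.

## What it computes

**Imaging** (`vermicelli.images`)

- *Heterogeneity level*: nucleoli and extranuclear pixels are zeroed,
  the nucleus is rescaled to a common mean gray value, 5×5-pixel box
  mean intensities are collected (boxes touching zeroed pixels are
  discarded), and their distribution is fitted with a double Gaussian
  f(x) = w·N(μ₁, σ₁²) + (1−w)·N(μ₂, σ₂²). The heterogeneity level is
  the peak separation μ₂ − μ₁: ~0 for uniform signal, large when the
  protein is clustered into sparse and dense regions.
- *Bead spacing*: difference-of-Gaussians detection of bead-like foci,
  mutual-nearest-neighbor chaining into fibers, Euclidean distances
  between consecutive beads (μm).
- Whole-ROI Pearson colocalization, threshold+size cluster
  segmentation, width-averaged line profiles.

**Kinetics** (`vermicelli.kinetics`) — FRAP traces are photobleaching-
corrected against an unbleached reference, normalized to 1 (pre-bleach)
and 0 (first post-bleach), and fitted with the double-exponential
recovery

    F(t) = A(1 − e^(−t/τ_A)) + B(1 − e^(−t/τ_B)),   τ_A ≤ τ_B,

where the slower constant τ_B estimates the chromatin residence time.
iFRAP decays are normalized to the first pre-bleach frame and
aggregated as mean ± SD.

**Geometry** (`vermicelli.geometry`) — 3D connected-component labeling
of segmented territories and the intensity-weighted radius of gyration

    R_g = sqrt( Σᵢ Iᵢ |rᵢ − r_c|² / Σᵢ Iᵢ ),  r_c = Σᵢ Iᵢ rᵢ / Σᵢ Iᵢ,

with per-axis physical voxel sizes (anisotropic z corrected).

**Hi-C** (`vermicelli.hic`, `.compartments`, `.tads`) — ICE matrix
balancing; distance-expected and observed/expected (O/E) transforms;
contact probability P(s) with log-log slope; trans-contact fraction;
differential maps; PC1 compartment calling (leading eigenvector of the
O/E Pearson-correlation matrix, sign oriented by a gene-density-like
track); compartment-switch fractions at the PC1=0 cutoff; the
AB/(AA+BB) mixing ratio; saddle enrichment by PC1 quantiles;
sliding-square insulation scores with valley boundary calling; TAD
score (intra-TAD / adjacent-inter-TAD mean contact); aggregate TAD
analysis (ATA) pileups; TAD length statistics.

**Generators** (`vermicelli.simulate`) — contact maps with power-law
distance decay (s+1)^(−α), checkerboard compartments (±ε), TAD blocks
(β), corner peaks (γ) and Poisson counting noise; fibrous nucleus
images with planted sub-pixel beads under Poisson camera noise;
FRAP/iFRAP traces with acquisition photobleaching; territory voxel
clouds. A paired preset (control vs cohesin-overloaded) reproduces the
direction of every Hi-C contrast with known truth.

## Worked example

```bash
vermicelli --seed 1 --out-dir results/demo demo
```

simulates the paired condition presets and recomputes every contrast.
`results/demo/demo_contrasts.json` contains, among others:

```
"mixing_ratio_control": 0.157,  "mixing_ratio_oe": 0.188,
"saddle_corner_control": 1.45,  "saddle_corner_oe": 1.26,
"tad_score_control": 5.04,      "tad_score_oe": 4.04,
"n_tads_control": 40,           "n_tads_oe": 40,
"all_directions_reproduced": true
```

Reading: in the cohesin-overloaded condition the A/B mixing ratio rises
(compartments blend), saddle corner enrichment falls (weaker
segregation), the TAD score falls (more inter-TAD contact) while TAD
count and size are unchanged, short-range contacts rise and long-range
contacts fall. The same pipeline runs per stage — `simulate-hic`,
`simulate-image`, `simulate-frap`, `heterogeneity`, `beads`, `coloc`,
`clusters`, `frap-fit`, `ifrap`, `hic-stats`, `compartments`, `tads`,
`ata`, `rg` — over files in the formats described above
(`vermicelli --help`). The numbered scripts under `analysis/` run each
analysis end to end and write tables under `results/`; for example
`analysis/03_frap_kinetics.py` prints

```
residence time over 14 cells: median 30.4 s (truth 30 s)
```

## Layout

```
src/vermicelli/     library: io, config, simulate, images, kinetics,
                    hic, compartments, tads, geometry, pipeline, cli
analysis/           numbered end-to-end drivers writing results/ tables
tests/              pytest suite incl. end-to-end property checks
scripts/acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
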