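# Methods

## The measurement

For one cell containing `n >= 2` segmented vesicles, the clustering index is
the fraction of vesicles with at least one touching neighbor in the same
cell.  It is a proportion in [0, 1], insensitive to vesicle count and cell
size, and monotone under adding contacts.  Cells with fewer than two
vesicles are reported as *undefined* rather than 0: a contact proportion
over a single object carries no information and would bias condition means
downward.

Contacts across cell boundaries are discarded.  The statistic is defined
per cell, so a vesicle whose only neighbor belongs to the adjacent cell
counts as non-contacting.  Both choices are exposed in the output table
(`n_vesicles`, `n_contacting`) so alternative conventions can be recomputed.

### Pixelizing "direct contact"

Two labels are adjacent when their pixel supports, each dilated `expand_px`
times with the 8-connected 3×3 element, overlap — equivalently when the
minimum Chebyshev distance between supports is ≤ `2·expand_px` (≤ 1 at
`expand_px = 0`, plain 8-connectivity).  The default `expand_px = 1`
("touching or one background pixel apart") absorbs the ±1 px boundary
jitter that watershed segmentation introduces at vesicle necks.  The flag
is a CLI option so sensitivity to the contact distance can be tested.  The
windowed-dilation implementation is checked in the test suite against a
brute-force all-pairs Chebyshev-distance oracle.

The synthetic generator's analytic oracle uses the matching rule on disks:
centers closer than `r_i + r_j + tol_px` with `tol_px = 1.0`, mirroring the
pixel rule.

## Synthetic scenes

The generator emulates single-plane (or max-projected) two-channel
fields: convex polygonal cells on a jittered grid, one nuclear disk per
cell, and `vesicles_per_cell = 40` circular vesicles of radius 3–5 px per
cell in a 512×512 field.  Field size, vesicle counts and radii are
engineering defaults chosen to look like high-resolution cultured-cell
images; they are not measured values.

Two presets fix the spatial regimes studied:

- **dispersed** — contact fraction 0.4 realized as incidental touching
  *pairs* scattered through the cytosol, the rest isolated with a
  boundary-to-boundary gap of ≥ 6 px.  The gap exceeds the adjacency
  tolerance (2 px), so "isolated" is unambiguous.
- **clustered** — contact fraction 0.7 realized as perinuclear chains of
  3–5 touching vesicles (boundary gap exactly 0 px, centers at `r_i+r_j`;
  members never fuse or overlap beyond rasterization).  Chain seeds fall
  within 0.3 cell radii of the nucleus centroid; the bias is a preference,
  not a constraint — when the perinuclear region saturates, seeds spill
  outward, and chains grow radially away from the nucleus so that dense
  packings remain feasible.  Long chains are placed first.  If a
  configuration still cannot be packed, generation fails with an explicit
  placement error — never by silently dropping vesicles.

The contact fractions 0.4/0.7 are the two regimes the index is reported to
occupy in dispersed versus perinuclear-clustered cells; the generator's
partition realizes them exactly (up to integer rounding), which the
construction-soundness tests assert.

Rendering draws each disk at peak intensity 150, convolves with a Gaussian
PSF (σ = 1 px default), adds a uniform background (10), Poisson shot noise
(photon scale 1, i.e. SNR ≈ 12 at peak) and Gaussian read noise (σ = 2) —
a plain Poisson-Gaussian camera.  Everything is driven by
`numpy.random.default_rng` seeded from the scene spec, so identical specs
give bit-identical scenes and images.

What the generator does **not** model: 3-D anisotropic PSFs, non-circular
or deformable vesicles, intensity heterogeneity between vesicles, other
organelles, cytoskeletal exclusion zones, uneven illumination, or cell
crowding/overlap.  Passing the recovery tests therefore shows the pipeline
is correct *given its imaging model*; on real images segmentation quality,
not the contact arithmetic, is the limiting factor.

## Segmentation

Cell territories: nuclei are Gaussian-smoothed (σ = 2), Otsu-thresholded,
hole-filled and size-filtered (≥ 80 px); territories grow by watershed on
the distance to the nearest nucleus (or on an inverted smoothed cytoplasm
channel when one exists).  Pre-made cell masks can be supplied and are
passed through unchanged.

Vesicles: the background is estimated by a large-scale Gaussian blur
(σ = 4·max_radius) and subtracted; the foreground is Otsu on the result.
Watershed markers are local maxima of the lightly smoothed (σ = 1)
foreground signal with a minimum separation of `min_radius − 1` px and a
relative height threshold of 0.05.  Each vesicle keeps a private intensity
peak even in a touching chain, so the marker-seeded watershed splits
contacting vesicles at the intensity neck; merged pairs would directly
corrupt the contact statistic, and splitting quality was the deciding
criterion for this marker design (scale-space blob maxima merged a few
percent of touching pairs under shot noise; intensity peaks do not).
Labels below half the minimal disk area (π·min_radius²/2) are discarded.
All thresholds are relative, so label counts are invariant under uniform
intensity rescaling, and all tie-breaks are fixed scan order — repeated
runs are bit-identical.

Measured on noise-free renders the pipeline index equals the analytic
oracle to < 0.01 across contact fractions 0 … 1; with the default camera
noise the dispersed regime reads ≈ 0.39 versus truth 0.40 (a small
deficit from occasionally merged pairs) and the clustered regime ≈ 0.70.

## Colocalization

Plain Pearson is computed over the ROI (per-cell mask when available, else
the whole image) and reported always.  The auto-threshold variant follows
the Costes procedure: orthogonal (total least squares) regression
`ch2 = a·ch1 + b`; the candidate threshold `t1` walks down from
`max(ch1)` in steps of one quantization level (integer data) or 1/256 of
the range (float), with `t2 = a·t1 + b`; the walk stops at the largest
`t1` for which the Pearson correlation of pixels below both thresholds is
≤ 0; the reported coefficient is over pixels above threshold in either
channel.  Perfectly correlated inputs never de-correlate below threshold;
the search then terminates at the minimum with an explicit
`search_exhausted` flag rather than a fabricated threshold.

## Statistics

Superplot convention: the condition mean is the unweighted mean of
per-experiment means, so experiments — the independent replicates — carry
equal weight regardless of how many cells each contributed.  Tests default
to per-cell values (the `n` reported in figure legends is a cell count);
`level="experiment"` runs the same tests on experiment means, the
conservative choice when experiments differ systematically.

Student's t is the classical pooled two-sided test; zero pooled variance
with equal means returns p = 1 by convention, with unequal means it is an
error.  ANOVA uses the direct sums-of-squares decomposition.  Tukey HSD
uses the studentized-range distribution with the Tukey-Kramer per-pair
standard error for unbalanced groups.  Dunnett's many-to-one adjustment is
computed by Monte Carlo of the null max-|t| statistic (shared control arm
and pooled variance; default 100 000 draws, seeded): adjusted p-values are
reproducible and carry an MC standard error of about
`sqrt(p(1−p)/n_mc)`.  The test suite cross-checks Tukey and Dunnett
against independent reference implementations and calibrates the Dunnett
familywise error rate at 5% ± 1% under a simulated global null.
Significance is star-coded in four tiers (0.05, 0.01, 0.001, 1e-4).

## Problem sizes and determinism

The regime-recovery computations use 3 experiments × 30 cells per
condition (≈ 1200 vesicles per experiment), enough for the grand-mean
standard error to sit well below the 0.1 acceptance band while a full
two-condition run completes in under a minute on one CPU.  Every random
draw — scene geometry, camera noise, Monte-Carlo nulls — flows from a
user-supplied integer seed through `numpy` `SeedSequence` streams; per-scene
seeds are derived arithmetically and stay below 2³¹.
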