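# Methods

This note documents the models and procedures floricolor implements,
the defaults it ships, and the choices made where the methodology was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral processing

Reflectance spectra are treated as % reflectance sampled on wavelengths
in [300, 700] nm. All computation happens on a fixed 1-nm grid
(401 points, inclusive endpoints); input series are linearly
interpolated onto it, values outside the range discarded, and a series
covering less than 80% of the range rejected. The 1-nm step makes
quantum-catch integration a plain rectangle rule and is finer than the
optical features of interest (transitions 10–50 nm wide), so grid error
is negligible relative to instrument noise.

Replicate measurements of a sample are pooled with equal weight and
averaged pointwise; for flowers with distinct lobe and tube coloration
the two parts are averaged separately. Averaging precedes smoothing by
default (configurable): the mean of noisy replicates is the better
estimate of the underlying curve, and smoothing a mean is cheaper and
no less accurate than meaning smoothed curves for a linear smoother.

Smoothing is LOWESS: tricube-weighted local linear regression over the
nearest ceil(span·n) grid points, span 0.25 by default, no robustness
iterations. Local linear fits preserve constants and straight lines
exactly, so flat and ramp-like spectra pass through unchanged; fitted
negatives (possible near sharp valleys with instrument noise) are
clipped to 0 after smoothing, not before, so the fit itself is not
biased by pre-clipping.

## Four-region color coding

Regions: UV 300–400, blue 400–500, green 500–600, red 600–700 nm.
A region codes `+` when reflectance strictly exceeds the threshold
(default 10%) at some wavelength outside the region's trailing boundary
window; `/` when the threshold is exceeded only inside that trailing
window *and* reflectance is still above threshold at the start of the
next region; `-` otherwise. Choices made here:

* "near the upper boundary" is operationalized as a trailing window of
  25 nm (configurable). The continuation requirement makes `/` encode a
  rising edge sitting on a region boundary — the configuration in which
  the `g/r+` code is used — rather than any bump that happens to sit
  late in a region.
* An isolated super-threshold bump confined to the trailing window that
  dies before the next region codes `-`.
* "above 10%" is strict; exactly 10.0 codes `-`. This keeps the coding
  monotone in the threshold.
* The red region has no successor, so `r/` is impossible; any
  super-threshold red reflectance codes `r+`.

Orange/red is exactly {`UV-b-g-r+`, `UV-b-g/r+`}; everything else is
"other". Coding is applied to smoothed spectra by default.

## Visual models

Receptor spectral sensitivities use the Govardovskii A1 α-band
template; the small β-band is available but off by default (its effect
on chromaticity for reflective, broadband floral stimuli is minor and
it complicates peak normalization). Default peaks: honeybee
(344, 436, 544) nm; average violet-type avian (416, 478, 542, 607) nm.
These are conventional literature values, are configurable, and are
echoed into every output: quantitative loci are config-dependent, and
reports carry the config hash for that reason.

The illuminant defaults to flat (ideal white); a smooth 6500-K
blackbody stand-in for daylight is available. Chromaticity in both
spaces is invariant to uniform illuminant scaling (it cancels in von
Kries adaptation and in relative catches), which the tests verify. The
adapting background defaults to a synthetic green-foliage curve (3%
floor plus a Gaussian band at 550 nm, peak 15%, sd 40 nm) and should be
replaced by a measured leaf spectrum when one is available.

Hexagon: excitations E = q/(q+1) of the von Kries catches, placed in a
regular hexagon with unit center-to-vertex distance; the background
maps to the center. Tetrahedron: relative catches are barycentric
coordinates of a regular tetrahedron with center-to-vertex distance
0.75, UV vertex on +z, the other three at azimuths 90°/210°/330° in the
z = −0.25 plane. Distances are invariant to this (documented)
orientation choice. The longest-wavelength receptor's adapted catch is
computed as the achromatic channel but not used by any downstream
statistic.

## Marker points, MAD, minAD

The smoothed curve is split into maximal monotone segments between
local extrema. Noise wobble is merged away before segmentation: a
segment bounded by two interior extrema with amplitude < 0.5 pp over
≤ 10 nm is treated as plateau noise (its extrema are dropped, or
replaced by the single extreme point when the flanking runs oppose).
Segments whose amplitude exceeds the change threshold (default 20
percentage points of reflectance — an absolute criterion, consistent
with the absolute 10% region rule) each yield one marker point: the
linearly interpolated wavelength where the curve crosses the midpoint
of the segment's min and max. Multiple crossings resolve to the one
nearest the segment's wavelength midpoint. Transitions truncated by the
300/700 nm range limits count if their in-range amplitude passes the
threshold.

MAD is the mean over marker points of the distance to the nearest
discrimination optimum; minAD is, per optimum, the distance to the
nearest marker point. Samples with no marker points have undefined
statistics and are excluded from group means (and logged); group n in
all summary tables reflects that exclusion, with SEM = SD/√n.

## Pigment chemistry

Hydroxyanthocyanidins: pelargonidin, cyanidin, peonidin, malvidin,
delphinidin. Deoxyanthocyanidins: apigenidin, luteolinidin, plus an
unidentified deoxy pigment. An additional unassigned anthocyanin
counts toward the hydroxy side by default (configurable), since the
binary category split needs every pigment on one side.

Categories: NONE (no anthocyanins), DEO90 / HYD90 (family share > 90%),
DEO_HYD otherwise; dominance: family share > 50%, with an exact 50/50
tie logged as undecided. Both cuts are strict inequalities.

The composition PCA uses four composite variables — PEL, CYA+PEO,
DEL+MAL, DEO — centered and unit-scaled by default (correlation PCA),
computed by SVD. Correlation form was chosen because the composite
variables have very different variances across datasets dominated by
one family; covariance form and dropping of all-zero (NONE) rows are
exposed as toggles. Presence for combination tallies means any positive
percentage by default, with an optional noise floor; anthocyanin-free
samples stay in the denominator of the size-distribution fractions.

## Color-space area and the subsampling null

Occupied area is the minimum convex polygon: discard the (100−percent)%
of points farthest from the arithmetic centroid (default percent = 95,
the convention of home-range MCP tools; 100 gives the plain hull), then
take the convex-hull area. Degenerate clouds (< 3 points, collinear)
give area 0 with a warning.

The null test draws n_iter (default 100) simple random subsets, of the
focal group's size, from all samples with loci (every pigment category
included), and computes each subset's MCP area. Two p-values are
reported for "the focal group occupies less area than random": a
one-sided t-model p, Φ_t((obs − mean)/SD) with n_iter − 1 df, and the
empirical proportion (count(null ≤ obs) + 1)/(n_iter + 1). The t-model
p is primary: with 100 draws the empirical proportion cannot resolve
tail probabilities below ~10⁻², while the t model can report e.g.
p < 10⁻⁴ for an observation far below every null draw — matching the
confidence-interval tooling this test emulates. Both are always
reported, with the 95% CI on the null mean.

## Phylogenetic comparative methods

Brownian motion gives tip values MVN(root·1, σ²C) with C the shared
root-to-tip path-length matrix. Simulation uses the Cholesky factor of
C (eigenvalue square root as the PSD fallback).

Phylogenetic ANOVA: the observed statistic is the classical one-way F
on tip values. σ² is estimated by ML on the pooled trait (GLS residuals
through C, 1/n normalization) — pooled rather than per group, matching
standard practice; a residual-based toggle is not provided because the
F statistic's null distribution under BM does not depend on σ² (F is
scale-free), making the choice immaterial to p-values. The null is
n_sim (default 10,000) BM simulations on the same tree with group
labels fixed; p = (count(F_sim ≥ F_obs) + 1)/(n_sim + 1), whose minimum
at 10,000 simulations is 10⁻⁴. Families of tests are adjusted by Holm's
step-down procedure. Calibration (type-I error within [0.02, 0.09] at
α = 0.05 for BM traits with arbitrary labels) is verified by simulation
in the test suite.

Ancestral states: joint ML of internal-node values under BM minimizes
Σ_edges (x_parent − x_child)²/length with tips fixed — a weighted
graph-Laplacian linear system solved directly. Its solution equals the
GLS conditional-normal estimate (verified against explicit covariance
inversion in the tests), and the root estimate equals the GLS
phylogenetic mean. Node variances are σ²_ML times the diagonal of the
inverted system. Zero-length edges get a 10⁻⁸ ridge with a warning.
Estimates of a trait bounded in [0, 100] (deoxy percentage) are convex
combinations of tip values and therefore stay in range.

## Synthetic-data generator

The generator emulates the study conditions the analysis assumes:
180 samples by default, split 24 DEO90 / 32 DEO_HYD / 96 HYD90 /
28 NONE (the proportions are configurable), two replicate measurements
per sample, and a pure-birth ultrametric tree over the samples.

* **Spectra** are sums of logistic steps and Gaussian bands plus
  Gaussian noise (sd 0.4 pp). Deoxy flowers are `red_step` shapes —
  < 10% below a steep transition drawn in 595–615 nm, > 30% above —
  which code orange/red and put their single marker near 600 nm.
  Hydroxy flowers mix `red_step`, `yellow_step` (transition ~500 nm),
  `purple_bimodal` (blue band ~440 nm + far-red rise) and `white_flat`;
  NONE samples mix white, yellow, leaf-like and dark shapes. Amplitudes
  straddle the 20-pp marker rule (leaf band: 12 pp, below it).
* **Compositions** draw the deoxy share per category (DEO90: 100 with
  probability 0.6, else U(91,100); HYD90: 0 with probability 0.75, else
  U(0.5,9); DEO_HYD: U(10.5,89.5)) and spread each family's share over
  a random subset of its members (single-member families most likely),
  so single-pigment samples are common, as in real profile data.
* **Phylogenetic clustering**: a latent BM trait is simulated on the
  tree and the deoxy categories are assigned to the highest-latent
  tips, so deoxy production is heritable on the tree and group tests
  face realistic non-independence.

Effect sizes are built in by direction, not magnitude: deoxy flowers'
markers sit near the hummingbird 600-nm optimum (low MAD_bird,
minAD600) and far from the bee optima (high MAD_bee, minAD400), and
their hexagon loci cluster tightly. What passing tests on these data
show is that the pipeline recovers structure of this kind when present
and stays calibrated when absent; they do not validate the visual
models against behavioral data, nor the generator against measured
Gesneriaceae spectra (no UV patterning, no specular/structural effects,
no intraspecific covariance beyond the tree).

The tree simulator stops at the n-th speciation, which would leave the
youngest cherry with zero-length branches (a degenerate BM covariance);
terminal branches are therefore extended by the hold time to the next,
censored, speciation event, which preserves ultrametricity.

## Problem sizes and determinism

Default analysis sizes: 10,000 ANOVA simulations, 100 hull subsamples.
The test suite uses smaller sizes chosen for tight-but-stable bounds
(199 null simulations × 200 replicates for ANOVA calibration; 100-draw
nulls × 200 replicates for subsampling uniformity; 1,000 simulations in
the end-to-end run). All randomness flows from explicit seeds through
`numpy.random.Generator` (and a seeded `random.Random` for tree
simulation); a fixed seed makes every result, including written
reports, bit-reproducible.

## Known limitations

* Quantitative color loci depend on the receptor peaks, background and
  illuminant configured; only the defaults are shipped, and no measured
  foliage spectrum or tabulated daylight illuminant is bundled.
* No receptor-noise discriminability model (ΔS/JND) — distances in the
  hexagon/tetrahedron are geometric only.
* Hull statistics are 2-D (hexagon) only; tetrahedral color volumes are
  not computed.
* The phylogenetic ANOVA assumes BM with a single rate; no Pagel's-λ or
  OU alternatives.
* Discrete (presence/absence) ancestral reconstruction is not included;
  only the continuous deoxy-percentage surface is estimated.
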