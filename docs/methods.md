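# Methods

## Scope

`nmjkit` quantifies structural plasticity at the *Drosophila* larval
neuromuscular junction (NMJ) and the locomotor behaviour that depends on
it. It covers four analysis stages — punctate synaptic-marker
segmentation and volumetry, NMJ morphometry, larval crawling
kinematics, and genotype-group statistics — plus a synthetic-phantom
generator that provides ground truth for all of them. No deposited
imaging data exist for this preparation, so validation is entirely
against phantoms with known truth; what that does and does not
demonstrate is discussed at the end.

## Puncta segmentation (local maximum-entropy thresholding)

Punctate markers (Brp for active zones, pCaMKII, Synapsin) are
segmented per slice, then assembled in 3D:

1. **Denoising.** Each slice is median-filtered with a 2D square window
   (default 3×3, edge-reflected borders). The median is the standard
   choice against the Poisson shot noise of confocal acquisition because
   it preserves punctum edges. The kernel size is configurable.
2. **Local thresholding.** Staining intensity varies within and between
   stacks, so a single global threshold is not meaningful. For every
   pixel brighter than a low-intensity cutoff (default 20 on the 8-bit
   scale) the Kapur maximum-entropy threshold is computed on the
   histogram of the 15×15 window centred on the pixel (clipped at image
   borders), and the pixel is foreground iff strictly brighter than that
   local threshold. Pixels at or below the cutoff are background by
   fiat — they carry no signal and skipping them makes the per-pixel
   method tractable. Windows are 2D within the slice; the subsequent 3D
   labeling joins puncta across slices.
3. **Labeling and volumetry.** Foreground voxels are labeled as 3D
   connected components (default 26-connectivity so that
   diagonally-touching voxels of one punctum are not split). Volume is
   `voxel_count × dz·dy·dx`; no minimum-size filter is applied by
   default (a `min_voxels` option exists).
4. **Normalization.** Counts and total volumes are reported as raw
   values and as densities per µm of axonal terminal length or per µm²
   of muscle surface area (MSA), the two normalizers used for NMJ size
   comparisons.

### The Kapur criterion and its numerics

For histogram counts `h_i`, probabilities `p_i = h_i/N` and
`P_t = Σ_{i≤t} p_i`, the threshold maximizes

    H_b(t) + H_f(t),
    H_b(t) = −Σ_{i≤t, p_i>0} (p_i/P_t) ln(p_i/P_t),
    H_f(t) = −Σ_{i>t, p_i>0} (p_i/(1−P_t)) ln(p_i/(1−P_t)),

over thresholds with both classes non-empty (tested on integer
cumulative counts, which is exact). The implementation evaluates the
algebraically equivalent form `ln P_t − S_t/P_t` with cumulative sums,
which is O(L) instead of O(L²). Tail quantities are accumulated from
the top of the histogram rather than as `1 − P_t`, avoiding
cancellation. Ties break to the smallest `t`; because two floating-point
evaluations of the same entropy can differ in the last couple of ulps,
scores within a relative `1e-10` of the maximum are treated as tied.
This makes the argmax invariant to evaluation order, and the test suite
verifies bit-identical decisions against an independent brute-force
implementation of the definition above (exhaustive search, explicit
class renormalization).

Windows with a single occupied gray level cannot be split and yield
background. The default pipeline asserts 8-bit data; for 16-bit stacks
the histogram length scales to 65 536 bins and the low cutoff must be
chosen by the user, since 20 is only meaningful on the 8-bit scale.

## Morphometry

The classical measurements here are manual (ImageJ tracing and the Cell
Counter plug-in); `nmjkit` defines deterministic automated equivalents
and validates them against phantom ground truth, not against manual
counts.

* **Masks.** Membrane/marker channels (HRP, Dlg) are near-bimodal, so a
  global Otsu threshold is used for them; the local max-entropy
  machinery is reserved for punctate channels where intensity varies
  locally.
* **Axonal length.** The HRP mask is thinned to a 3D skeleton; the
  skeleton's voxels form a 26-connectivity graph whose maximal
  degree-2 chains are branches. Raw inter-voxel Euclidean chain length
  systematically overestimates oblique curves (staircase metrication,
  up to ~8% at the worst angle), so each branch is resampled at a
  5-voxel chord step and chord lengths are summed. Endpoint erosion by
  thinning loses roughly one tube radius per terminal tip; with the
  default 0.4 µm tube this is ~2% of a 100 µm arbor, inside the 5%
  recovery tolerance the test suite enforces.
* **Cycle removal.** 3D thinning of thick tubes and swellings can leave
  small spurious cycles in the voxel skeleton whose junctions would be
  counted as forks. A terminal arbor is anatomically a tree, so the
  skeleton graph is reduced to a deterministic BFS spanning forest; the
  halves of each broken cycle become short spurs that the spur pruning
  below removes.
* **Spur pruning.** Thinning produces short spurs at bouton swellings;
  terminal branches shorter than 2 µm (configurable) are pruned before
  measuring, iteratively. Real side branches in this preparation are an
  order of magnitude longer.
* **Branch points.** Skeleton voxels of degree ≥ 3, with touching
  junction voxels merged into one (thinning can leave 2–3 adjacent
  high-degree voxels at a single anatomical fork). Whether this counts
  primary branches only or all forks is a modelling choice; all forks
  are counted.
* **Boutons.** 3D components of the Dlg mask with volume above a floor
  (default 0.2 µm³). Is/Ib subclassing is exposed as a size-threshold
  hook but reported "unclassified" by default — there is no published
  volumetric criterion separating the classes.
* **MSA.** Foreground pixel count of a 2D muscle mask times pixel area.
  Muscle segmentation from raw bright-field images is out of scope; the
  mask is an input.

## Locomotion

Films (default 400 frames / 40 s, i.e. 0.1 s frame interval) are
tracked as the centroid of the largest above-threshold 8-connected blob
per frame, converted to mm. Frames without a blob are invalid; a film
with more than 50% invalid frames fails tracking. Speeds are
`‖c_{k+1} − c_k‖ / Δt`, with intervals touching invalid frames dropped.

* **"Speed = 0".** A continuous centroid is never exactly stationary,
  so the dwell criterion is `speed ≤ ε`, with ε defaulting to a quarter
  pixel of motion per frame interval. This sits comfortably above the
  jitter floor of sub-pixel blob centroids (≲ 0.1 px) while staying
  below the slowest genuine crawling; a full pixel per interval would
  equal typical crawling speed at common magnifications (0.1 mm pixels,
  10 fps ⇒ 1 mm/s) and would absorb real locomotion into the dwell bin.
* **Reporting.** Percentage-of-frames histograms over half-open speed
  bins; coarse speed categories over configurable boundaries (the
  boundaries are explicitly arbitrary and default to 0.2/0.5/0.8 mm/s);
  maximum speed; distance travelled (`Σ speed·Δt`, exactly the polyline
  length of the tracked path).
* No trajectory smoothing is applied by default, keeping the speed
  definition exact; a smoothing window would bias dwell fractions.

## Statistics

Continuous measurements are routed through a deterministic decision
tree at α = 0.05: normality is screened per group by comparing sample
skewness and excess kurtosis (bias-corrected, SPSS-style) against 1.96×
their finite-sample standard errors

    SE_skew = sqrt(6n(n−1)/((n−2)(n+1)(n+3))),
    SE_kurt = 2·SE_skew·sqrt((n²−1)/((n−3)(n+5))),

and variance homogeneity by Levene's test centered on the mean (the
classic form; Brown–Forsythe's median-centered variant is deliberately
not used since the workflow names Levene without qualifier). Routing:
Student t (normal, homogeneous, 2 groups); one-way ANOVA with Dunnett
versus a named control or Bonferroni all-pairs post hoc (normal,
homogeneous, >2); Welch ANOVA with Games-Howell (normal,
heterogeneous); Mann-Whitney U (non-normal, 2); Kruskal-Wallis with
Bonferroni-adjusted Dunn comparisons (non-normal, >2).

Note the multiplicity inherent in the screen: with two groups, four
moment tests run at ~5% each, so perfectly Gaussian data are routed to
the nonparametric branch in roughly 1 − 0.95⁴ ≈ 19% of samples. This is
a property of the screening rule itself, which is implemented as
stated; the routed pipeline's overall type-I error remains calibrated
at 0.05 (verified by simulation) because both branches are valid level-α
tests under the null.

Dunn's test is implemented in-house (tie-corrected mean-rank z
statistics); for two groups it reduces exactly to the asymptotic
tie-corrected Mann-Whitney test, which the suite uses as an independent
check. Welch ANOVA and Games-Howell are delegated to pingouin, Dunnett
to scipy; Welch's F is cross-checked against a hand-coded textbook
formula. Categorical data use Pearson's χ² (no continuity correction)
with Bonferroni-adjusted pairwise group comparisons.

Measurement rows (hemisegments, larvae) are treated as exchangeable
units. If hemisegments of one larva are correlated, effective sample
sizes are smaller than row counts — a caveat of the original design
that the package inherits and does not attempt to model.

The pull-down candidate filter accepts a protein iff it has ≥ 2
high-confidence peptides in the bait sample and is absent from the mock
control, preserving sample order.

## Synthetic phantoms

* **Puncta stacks** (default 20×256×256 voxels at 0.25/0.1/0.1 µm,
  matching a Brp acquisition): isotropic Gaussian spots with
  σ = radius/2 truncated at 3σ — smoother and closer to PSF-blurred
  reality than hard spheres — amplitude peak−background (defaults
  150/10), radius 0.3–0.6 µm, rejection-sampled so spots stay separated
  by the sum of radii + 0.3 µm and inside the stack. Poisson noise draws
  every voxel with mean equal to the noiseless value. 8-bit output by
  default, because the ≤ 20 background shortcut presumes the 8-bit
  scale.
* **NMJ phantoms**: a gently wiggling main tube (60% of the requested
  arc length) with equally sized side branches, spherical boutons on the
  trunk (radius ≥ 1.5× tube radius, spaced so Dlg shells never touch),
  Dlg rendered as 0.3 µm spherical shells, Brp as 3 small surface puncta
  per bouton, over a rasterized muscle polygon. Ground truth records
  exact polyline arc length, bouton/branch counts and shoelace polygon
  area.
* **Larva films**: one Gaussian blob (half-maximum radius ≈ 8 px)
  following a heading random walk at prescribed per-frame speeds;
  heading reflects at the frame walls so the speed profile is preserved
  exactly.
* **Group tables**: long-format (group, value) draws from normal,
  lognormal or exponential distributions.

All generators are pure functions of (spec, seed).

### What the phantoms do not capture

No PSF convolution, bleaching, stage drift, depth-dependent
attenuation, autofluorescence or touching/overlapping puncta; larvae
are rigid blobs without peristalsis, occlusion or shape change; group
tables are i.i.d. within group. Passing the phantom suite therefore
demonstrates algorithmic correctness and calibration under the stated
noise model, not robustness to every artifact of real confocal stacks
or films. Parameters most likely to need retuning on real data are the
tracking intensity threshold, the bouton volume floor and the spur-prune
length.

## Problem sizes used in validation

The acceptance script and test suite validate at: 1 000 random
histograms (threshold oracle, exact); 20 random 32×32×3 stacks
(segmentation oracle, voxel-exact); 10 phantom stacks of 50 puncta at
20×256×256 (recovery: count within ±10%, object-level F1 ≥ 0.9); 10 NMJ
phantoms of 100 µm / 5 boutons / 3 forks (length within 5%, counts
exact); one 400-frame constant-speed and one stationary film (mean
speed within 5%, ≥ 99% dwell); 2 000 null replicates per distribution
at n = 30/group (rejection 0.05 ± 0.02, skewed data routed
nonparametric ≥ 95%); 1 000 replicates of 25% deficits at CV 30%,
n = 30/group (power ≥ 0.8).
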