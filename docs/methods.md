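# Methods

This note documents the models and conventions behind gelkit: what each
stage computes, the defaults and why, what the synthetic generator does and
does not emulate, and the numerical choices made where the design was open.

## Conventions

Pixels are 0-based and row-major; y increases downward (wells at the top,
migration downward); intervals are half-open `[lo, hi)`. Internally the
canonical polarity is *bands-bright* (signal brighter than background);
images photographed the other way round are handled by inverting first,
which flips the polarity flag. All image operations are pure and append one
entry to the image's provenance log.

## Synthetic gels

`gelkit.synthetic` renders a gel as

```
pixel(r, c) = background_level + gradient · r + Σ_bands peak · exp(−(r − y₀)²/2σ²) + ε
```

with the band term applied on the lane's columns only (uniform across the
lane width, 1-D Gaussian in y — the simplest realistic point-spread),
`ε ~ N(0, noise_sigma²)`, then rounding and clamping to 8-bit. Tilted lanes
are straight-edged quadrilaterals: the column interval shifts linearly from
the top edge to the bottom edge. Ground truth records each lane's top and
bottom intervals and each band's centre and integrated signal (the sum of
its rendered values above background, before noise and clamping), so the
noiseless image conserves signal exactly.

`random_gel_spec` draws the layouts used by the detection benchmark: 3–8
lanes of width 40 px on a 1000×500 px image, 2–10 bands per lane with
centre spacing of at least five band widths, and an equal-loading model —
the total signal per lane is roughly constant (as when the same amount of
sample is loaded in every well), each band's peak clamped into
[10·noise_sigma, 235] so the weakest band keeps peak SNR ≥ 10 and the
brightest never saturates. Equal loading matters: the lane threshold is a
fraction of the strongest lane's profile, so a gel mixing very heavy and
very faint lanes would lose the faint ones (a real limitation of
fixed-fraction thresholding, documented below).

What the generator does **not** emulate: lane curvature ("smiles"), spatially
correlated or multiplicative camera noise, saturation bloom, within-lane
intensity gradients, and partial band overlap beyond what the separation
rule allows. Passing tests therefore demonstrate correctness of the
algorithms under clean-to-moderately-noisy conditions, not robustness to
every pathology of real gel photographs.

The ladder generator places bands by a log-linear migration model
(Rf linear in log₁₀ size, anchored at two points), the same functional form
the calibration fits, so calibration round-trips are exact by construction.

## Detection

The column profile is the per-column mean intensity, minus a rolling-minimum
baseline (window 5% of the image width, at least 3 px), clipped at zero and
smoothed with a 3-px moving average. The rolling minimum removes both a
constant offset and the slow background gradient while leaving lane plateaus
*narrower than the window* intact — lane width must be below ~5% of image
width, i.e. gels photographed with generous gutters. Lanes are maximal runs
of columns at ≥ 20% of the profile maximum (`threshold_frac`), runs under
`min_lane_width` = 5 px discarded, gaps under half that merged.

Degenerate case: a single lane filling the entire width produces a flat
column profile, indistinguishable from a blank image by columns alone. When
the column profile is flat but the whole-image row profile still shows band
structure, one full-width lane is returned; an image flat in both axes has
no lanes.

Bands are peaks of the lane's row profile (same baseline treatment; for
tilted lanes the column interval is interpolated per row), found with
prominence ≥ 10% of the profile maximum and separation ≥ 3 rows
(`scipy.signal.find_peaks`); band extents are the half-prominence crossings,
the conventional half-height width in densitometry. Detection is
deterministic and idempotent.

Manual edits preserve the no-overlap invariant everywhere. Lane-geometry
edits (add, resize, set_tilt, split, merge) re-detect the affected lanes'
bands; band-level edits never trigger re-detection, so user-drawn bands
survive. Lane split interpolates the tilt offset proportionally; band merge
places the centre at the density-weighted centroid (first moment of the
signal), falling back to the extent midpoint when densities are absent.
Lane merging does not require adjacency: the merged lane spans the hull.

## Densitometry

Rf is measured from the lane's top row (well) to its last row (front) by
default; both endpoints can be overridden when the loading well or dye
front was located elsewhere. Size calibration interpolates log₁₀ MW
piecewise-linearly between the ladder knots — the standard model for gel
migration — and extends the end segment linearly when queried outside the
calibrated range, emitting an `ExtrapolationWarning` rather than refusing.

Band density sums `max(0, pixel − baseline)` over the band rectangle, the
baseline being a rolling minimum of the lane's raw row profile (window 5%
of image height): density is baseline-corrected, and this choice is
documented because raw summed intensity is also defensible. Quantity is
linear through the origin against a single reference band — the minimal
model given one known-quantity band; multi-point regression is out of
scope.

Band matching (within one gel and across gels) is the same deterministic
greedy pass: pool the bands, sort by the basis value (MW or Rf, ties broken
by gel then lane order), and let each band join the open class iff it lies
within the tolerance of the class's *running* mean and its sample is not
yet represented there; otherwise a new class opens. The final class value
is the arithmetic mean of its members (averaged once at the end, not
incrementally). One band per sample per class prevents chain-merging
artifacts; the tolerance is an absolute difference in the basis units.
Cross-gel classes whose members all come from one gel are flagged unique to
that gel. Tolerance 0 merges only exactly coincident values, and increasing
the tolerance never increases the class count on fixed input
(property-tested).

A class present in every sample is monomorphic; in exactly one, unique; in
some but not all, polymorphic. Unique classes count as polymorphic in the
percentage (the fingerprinting convention); the separate label lets users
recompute otherwise.

## Markers

With p the presence fraction in the chosen group and q in the complement: a
positive marker requires `p ≥ min_presence_frac` and
`q ≤ max_contamination_frac`; a negative marker is the exact mirror on
absence (`1 − p ≥ min_presence_frac`, `1 − q ≤ max_contamination_frac`).
The defaults (1.0, 0.0) demand perfect separation — the textbook marker
definition — and the two fractions are the relaxation knobs. Whether a
"negative marker" means absence-in-preferred or presence-in-unpreferred is
ambiguous in common usage; the symmetric definition covers both readings.
A class is reported as at most one type; in the overlap only reachable at
`min_presence_frac ≤ 0.5`, positive takes precedence. No association test
(chi-square/Fisher) is attached — calls are purely set-theoretic.

## Similarity and UPGMA

All fourteen coefficients are evaluated exactly as printed in the
fingerprinting literature; three algebraic identity classes
({Czekanowski, Dice, Sørensen, Nei–Li}, {Anderberg, Sokal–Sneath 1},
{simple matching, Sokal–Michener}) are kept as separate selectable names
because the literature cites them separately, and the identities are
enforced by tests. When a formula's denominator vanishes (e.g. Jaccard
between two all-absent profiles) the result is 0 with a warning — the
conservative "no evidence of similarity" convention; the matching family
stays well-defined through d. Self-similarity is stored as computed, which
for Russel–Rao and Faith is below 1 when shared absences exist.

Distances are d = 1 − s (bounded, simple; no log transform). UPGMA is the
classical size-weighted form: the joined pair minimises the mean pairwise
distance over original leaf pairs; the new node sits at height d/2; ties
break on the lexicographically smallest pair of sorted leaf-name sets, so
the tree is fully deterministic and reproducible. "Arithmetic mean" is read
as the size-weighted (classical UPGMA) average rather than WPGMA. The
output is ultrametric by construction and verified by the three-point
condition. Newick branch lengths are parent height minus child height.

## Population genetics

No single convention exists for deriving genotypes from band tables, so the
bridge is explicit: a user-supplied locus map groups band classes into loci
(codominant mode — each class is an allele; one class present means
homozygote, two heterozygote, none missing, three or more rejects the
diploid model). The formulas are the canonical ones: gene-counting allele
frequencies with per-locus deletion of missing genotypes; chi-square
goodness of fit to Hardy–Weinberg proportions with df = k(k−1)/2 (genotype
cells minus fitted allele frequencies), expected cells under 1 pooled into
the next-smallest cell and a warning whenever any expectation is under 5;
Nei gene diversity Hₑ = 1 − Σpᵢ²; Botstein PIC = Hₑ − Σᵢ Σⱼ>ᵢ 2pᵢ²pⱼ²; and
Nei F-statistics from H_I (observed heterozygosity), H_S (within-subpop
gene diversity; both averaged over subpopulations weighted by non-missing
sample size) and H_T (gene diversity of the pooled frequencies). Averages
over loci are unweighted. The identity (1−F_IS)(1−F_ST) = (1−F_IT) holds
exactly by construction and is tested;
degenerate loci (H_S or H_T zero) yield NaN F-values rather than errors.
The Weir–Cockerham variance-components estimator is deliberately not used;
Nei's formulation matches the H-statistics reported alongside.

Dominant mode treats each band class as a biallelic locus with recessive
null allele q̂ = √(band-absent fraction) under Hardy–Weinberg; observed
heterozygosity and the HWE test are undefined there and not reported.

## Persistence and CLI

Projects are versioned JSON with canonical serialization (sorted keys), so
save → load → save is byte-identical and unknown keys survive a round-trip.
CSV export is RFC-4180-style UTF-8 with shortest-round-trip float
formatting. The annotated image writes a sidecar JSON of every drawn label
so downstream checks need no OCR; with the overlay disabled the output is a
pixel-exact copy. The CLI's six subcommands mirror the six pipeline parts;
the library functions, not the CLI, are the primary interface.

## Problem sizes

The detection benchmark uses 50 random gels (1000×500 px, 3–8 lanes, 2–10
bands per lane); the UPGMA oracle comparison uses 200 random 4–7-leaf
matrices; marker equivalence enumerates every binary matrix up to 4
classes × 4 samples plus 500 random 10×10 matrices; the Hardy–Weinberg
type-I calibration uses 2000 replicates of 100 individuals at p = q = ½.
These sizes make the full suite run in seconds while keeping the Monte
Carlo bands tight (3 standard errors).

## Known limitations

- Fixed-fraction lane thresholding assumes comparable loading across lanes
  and lane widths below ~5% of image width.
- No curved-lane (spline) tracking; tilted straight-edge lanes only.
- No 2-D background subtraction (rolling ball) or saturation correction.
- Quantity estimation is single-reference proportionality.
- Cross-gel matching is greedy and tolerance-based, not a statistical test
  of size differences, and does not warp ladders between gels.
- No bootstrap support or alternative tree methods (e.g. neighbour
  joining); no exact (permutation) Hardy–Weinberg test.
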