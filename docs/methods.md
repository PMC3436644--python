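# Methods

This note documents the models, conventions and numerical choices
behind each stage of the pipeline, what the synthetic generator does
and does not emulate, and the known limitations.

## Spatial statistics (Voronoi)

Each soma's cell is the locus of the section plane nearer to it than to
any other soma. The raw diagram is computed with GEOS
(`shapely.voronoi_polygons`) over an envelope twice the data extent,
cells are matched to their seeds by point-in-polygon lookup, and every
cell is **clipped to the section boundary polygon**. Clipping is the
boundary-handling convention: no cell is unbounded, the clipped cells
partition the section exactly (areas sum to the boundary area; the test
suite checks 1e-6 relative, achieved at machine precision), and the
only exclusion mechanism is the explicit area filter. `was_unbounded`
records pre-clipping status for diagnostics, and `touches_boundary`
lets callers restrict statistics to interior cells — boundary cells are
truncated by the clip and bias dispersion estimates. Under complete
spatial randomness the interior-cell area CV approaches the
Poisson–Voronoi constant ≈ 0.53, which the acceptance checks use as a
calibration point.

Conventions: polygon areas above 60,000 μm² are flagged excluded
(strict `>`) and summaries recomputed over the remainder; histograms
use half-open bins [k·w, (k+1)·w) of width 3,000 μm²; SD is the sample
standard deviation (n−1) throughout; case statistics pool all included
areas across the case's sections, and group aggregates are means over
case values. Degenerate input (fewer than 3 points, collinear points,
duplicate coordinates, zero-area boundary) is rejected, never silently
perturbed; vertices are snapped at 1e-9 μm².

## Stereology

Abercrombie: N = n·T/(T+h). T defaults to the 50 μm section thickness.
**h (mean particle height) is a convention**: it is not derivable from
charted material, defaults to 10 μm (a medium-sized interneuron soma
radius scale), and should be set explicitly for real data. Cavalieri:
V = T·k·ΣAᵢ with k = 5 (every fifth section), giving a 250 μm sampling
period; no shrinkage correction is applied. Packing density divides the
summed corrected counts by the volume of the counted sections only
(ΣAᵢ·T), while the total number multiplies density by the full
Cavalieri volume — the two estimators stay independent. Recovery tests
simulate profile counts as Poisson with mean λ_V·A·(T+h), i.e. every
particle whose centre lies within h of the section produces a profile,
which is exactly the overcount the correction removes; density and
total recover λ_V with ≈ 1–2 % median error over 100 seeds.

## Morphometry

Neurons are rooted trees (SWC dialect: 7 columns, `#` comments,
parent −1 = root); the soma is a point at the root, so no soma-surface
offset is subtracted from path distances. Files may declare nodes in
any order; declaration order is kept when already topological (so
write→read round-trips node for node), otherwise nodes are re-indexed
by depth-first traversal. Orphans, multiple roots and cycles raise
parse errors naming the offending line.

Eligibility is two-tier: a neuron is reconstructed when ≥ 50 % of its
end points lie within the section (z ∈ [0, T]); a *single dendrite's*
length is only trusted (`complete = True`) when **all** of its end
points are inside. Incomplete dendrites still contribute to
neuron-level totals of eligible neurons.

Terminal branches run from the most distal branch point to an end
point; the soma never terminates a branch early, so an unbranched
dendrite is 100 % terminal. Path distance is arc length along the tree
(≥ the Euclidean soma–end-point distance, property-tested).

Sholl uses **crossing-count semantics in the 2D projection** (x, y):
each polyline segment contributes the number of its intersections with
the soma-centered circle, a segment crossing twice counts 2, tangency
counts 0. Crossing parameters are counted on the half-open segment
[0, 1) so a vertex lying exactly on a circle is attributed to exactly
one segment. The literal reading of "counting intersections" was
chosen over unique-branch semantics (identical for radial trees); an
independent dense-resampling counter (`sholl_brute_force`, 0.01 μm
steps) is kept as the oracle and agrees on 100/100 random trees.

## Image quantification

The isodata / iterative-intermeans threshold is pinned for bit-exact
reproducibility: start at the mid-level of the occupied intensity
range, iterate t ← round((mean of pixels ≤ t + mean of pixels > t)/2)
with round-half-up to the fixed point. A constant image has no
threshold and raises. Stained pixels are those ≤ t when the stain is
dark (DAB–nickel on bright field, the default) and ≥ t otherwise; the
fraction is monotone in t and invariant under polarity inversion with
the flag flipped. No background subtraction or smoothing is applied.
`skimage.filters.threshold_isodata` serves as an independent
cross-check in the tests (agreement within one grey level) but is not
the implementation, since its interpolation conventions differ.

## Inference

Cases (animals) are a random factor nested in the fixed group factor;
the group F is MS_group/MS_case(group) with df (g−1, Σcases−g) — for
the reference design (2 groups × 4 cases) df = (1, 6). Strict mode
requires a balanced design; neuron-level analyses after eligibility
filtering may be mildly unbalanced and use the same mean-square ratio
with a documented caveat. For balanced two-group data F equals the
squared pooled t on case means (verified to 1e-10 on 1,000 random
datasets), which is why printed case-level mean ± SD summaries are
sufficient to recompute published F values; `sample_with_moments`
constructs a sample with exactly those moments. Type-I error is
calibrated: 4.8–5.0 % rejections at α = 0.05 over 5,000 null
simulations. An independent plain-loop implementation
(`nested_anova_oracle`) guards the production path.

Mann–Whitney U uses midranks with ties counting ½; the two-sided p is
exact by full enumeration of all C(n, n_a) labelings when
n_a + n_b ≤ 12, otherwise a tie-corrected normal approximation with
continuity correction. All p-values are two-sided; no multiple-testing
correction is applied (none is used in the reference analyses).

## Synthetic generator

The generator defines the conditions every validation runs under.

**Point patterns.** Homogeneous Poisson (CSR baseline) and Thomas
cluster processes — Poisson parents, Poisson-distributed offspring
displaced by an isotropic Gaussian — chosen because the Thomas process
has a closed-form intensity (parent_intensity × offspring_mean) usable
as an oracle. Parents are placed in the bounding box dilated by 4σ so
the process is stationary over the section. Default overall intensity
is 5.4×10⁻⁵ somata/μm², the reciprocal of the ≈ 18,500 μm² mean
free-space polygon reported for this population (mean Voronoi cell
area = 1/intensity); no density was printed directly, so this is a
derived convention. Cluster dispersion σ = 150 μm gives polygon-area
CV ≈ 0.7–0.9 on the generator's 1×1 mm sections — clustered, but
milder than tight σ = 30 μm clumping; the reported CV ≈ 0.60 was
measured on whole caudate cross-sections and is not reproduced
exactly, since matching it on 1 mm sections would require clusters as
wide as the section.

**Trees.** Depth-limited stochastic bifurcation: 2–8 primary dendrites
(uniform), segments of truncated-Gaussian length, bifurcation with
probability p after each segment up to max_depth branch orders.
Expected segments per primary is Σ_{d<D}(2p)^d, so expected tree
length is closed-form and Monte-Carlo-testable. Defaults (p = 0.5,
D = 3, 5 expected primaries) put expected segment counts at 15 per
neuron; segment-length means of 15.735 μm (ethanol) and 23.880 μm
(control) target the reported case-level tree-length means of 236.03
and 358.20 μm. A per-case Gaussian factor on segment length
(`between_case_cv` = 0.07) supplies between-animal variance; the value
was obtained by matching the generator's total case-level SD (between-
case effect plus within-case sampling noise of a 20-neuron case mean)
to the reported case SDs (42.15 / 40.31 μm) in least squares over both
groups. Varicosities are not modeled (cosmetic). z-drift per segment
is small (σ = 1.5 μm), so nearly all synthetic neurons pass the 50 %
eligibility rule; the rule is exercised separately with constructed
trees.

**Images.** Polylines and soma disks rasterised at 2 μm/pixel onto a
bright background (200) with dark foreground (60) and optional Gaussian
noise; the exact drawn-pixel mask is returned as ground truth. The
synthetic frames image whole sections and reach sub-percent stained
fractions — far below the 13–28 % of real neuropil staining, which
includes out-of-focus processes and densely overlapping arbors the
generator does not attempt. Passing threshold-recovery tests therefore
shows the measurement chain is exact on known foreground, not that the
images look like histology.

**Cohorts.** 2 groups × 4 cases × 4 sections × 5 neurons × 2 frames by
default, all randomness drawn from `numpy` SeedSequence spawns of one
seed: regeneration is deterministic and serialized bundles
(CSV/SWC/PNG + JSON manifest) are byte-identical across runs. With
identical branching parameters in both groups, count-valued measures
(primary dendrites, end points) differ between groups only by chance;
at the 5 % level, occasional nominally significant differences across
cohort seeds are expected and observed at the nominal rate.

## Problem sizes

Validation runs use: 100 random patterns for conservation; five
2,000-point CSR patterns for the Poisson–Voronoi constant; 200 paired
Thomas/Poisson patterns (~200 points each) for clustering sensitivity;
1,000 datasets for the F = t² identity and 5,000 for type-I error; 100
cohorts (160 neurons each) for power; 100 seeds for stereology
recovery; 100 random trees for the Sholl oracle. The full suite runs
in well under a minute on one CPU.

## Limitations

* 2D only: no 3D Voronoi, no Sholl spheres, no optical-disector
  counting (the reference analyses use none of these).
* The Abercrombie h and all generator densities are documented
  conventions, not measurements.
* Nested ANOVA assumes the mean-square ratio F; no REML/mixed-model
  estimation, no post-hoc tests.
* The synthetic images validate the measurement chain, not staining
  realism; absolute stained fractions and absolute polygon-area CVs of
  real material are out of reach at this scale and are deliberately
  not asserted.
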