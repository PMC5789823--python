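# Methods

## Lesion definition and meshing

A subject's WMH segmentation is a binary volume on a grid with per-axis
voxel spacing in mm (anisotropic spacing allowed; the motivating regime is
thick-slice 2D FLAIR, e.g. 0.96 × 0.96 × 3.00 mm³). Individual lesions are
maximal 26-connected components: voxels touching even only at a corner
belong to one lesion. Components are labeled in ascending order of their
lexicographically smallest voxel index, which makes lesion ids
deterministic and intrinsic to the grid. Lesions below `min_voxels = 5`
voxels are excluded; shape analysis is unreliable on them. The voxel
count is the operative rule — the equivalent volume (0.014 ml at the
FLAIR spacing above) is documentation, not an independent threshold, so
the filter behaves identically on grids with other spacings.

Each surviving lesion is meshed with marching cubes at iso-level 0.5 on
its binary sub-volume, zero-padded by one voxel on every side. Padding
guarantees a closed, orientable surface for any lesion, including lesions
touching the image border; iso 0.5 treats foreground and background
symmetrically. Marching cubes runs in index space and anisotropy is
applied in exactly one place, by multiplying vertex coordinates with the
voxel spacing. Face winding is normalized so the signed volume is
positive. We label components first and mesh each separately rather than
meshing the whole segmentation and splitting the surface; at iso 0.5 with
padding, marching cubes creates no surface between 26-disconnected voxel
sets, so the partition is the same and the bookkeeping is simpler.

Mesh volume is the absolute signed-tetrahedra sum over faces (reported in
ml), surface area the triangle-area sum (mm²); both are cross-checked
against an independent mesh library in the tests.

## Shape features

**Eccentricity.** d_max is the maximum pairwise vertex distance (3D
caliper), searched exhaustively over the convex-hull vertices — every
diameter endpoint lies on the hull, so this is exact — with ties broken
by the lexicographically smallest vertex-index pair. d_min is the
smallest projected extent of the mesh over in-plane directions orthogonal
to the d_max axis, evaluated on a 1° angular grid (0°…179°). "Smallest
orthogonal diameter" is read as minimal orthogonal *width* (extent),
which is rotation-invariant; the 1° grid agrees with a 0.1° grid within
1% on random ellipsoids (tested). Eccentricity = d_max / d_min ≥ 1 for
any body.

**Compactness.** compactness1 = V²/A³ with V in mm³ and A in mm²; its
supremum over closed surfaces is the isoperimetric constant
1/(36π) ≈ 0.008842, attained by the sphere. compactness2 = V/(dx·dy·dz)
and compactness3 = V/max(dx,dy,dz)³ use the mesh-vertex bounding-box
extents along the *image* axes (not principal axes), which keeps both in
(0, 1] with the ceiling attained by an axis-aligned box resp. cube.

**Fractal dimension.** Boundary voxels (lesion voxels with a 6-connected
background neighbor) are covered by grids of cubic boxes anchored at the
bounding-box corner with sides s = 1, 2, 4, … voxels, restricted to
s < max_extent/2: boxes comparable to the object itself saturate the
count and bias the slope upward (for a 32³ cube boundary the s =
extent/2 term shifts the fitted slope from ≈ 2.2 to ≈ 2.4). The dimension
is the least-squares slope of log N(s) against log(1/s). Fewer than three
usable scales (lesions with max extent ≤ 8 voxels) yield NaN — a flagged
undefined value, not an error. A single grid origin is used (no offset
averaging); a 64-voxel line scores exactly 1.0 and a solid cube's
boundary ≈ 2 under this scheme.

**Shape index and curvedness.** Principal curvatures k₁ ≥ k₂ of the image
isophotes come from Gaussian-derivative gradient g and Hessian H at scale
σ = 1 voxel, via the implicit-surface formulas for mean curvature
(g′Hg − |g|²·trH)/(2|g|³) and Gaussian curvature (g′·adj(H)·g)/|g|⁴, with
k₁,₂ = H_m ± √(max(H_m²−K, 0)). The sign convention makes a bright ball
of radius r score k₁ = k₂ = +1/r. Derivatives are taken in index space
with σ in voxels, so curvedness carries voxel⁻¹ units and anisotropy is
deliberately not corrected — a unit convention, stated rather than
hidden. Voxels whose gradient magnitude is below 1e-8 have no defined
isophote and are skipped; at umbilic points (k₁ = k₂) the shape-index
formula's denominator vanishes and the analytic limit sign(k₁) is used
(0 when both curvatures vanish). The per-lesion value is the median over
the lesion's defined voxels. By default the curvature image is the
lesion's own binary mask, keeping the pipeline self-contained and
deterministic; the co-registered scalar MRI can be substituted via the
`image` argument. On a raw binary mask at σ = 1, residual staircase
structure keeps k₁ and k₂ apart even on a sphere (median shape index
≈ 0.81 instead of 1); with a modestly pre-smoothed image the closed forms
are recovered within tolerance, which is how the curvature tests are
framed.

**Surface-area normalization** is the plain ratio surface area (mm²) /
ICV (ml); a residual-based correction would tie the feature to a specific
cohort fit.

## Location features

Lesion-to-ventricle distance is an anisotropy-aware Euclidean distance
transform of the ventricle mask, minimized over the lesion's voxels: the
conservative reading of "located > 1.0 cm from the ventricles" is that
the *whole* lesion is beyond the threshold. A lesion is punctuate deep
iff distance > 10 mm AND maximum diameter < 15 mm, both strict; the
diameter reuses the caliper d_max so "diameter" means one thing
throughout. Everything else — periventricular and (early) confluent
lesions — forms the single non-punctuate group, whose lobe is not
determined because such lesions routinely span lobes. Automatic classes
can be overridden from a manual-correction list; an override always sets
a flag, even when it confirms the automatic class, so the table records
that a human decision was made.

Lobe assignment is a majority vote of the atlas labels over lesion
voxels; background does not vote, ties go to the fixed order frontal >
parietal > temporal > occipital > basal-ganglia-region > cerebellum, and
an all-background lesion takes its nearest labeled voxel. Basal-ganglia
and cerebellar labels are carried through the records but dropped from
the four-lobe comparison table, mirroring how small-sample locations are
reported. Registration to atlas space is an input contract: masks arrive
already resampled to the atlas grid; re-implementing registration is out
of scope.

The eccentricity map sums, per atlas voxel, the eccentricities of all
covering lesions and divides by the covering-lesion count (0 where no
lesion), so total "mass" Σ map·count equals Σ lesions' eccentricity ×
size — an invariant the tests assert.

## Cohort statistics

Per subject and stratum (all / non-punctuate / punctuate-deep): total
mesh volume as %ICV, lesion count, median per-lesion eccentricity. Group
differences are OLS fits of the outcome on a patient indicator plus age
and sex, reporting the raw coefficient B with its 95% CI and the
standardized Beta = B·SD(indicator)/SD(outcome), CI scaled identically
(standardization on the analysis sample). Volumes and counts are
natural-log transformed for their right skew; volumes (ICV fractions) are
first multiplied by 10000 so the transformed values stay positive and the
direction of effect is retained. Subjects with zero lesions in a stratum
are necessarily excluded from that stratum's log-scale regressions, which
is why stratum ns can fall below the cohort n. Secondary associations
(lesion features vs white/gray-matter volume or diabetes duration) use
the same OLS contract within the subjects supplied — intended for the
patient group — with ICV added to the design exactly when the outcome is
a volume.

Per-lobe location comparisons are 2×2 χ² tests on counts (lobe vs all
other lobes × patient vs control, no continuity correction); testing
literal percentages is ill-defined, so percentages are reported alongside
(full precision and half-up-rounded integers). Per-lobe shape comparisons
are two-sided Mann-Whitney U tests: exact null distribution for tie-free
samples with min(n) ≤ 8, otherwise the tie-corrected normal approximation
without continuity correction (so identical samples give p = 1 exactly).
Feature distributions are summarized by mean/min/max and Fisher's
moment-based skewness g₁, with a one-sample Kolmogorov-Smirnov test
against a normal with the sample mean and SD. Because the parameters are
estimated, the KS p-value is approximate (the Lilliefors situation); it
is used as a descriptive screen, matching common practice. No
multiple-testing correction is applied anywhere.

## Synthetic data

`make_phantom` voxelizes analytic bodies (sphere, ellipsoid, box, rod,
blob) by testing each voxel center against the shape inequality —
deterministic ground truth for every geometric feature. `make_toy_atlas`
builds a brain ellipsoid with two paramedian slab ventricles, a central
basal-ganglia box, a posterior-inferior cerebellum wedge, and
frontal/parietal/temporal/occipital blocks split at the grid center
planes; labels, ventricles and background tile the grid exactly.

`make_cohort` emulates the two-group study design. Defaults mirror the
reference cohort: punctuate Poisson rate 12/subject in both groups;
non-punctuate control rate 26 with patient rate ratio ≈ 1.54; lesion
log-elongation N(0.59, 0.28) (median ≈ 1.8, right-skewed, matching
per-lesion eccentricity distributions) with a per-subject random effect
(SD 0.08) and a patient shift of 0.141 on the log scale (≈ the observed
punctuate-deep group difference); ages ≈ N(71, 4.5) clipped to 65–80,
58% male, ICV ≈ N(1450, 110) ml. The default grid is 128 × 128 × 64 at
(1, 1, 3) mm so anisotropy is always exercised. Punctuate candidates are
ellipsoids (minor radius ~2 mm) placed where the ventricle distance
exceeds the classification threshold with margin, elongation clipped so
the meshed diameter stays under 15 mm; their long axis is placed *in the
slice plane*, because on 3 mm slices a through-plane long axis is
quantized away and measured eccentricity would decouple from the intended
elongation. Non-punctuate lesions are multi-sphere blobs seeded at the
ventricle boundary, so they always violate the distance criterion.
Overlapping placements merge by voxel union; the returned ground truth
records every intended placement, making merges detectable. Everything is
reproducible bit-for-bit from the seed.

What the generator does *not* emulate: FLAIR intensities (bias fields,
noise, partial-volume effects), segmentation error, anatomically shaped
ventricles and lobes, spatially confluent lesion growth, or registration
error. Passing tests therefore demonstrate that the measurement and
statistics machinery is correct on known geometry and known effects —
not that segmentation-dependent steps are robust on real scans.

`simulate_subject_summaries` draws per-subject summaries (counts, median
elongations, volumes) directly from the same generative model without
voxelizing lesions. The regression layer consumes per-subject summaries
either way, so power and CI-coverage studies over many seeds run on this
path at negligible cost; the voxel path is exercised end-to-end by the
recovery and classification-invariant tests at smaller n (e.g. 3/group
for the recovery fixture, 5/group for the elongation-correlation test,
100 lesions minimum). Those problem sizes are the package's validation
scale; all statistical tolerances (≥ 90% detection over 50 seeds,
coverage 95 ± 6 points) are stated in the tests themselves.

## Numerical conventions and edge cases

- Voxel indices are 0-based; world coordinates are voxel centers under
  the affine. Masks are uint8 {0, 1}; features are float64; missing
  optional table fields are empty strings, never 0.
- Grids of one subject must agree in shape, spacing and affine within
  1e-4.
- Degenerate inputs raise (`ValueError` subclasses) where the quantity is
  meaningless (open mesh volume, zero bbox extent, empty ventricle mask)
  and return flagged NaN where the feature is legitimately undefined
  (fractal dimension with < 3 scales, curvature with no defined voxel,
  skewness of a constant sample).
- The per-lobe report rounds percentages half-up to integers; full
  precision is kept in adjacent columns.

## Known limitations

- Curvedness is in voxel⁻¹ and not comparable across grids with
  different spacing; use the same protocol within a study.
- The binary-mask curvature default inherits staircase noise at σ = 1;
  supplying the scalar MRI (or pre-smoothed mask) gives smoother
  curvature fields at the cost of intensity dependence.
- The min-over-voxels ventricle distance makes the punctuate rule
  sensitive to single spurious voxels near the ventricles; the override
  mechanism exists precisely for such cases.
- Box counting uses a single grid origin; offset averaging would reduce
  variance for small lesions but breaks strict determinism of the
  current scheme and is not implemented.
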