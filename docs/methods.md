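# Methods

## Scope and model

`canopyqtl` couples two measurement models to one statistical model.

**Vegetation fraction (VF).**  A plot region is a fixed 450 × 270 px
window (2 mm/px; 3 × 3 plants, 18 cm within-row and 30 cm between-row
spacing, so plant centres are 90 px apart vertically and 150 px apart
horizontally in image coordinates).  The RGB region is converted to
CIELAB and only the a* (red–green opponent) channel retained; Otsu's
threshold on the per-image 8-bit-rescaled a* histogram separates the
low-a* (green, plant) class from the near-zero/positive (soil) class,
and VF = 100 · n_plant / n_total.

The sRGB → XYZ → CIELAB conversion is implemented in the package with
the high-precision IEC 61966-2-1 matrix and the piecewise companding
curve (linear segment below 0.04045).  The D65 white point is defined
as the matrix image of RGB white rather than a separately tabulated
triple: this makes every grey pixel map to a* = 0 exactly, which the
segmentation polarity contract relies on.  Library conversions that mix
a rounded matrix with a tabulated white point leave grey at |a*| of
order 10⁻³ and differ from ours by < 0.05 a* units — visually nothing,
but enough to matter for exactness tests.

Otsu's threshold is computed by exhaustive search over the 255 splits
of a 256-bin histogram, maximizing the between-class variance
ω₀ω₁(μ₀−μ₁)².  Ties are real (any split through an empty-bin gap
between two classes is equally optimal); among tied optima the midpoint
of the optimal run is returned, rounded down — deterministic and
symmetric for symmetric histograms.  The threshold bin itself belongs
to the plant (low) class.  A constant image has no threshold and is an
error, not VF = 0.

**Archery-target score (AT).**  Nine odd-sided square tiles centred on
the plant centres (default side: largest odd value ≤ min spacing − 1,
i.e. 89 px) are averaged pixel-wise into a mean mask.  The mask is
partitioned into five concentric regions a…e weighted 1…5
outside → centre, and

AT = Σᵢ wᵢ · P̄ᵢ / P̄_all.

Two geometries are provided.  *Square annuli* (default): nested square
frames whose outer half-widths sit at fractions 0.2, 0.4, …, 1.0 of
side/2 on the max-norm distance; they partition the raster exactly.
*Circular annuli*: the same fractions as Euclidean radii, corners
outside the largest circle excluded from every region and from P̄_all.
Boundary pixels belong to the inner region (≤ comparisons); the centre
pixel is region e.  Square annuli need side ≥ 9 for all five regions to
be non-empty (a 5 × 5 raster has only three square rings).  AT of a
uniform mask is exactly 15 in any geometry; for equal-area regions the
extreme scores are 5 (all mass outermost) and 25 (all mass innermost).
An all-zero mask is an error: the score divides by P̄_all.

**Haplotype-based GWAS.**  The population is n lines from 8 founders;
at every SNP each line carries a founder label (or missing).  The scan
is exposed as a model/results pair: `HaplotypeScan(haplo, pheno, trait,
environment)` holds the aligned data; `.fit(min_groups=3,
min_group_size=2)` tests every SNP with the Kruskal–Wallis rank-sum
test — mid-ranks for ties, H divided by the tie-correction factor
1 − Σ(t³−t)/(N³−N), p from the χ² upper tail with k−1 df.  Lines with
missing labels are dropped per SNP; groups below `min_group_size` are
dropped; SNPs with fewer than `min_groups` groups are flagged
`discarded` rather than tested (the 1-or-2-haplotype discard rule at
the defaults; a singleton "group" contributes a degenerate rank mean,
hence `min_group_size` = 2).  No multiple-testing correction is applied
— peaks are ranked, not thresholded — but a Bonferroni column is
emitted for information.

Peaks are strict local maxima of the −log₁₀P track in map order
(plateaus contribute their leftmost index, a deterministic choice the
reference routine leaves unspecified), selected greedily in decreasing
height while discarding candidates within `min_distance` SNP indices
(default 100, measured in index units, not bp) of an already selected
peak, up to `n_top` (default 8).  Untested SNPs (NaN) never form peaks.

At a QTL the effect vector is the arithmetic mean phenotype per founder
group (NaN where a founder is absent; the whole vector discarded when
fewer than 3 groups are present).  Effect vectors are compared by
Pearson r over pairwise-complete entries, two-sided p from the t
transform with n−2 df, annotated at the 0.01 / 0.05 / 0.1 tiers.
Founder allele-class contrasts use the pooled-variance (Student's)
two-sample t-test; zero pooled variance returns p = 1 with equal means
and is flagged degenerate otherwise.

## Synthetic data: what it emulates, what it does not

**Canopy scenes.**  Each of the 9 plants is 8–15 elliptical leaves
with uniformly random orientation, anchored with their inner end at the
plant centre.  Leaf half-length scales with (0.5 + spread), so
`spread` ∈ [0, 1] moves mass radially outward — the closed-to-spreading
habit axis; a per-plant log-normal size multiplier (SD 0.1 by default)
models within-line variability among the 9 plants.  Ground cover is
calibrated by bisection on a single global isotropic leaf scale until
the rendered mask is within ±0.003 of `coverage_target` (hard error
beyond ±0.03); scaling length and width together preserves the relative
radial-mass ordering across spread levels at fixed coverage, keeping
`spread` the only architecture dial.  Plant pixels are jittered ±15 per
channel around RGB (40, 120, 35) (a* ≈ −41), background around
(110, 95, 80) (a* ≈ +3): the two classes sit on opposite sides of
a* = 0 with realistic within-class scatter but essentially no overlap.

Consequently the segmentation problem is *solvable by construction*:
passing VF-recovery tests shows the a*/Otsu chain is correct, not that
it would survive shadows, specular water, mixed pixels at leaf edges or
illumination gradients — none of which are rendered.  The same applies
to AT: the spread dial induces a clean monotone radial-mass signal that
real canopies blur with leaf overlap between neighbouring plants.

**Founder mosaics.**  Per line × chromosome: the founder at the
chromosome start is uniform over 8; breakpoint count is
Poisson(`breakpoint_rate`), positions uniform in physical coordinates
(interval space, not SNP-index space); at each breakpoint the founder
is redrawn uniformly over all 8, so visible label switches occur at
rate 7/8 × `breakpoint_rate`.  The default rate of 6 per chromosome
reflects the crossovers an inbred 8-way line accumulates over three
funnel meioses plus selfing, with rice chromosomes of roughly 1–1.8
Morgans.  SNPs are equally spaced (default 30 Mb chromosomes).  Not
modelled: recombination hot/cold spots, segregation distortion,
residual heterozygosity, genotyping error, kinship structure among
lines (every line is simulated independently, whereas a real MAGIC
panel has relatedness the scan would ideally correct for).

**Phenotypes.**  Line value = Σ over QTLs of the planted per-founder
effect + intercept + independent Gaussian noise per environment; the
genetic part is identical across environments (year-stable haplotype
effects).  `draw_qtl_effects` standardizes a Gaussian draw to exact
unit SD across the 8 founders so a QTL's variance share is controlled:
with unit-SD effects and noise SD 2 the QTL explains ≈ 20% of variance
(the realized group-mean R² at n = 165 runs ≈ 0.23 because fitting 8
means inflates R² by (k−1)/n).

## Experiment sizes and numerical choices

The test suite and `scripts/acceptance.py` use desk-scale problem
sizes chosen to keep the full run in the low minutes on one CPU while
leaving the statistical conclusions stable: VF recovery over coverage
5–70% (step 5) × spreads {0.1, 0.5, 0.9} × 5 seeds (210 scenes); AT
monotonicity over 5 spread levels × 10 seeds at 30% cover; null
calibration with 1000 independent 165-line 8-group tests; QTL
localization with 50 replicates of 165 lines × 1000 SNPs
(10 chromosomes × 100, a GBS-like sparse map) and a single ~20%
-variance QTL; effect stability with 30 replicates of a major
(~30%-variance) QTL observed in two years, with the null reference
taken from matching no-QTL simulations — at a null SNP of a QTL
simulation, both years share the causal QTL's genetic leakage through
group composition, so its cross-year correlation reflects the QTL's R²
rather than instability of the method.

Numerical conventions worth knowing: rectangles are 0-based half-open;
per-image a* rescaling maps min→0, max→255 before binning (`rescale=False`
switches to a fixed [−128, 127] clip for workflows that want a common
domain); the Otsu tie rule and the peak plateau rule are the
deterministic choices described above; pipeline summaries round floats
to 10 decimals and serialize with sorted keys so identical seeds give
byte-identical JSON; every generator owns one explicitly seeded RNG
stream and no global random state is touched.

## Known limitations

* The renderer produces binary leaf masks (no anti-aliasing or mixed
  pixels), making Otsu recovery near-exact; real imagery would show
  1–2 point VF errors from edge pixels alone.
* The scan is a marginal per-SNP test: no kinship or population
  structure correction, no LD-aware multi-SNP model.  In a real MAGIC
  panel the top peaks can be inflated by relatedness.
* `min_distance` operates in SNP-index units, so its physical meaning
  depends on map density; both index and bp are reported.
* The χ² reference for Kruskal–Wallis is an approximation; at very
  small N (≤ 8) it deviates from the exact permutation null by up to
  ~0.1 in p, and it is very slightly conservative at 8 groups of ~20
  (null rejection ≈ 0.047 at α = 0.05).
* AT region geometry is a convention (two are provided); absolute AT
  values are comparable only within one geometry and tile side.
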