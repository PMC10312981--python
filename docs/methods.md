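# Methods

## Synapse strength

A reference cell's membrane is its internal boundary: cell pixels within
Chebyshev (8-connected) distance `w` of any non-cell pixel, i.e.
`cell \ erosion(cell, (2w+1)×(2w+1) square)`, with `w = 2` px for
fluorescence and `w = 1` px for IMC (IMC pixels are ~1 µm, so a 2-px band
would swallow most of a cell). Pixels outside the image count as non-cell,
so border-touching cells keep a defined membrane; records carry a border
flag for optional filtering but are retained by default. Cells thinner than
`2w` are entirely membrane.

A neighbor is in contact where its mask, dilated with an L1-ball (diamond)
structuring element of radius 2, intersects the reference membrane. Radius
2 is required to bridge the neighbor's own membrane band plus the ≤1-px
rasterization gap between adjacent masks; radius 1 would miss the inner
membrane row. Contact records are directional (`sigma(ref→nb)` ≠
`sigma(nb→ref)`); the T-cell is always the reference. When one reference
touches several neighbors of the same type, every record against that type
shares a noncontact pool equal to the membrane minus the union of that
type's contact interfaces; interfaces with *other* types are not removed.

`sigma = log2(contact mean / noncontact mean)`. The score is invariant to
positive rescaling of the channel and antisymmetric under swapping the two
pixel sets. Scores with an empty noncontact pool are flagged and excluded
rather than filled.

### Zero handling for ion counts

IMC channels are log2(x+1)-transformed on load (no noise floor is
subtracted — low pixels carry information and the ratio form cancels
background). Sparse counts still produce exact-zero means. With a
per-sample noise term `nu` (mean channel intensity over all pixels of cells
holding no reference type label):

- contact mean = 0 and noncontact mean < `nu` → `sigma = 0` (zero rule);
- otherwise any zero mean is replaced by `nu` (fill-in, flagged per side).

The fill-in is applied symmetrically to either side; the zero rule takes
precedence. In non-IMC mode a zero mean excludes the score instead, since
the fill-in is motivated by count statistics.

### Seed-and-grow null model

Per iteration, each eligible cell (membrane ≥ 15 px) contributes the mean
sigma of 5 randomly seeded contiguous membrane regions grown to ≥ 15 px
(uniform seed; uniform draws from the 8-connected frontier), scored as
contact against the remaining membrane. The cell average, then the sample
average over cells, then the mean over 100 iterations give the null value.
Each (cell, iteration) has its own RNG stream derived from the master seed,
so results are independent of iteration order and cell scheduling. On
spatially uniform membranes every ratio is 1 and the null is exactly 0.
Cells below 15 membrane px are excluded from both observed and null
aggregates for symmetry.

### Aggregation and stratification

Per-sample summaries are arithmetic means of non-excluded sigma over
(sample, marker, target type, region); each (reference, neighbor) contact
contributes one sigma. Patients split into group 1 when the mean sigma is
strictly positive and group 2 otherwise — including patients with no
contact at all, who cannot form synapses. One-sided Wilcoxon signed-rank
(observed vs null, paired by sample) and one-sided one-sample t-tests vs 0
are the intended cohort comparisons; p-values are reported unadjusted.

## Correlation analyses

Contact-aware correlation is Pearson r between two markers' sigma values
over matched contacts (matched on sample, reference and neighbor ids;
excluded scores drop pairwise), pooled across samples or per sample.
Pearson is the default (the scores are continuous log-ratios); the
pixel-wise baseline pools every pixel of every cell of the type — whole
cell areas, not membranes — into one coefficient per sample. The paired
t-test of per-sample coefficients reports the mean difference; zero
variance of the differences is flagged degenerate (p = 1 for a zero mean
difference, undefined otherwise) instead of fabricating a statistic.

## Radial distribution function and delta-CDF

For each reference cell, target cells (self excluded) are counted in
half-open 1-µm annuli `[r, r+1)` out to 100 µm (centroid-to-centroid
Euclidean distance). Counts are summed over references, divided by the
reference count and by the full annulus area `pi[(r+1)^2 - r^2]`. The
textbook normalization by overall density is deliberately omitted so curves
read as true local densities (cells/µm²; reported per mm² where more
legible).

Edge correction divides each per-cell, per-bin count by the in-window
fraction of that annulus. The fraction is computed analytically for
rectangular windows from the exact disk–rectangle intersection area
(inclusion–exclusion of signed quadrant areas); division, not
multiplication, is the unbiased choice — multiplying would bias border
densities downward. Correction is on by default for TMA-sized windows and
switchable off for whole-slide analysis where edges are negligible.

The expected curve permutes type labels among each reference's ≤100 µm
neighbors (the reference keeps its label, distances stay fixed), 100 times,
and averages, normalized identically. Neighbors are processed in sorted
index order so the permutation stream is reproducible. Permuting labels
conserves each neighborhood's target-label total by construction.
Multi-label cells contribute their full type set as one unit — equivalent,
for counting one target type, to permuting the is-target indicator.

Delta-CDF: both curves are normalized to total mass 1, cumulated, and the
100 per-bin CDF differences summed. Positive values mean observed mass sits
at shorter distances (colocalization); the magnitude is bounded by the bin
count. Zero-mass curves yield a missing value. The cohort test is a
one-sided (greater) one-sample t-test vs 0, requiring ≥3 samples, with
zero-variance input flagged degenerate.

## Tumor/stroma segmentation and cell labeling

Region channels are Gaussian-blurred (sigma = 1 px) then log2(x+1)
transformed. Multi-Otsu with four classes (non-tissue background, tissue
background, low- and high-intensity foreground) is computed *exactly*: the
optimal contiguous partition of the distinct-value histogram (equal-width
binned to ≤256 levels only when there are more) is found by dynamic
programming over all cut positions — the same optimum as exhaustive search
over threshold triples, without iterative-k-means initialization
sensitivity. Reported thresholds are midpoints between the bordering
levels of consecutive classes. The region threshold is the mean of the
low-intensity-foreground class (limiting undersegmentation of the bright
compartment), followed by a 10×10-square morphological closing, filling of
holes under 2500 px, and removal of 8-connected objects under 2500 px. The
hole/object filters are implemented directly on labeled components so the
"fewer than 2500" boundary is exact (2500-px features survive). Tumor is
the tumor-marker mask; stroma is the leukocyte mask minus tumor, so the two
never overlap. Cells are assigned to regions by their centroid pixel.

Cell labeling clusters per-cell log2(mean+1) intensities with an exact 1D
two-means (scan of all sorted split points; deterministic, first minimal
split wins); the threshold is the mean of the upper (membership) cluster,
biasing against false positives, and positives are values ≥ threshold.
Antigen-loaded macrophages are called on the upper-quartile average
(mean of cytoplasm pixels at or above their linear-interpolation 75th
percentile) of the tumor-marker channel in the cytoplasm (cell minus 1-px
membrane), thresholded with the tumor-marker cell-labeling threshold on the
log scale. Cells with no cytoplasm get a missing flag.

## Synthetic data

The tissue generator lays tangent reference/neighbor disk pairs on a
jittered grid with guaranteed ≥4-px clearance between sites, verifies on
the rasterized masks that every designated pair is within contact reach,
and multiplies the reference's contact-facing membrane pixels by the
polarization factor `f` using the *same* dilation rule as the analyzer —
so the noiseless expected sigma is exactly `log2 f`, giving a clean oracle.
Optional per-contact lognormal variation around `log2 f` with correlation
`rho` across two markers supports co-polarization tests. Noise is additive
Gaussian clipped at 0, or per-pixel Poisson counts (producing the
exact-zero pixels that exercise the fill-in rules). Point patterns are
homogeneous Poisson (independent labels — a delta-CDF null by construction)
or parent–offspring clusters over a uniform background. Two-compartment
images place a bright tumor blob inside a leukocyte-filled tissue disk with
multiplicative Gaussian noise; blur transition pixels populate the
low-intensity-foreground class as they do in real images.

What the generator does **not** emulate: realistic cell morphology,
point-spread functions, spectral spillover, marker co-expression structure
beyond the modeled coupling, segmentation errors (touching-cell
undersegmentation), or tissue-scale intensity gradients. Passing tests
therefore validate the estimators' correctness and calibration, not
robustness to those real-data effects.

## Problem sizes and defaults

| Parameter | Default | Meaning |
| --- | --- | --- |
| `membrane_width_px` | 2 (1 for IMC) | internal-boundary width |
| `dilation_radius_px` | 2 | diamond radius defining contact |
| `rdf_max_um`, `rdf_bin_um` | 100, 1 | RDF range and bin width (µm) |
| `n_permutations` | 100 | label permutations per reference |
| `null_seeds_per_cell` | 5 | seeded regions per cell per iteration |
| `null_min_region_px` | 15 | region size and eligibility floor |
| `null_iterations` | 100 | iterations of sample averages |

Validation runs use tissues of 200 contacts for polarization recovery, 100
25-contact samples for the correlation ordering, a 10 mm² window (~2000
points at 200 cells/mm²) for density calibration, and 100–200 replicates of
1 mm² patterns for the delta-CDF null and clustered detection; these sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping the suite fast. Poisson-noise checks use membrane means of 25
counts (per-pixel signal-to-noise ≈ 5), a realistic low-count regime.

## Numerical choices and limitations

- Intensities are float64 throughout after load; square pixels only.
- Contact/noncontact pixel sets are exact integer index arrays; no
  sub-pixel boundary estimation, no 3D geometry.
- The exact two-means and Multi-Otsu scans resolve ties toward the first
  (lexicographically smallest) optimum.
- RNG: `numpy` Generator streams derived from one master seed
  (`SeedSequence([seed, cell, iteration])` for the null model); no global
  RNG state, so identical seed + config reproduce byte-identical outputs.
- Run manifests record command, config, seed, input digests and package
  version; timestamps are omitted so reruns are byte-comparable.
- The analytic edge correction covers rectangular windows; masked/irregular
  regions would need a pixel-counting fallback, which is not implemented.
- Survival model fitting is out of scope; only the `sigma > 0` grouping
  rule is provided, for use with standard survival packages.
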