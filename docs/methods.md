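# Methods

`camii` implements the computational core of an imaging-guided culturomics
workflow: plates of a complex microbial community are photographed under
trans- and epi-illumination, every colony is segmented and quantified by 14
morphological features, a maximally diverse subset is picked, picked isolates
are identified by 16S amplicon sequence variants (ASVs), and the resulting
colony tables and genome sets feed spatial cogrowth and comparative-genomics
statistics. All of it runs on synthetic fixtures with known ground truth, so
every statistic can be scored against what was planted.

## Plate rendering and segmentation

Synthetic plates draw each colony as an intensity plateau with a 0.5-px
linear edge ramp centered on the nominal radius, optionally Gaussian-blurred
(default sigma 0.8 px) with additive Gaussian noise (default sd 2 on a 0–255
scale). The defaults mimic a well-focused transilluminated plate: high
colony-to-background contrast (peak 120–200 over background 30) and low
sensor noise. Shapes are disks, 1.4:1 ellipses, or disks perturbed by
low-order Fourier boundary noise ("irregular"); no optics or agar physics is
modelled.

Segmentation estimates the background by a coarse median filter (computed on
a 4x-downsampled copy, window 64 px at full scale), subtracts it, and
thresholds at max(8, 5 x noise sigma) where sigma comes from the median
absolute deviation of the subtracted image. Connected components are split,
when necessary, by a marker watershed whose markers are the h-maxima of the
component's distance transform (h = 30% of the maximum distance, 8-connected
labelling); h-maxima are insensitive to plateau and ridge noise inside a
single colony, so round colonies are never over-split while touching lobes
of comparable size separate cleanly. Each region is then re-thresholded at
half its plateau intensity. The plateau is estimated as the 90th percentile
of the region's values rather than the maximum, which rides on noise and
would bias the half-height boundary inward.

Area, perimeter and mean radius are measured on the sub-pixel half-height
iso-contour of the background-subtracted image (polygon area by the shoelace
formula, perimeter as polygon arc length, mean radius as mean
centroid-to-contour distance). Measuring on the iso-contour rather than by
counting pixels removes lattice quantization, which at the smallest colonies
(r = 8 px) contributes 2–3% area error on its own. When a caller supplies a
bare contour to `extract_morphology` with no intensity surface, area falls
back to the interior pixel count and perimeter to the weighted pixel-edge
estimator.

The shape descriptors are the common blob-detector definitions, all in
(0, 1]: circularity = 4 pi A / P^2; convexity = interior pixel count divided
by the number of pixel centers inside the convex hull of the region (counting
lattice points, not the hull polygon area, makes convexity exactly 1 for any
digitally convex region such as a rasterized disk); inertia =
lambda_min / lambda_max of the second-central-moment matrix. Intensity means
and variances are taken over interior pixels of the raw trans image (gray)
and epi image (R, G, B). Pixel coordinates are 0-based with x = column,
y = row, origin top-left.

Defaults that matter: rim-exclusion margin 10 px (colonies with any pixel in
the margin band are dropped), accepted area 20–50,000 px^2, minimum
circularity 0.2. These are configuration, not claims about the original
instrument, which does not publish its gates.

## Diversity-maximizing selection

Features are z-scored and embedded by PCA (eigendecomposition of the
covariance; all components kept; component signs fixed so the
largest-magnitude loading is positive; zero-variance columns dropped with a
warning). Selection is greedy farthest-first in the embedding: start from the
two points at maximum Euclidean distance, then repeatedly add the point whose
minimum distance to the chosen set is largest, breaking every tie toward the
lowest colony id. Farthest-first is a 2-approximation of the optimal max-min
dispersion subset, and the test suite checks the 1/2 bound against exhaustive
enumeration up to n = 12, k = 5. Strategies are compared by the accumulation
of unique taxa along the pick order: area under the curve by the trapezoid
rule, two-sided paired t-test across replicates, with all-equal differences
flagged as degenerate instead of dividing by zero.

## Isolate taxonomy and community summaries

An isolate is assigned the taxonomy of its highest-count ASV; it fails QC
when its total reads fall below 5 or its purity (top-ASV read fraction)
below 0.5 — both boundaries inclusive on the passing side, so exactly 5
reads or purity exactly 0.5 passes. Top-ASV ties break to the
lexicographically lowest ASV id and are logged. Bulk relative abundance is
reads over total mapped reads; biobank coverage is the cumulated bulk
abundance of ASVs represented by isolates. Shannon index uses the natural
log by default (configurable base); equitability is H / ln S with the
single-taxon case defined as 0. Condition ranking scores each growth
condition by the families it detects (relative abundance >= 0.001, matching
the 0.1% "abundant taxon" convention) that the base condition lacks, plus
Bray–Curtis dissimilarity to the base, and greedily orders conditions to
maximize the cumulative family union. The precise ranking used on the
original instrument is not published; this greedy union score is this
package's stand-in and is labelled as such.

## Taxonomy prediction from morphology

A multiclass random forest (500 trees, scikit-learn defaults otherwise,
seeded) is trained on the 14 features plus one-hot antibiotic condition and
the nearby-colony count. "Multilabel" is interpreted as single-label
multiclass — each colony carries exactly one genus. Evaluation resplits
70/30, stratified by genus to avoid empty test classes at realistic counts,
20 times; per-genus precision and recall on the held-out 30% are recorded,
with a genus absent from (or never predicted in) a test split recorded as
missing, never zero. The null model assigns each genus a precision equal to
its frequency among isolates. The data-rich-genus floor defaults to 100
isolates (15 for per-individual targeted models). Targeted picking returns
colonies whose argmax class is the target, ordered by probability, and is
scored as precision / base rate (fold improvement), flagged when the base
rate is zero or the prediction set empty.

A design note on the permutation baseline: repeatedly resplitting one fixed
label shuffle leaves that shuffle's chance feature–label correlations in
both folds, so its measured precision sits above the frequency null by
construction. The shuffle tests therefore re-permute labels independently
for every repeat, under which the expected precision equals the null exactly
(exchangeability).

## Spatial statistics

Two colonies are neighbors when their center distance is below 30 px plus
the sum of their radii, computed within a plate only. Crowding compares
colony areas between sparse (<= 1 neighbor) and crowded (>= 4 neighbors)
groups by a one-sided Mann–Whitney U test. The directed genus–genus network
compares, for every ordered pair (A, B), B colonies with at least one A
neighbor against B colonies with no neighbors at all; the effect size is the
fold-change of mean area, both one-sided tests are run and the smaller p is
reported with its sign, and Holm adjustment spans all conducted tests.
Pairs with fewer than 5 colonies on either side are skipped and logged.
When a condition column is present, only antibiotic-free ("mGAM") colonies
enter the analysis. The Mann–Whitney p is exact — full enumeration of group
assignments, valid under ties — whenever C(n1+n2, min(n1, n2)) <= 200,000,
and otherwise uses the tie-corrected normal approximation with continuity
correction; fully tied data return p = 1. Holm and Benjamini–Hochberg are
implemented from their step-down/step-up formulas and cross-checked against
statsmodels in the tests.

Growth kinetics match colonies across imaging days by greedy
nearest-centroid pairing within a 10-px tolerance (closest pairs first, ties
to the lowest colony id); unmatched later-day colonies start new tracks. The
detectable proportion of a genus on day d is the fraction of its final-day
tracks already detected by day d — non-decreasing by construction and
exactly 1 on the final day.

The synthetic community places colonies uniformly with rejection sampling
(minimum center separation = sum of radii + 2 px) on a plate sized so a
500–1,000-colony community has a mean neighbor count near 1, leaving a large
zero-neighbor reference group. Planted interactions multiply a colony's area
by the fold effect once per source genus present among its neighbors (not
per neighbor), times lognormal noise (sigma 0.3); because the noise is
multiplicative and i.i.d., the planted fold is exactly the expected ratio of
group means, which is what the network estimator measures.

## Comparative genomics

The HGT null assumes every aligned base of a candidate block matches
independently with probability equal to the genome pair's ANI, giving
p = P(Binomial(L, ani) >= round(identity x L)), evaluated through the
regularized incomplete beta function (scipy's binomial survival function)
and verified against an exact rational-arithmetic tail sum to 1e-12 relative
error. P-values are Benjamini–Hochberg adjusted over all blocks jointly; a
block is an HGT event iff adjusted p < 1e-5 and length strictly greater
than 2,000 bp. Species-pair frequency divides the number of unordered
genome pairs sharing at least one event by (genomes in A) x (genomes in B);
edge categories are interphyla / intraphyla-interfamily / intrafamily from a
taxonomy map. Gram enrichment builds a 2x2 contingency of HGT
presence/absence versus same/different Gram stain over all species pairs and
applies Pearson's chi-squared without continuity correction. Genotype cells
are reliable at depth >= 5 and haploidy >= 0.9 (inclusive); a SNP site is
retained only when strictly more than 90% of its cells are reliable. A leaf
SNP is a retained polymorphic site whose non-majority calls all sit in one
isolate. Genome QC requires coverage > 20x, N50 > 5,000 bp, completeness
> 80% and contamination < 5%, all strict. Species clustering is
single-linkage over ANI > 0.95 — deliberately transitive, so an A–B–C chain
above threshold is one cluster even if ANI(A, C) falls below it.

The genome generator derives all genomes from one ancestor by i.i.d.
substitutions (no indels), solving (1-p)^2 + p^2/3 = ANI for the per-lineage
substitution rate so pairwise identity hits the background ANI in
expectation; one scalar background ANI applies to every species pair, since
arbitrary per-pair targets are not mutually consistent under a star
phylogeny. Genomes are colinear, so the test fixture's candidate blocks come
from direct window comparison at equal coordinates (every planted block plus
random background windows) — a synthetic stand-in for an all-vs-all BLASTN
screen, whose tabular output is what `parse_blast_tab` consumes in real use.
Planted blocks are copied between the first genomes of the two species and
slightly raise that pair's measured ANI; with a 3-kb block in a 20–50-kb
genome the shift is below 0.01 and does not mask the block.

## What the fixtures do and do not show

The generators reproduce the statistical structure the analyses assume —
Gaussian genus morphologies, presence-based multiplicative growth effects,
i.i.d. substitution divergence, multinomial read sampling — not real plates
or genomes. Passing tests demonstrate that each estimator recovers what was
planted under its own model assumptions and that every threshold sits on the
stated side of its boundary; they say nothing about focus drift, uneven
illumination, colony merging on crowded real plates, indel-rich alignments,
or chimeric reads. Problem sizes in the test suite and acceptance script
(100 plates of up to 40 colonies, 500–1,000-colony communities, 20–50-kb
genomes, 20 bootstrap repeats, 50–100 simulation seeds) were chosen as the
smallest sizes at which the planted effects are comfortably identifiable.

## Numerical choices

Ties break deterministically everywhere (lowest id); PCA signs are fixed by
the largest-magnitude loading; all randomness flows from explicit integer
seeds through `numpy.random.default_rng`, making every result
bit-reproducible. Degenerate inputs fail loudly (mismatched image sizes,
single-genus training tables, zero margins in contingency tables, asymmetric
ANI matrices) or are flagged rather than silently zeroed (empty prediction
sets, zero base rates, zero retained SNP sites, undefined paired-t variance).
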