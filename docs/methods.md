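# Methods

## Model

Tumor transcriptomes are modeled as convex mixtures of K task-optimal
archetype profiles. In log2 expression space a sample s is

    x_s = w_s · A + o_{type(s)} + ε_s,   w_s ≥ 0, Σ_k w_sk = 1,

with A the K × G archetype matrix, o a per-cancer-type offset (tissue
identity), and ε Gaussian noise. Under this model the noise-free cloud
is a (K−1)-dimensional simplex whose vertices are the archetypes;
samples near a vertex are task specialists, interior samples are
generalists. All geometry is performed on per-gene-centered log2
values ("log2 fold change vs the cohort mean of that gene") because
polytope structure is a property of relative regulation, and on
unscaled (covariance) PCA so that large correlated programs dominate
the leading components rather than measurement noise.

## Polytope fitting and significance

K archetypes are fit in the first K−1 PCs. The fit is archetypal
analysis: minimize ‖X − S Z‖² with rows of S on the probability
simplex and archetypes Z constrained to the convex hull of the data
(without the hull constraint the objective is degenerate — any simplex
enclosing all points has zero residual). The weight step is solved
exactly: the optimal convex reconstruction of a point is its Euclidean
projection onto the simplex conv(Z), found by enumerating the 2^K − 2
faces, which is cheap at K ≤ 5 and fully vectorized. The archetype
step is unconstrained least squares followed by a pull-back into the
hull (perpendicular facet projection for single-facet violations, ray
clipping toward the data centroid otherwise). Ten seeded restarts
guard against local minima; restart positions are drawn from a
canonically sorted copy of the data so the result is invariant to
sample order, and the returned archetypes are ordered
lexicographically.

Fit quality is the t-ratio: the volume of a locally minimal enclosing
simplex (initialized from the fitted archetypes, inflated from their
centroid until enclosing, then optimized by SLSQP with analytic
gradients; enclosure constraints are imposed only on the data's hull
vertices, which is sufficient) divided by the volume of the data's
convex hull (Qhull; exact hulls are computed up to 8 dimensions,
covering the 3–5-archetype regime). Significance: every PC column is
permuted independently (preserving each component's marginal loading
distribution while destroying their dependence) and the full
fit → enclosing simplex → t-ratio pipeline is recomputed per shuffle
with exactly the same settings as the observed statistic, so observed
and null are exchangeable under independence and the test is
calibrated. p = (1 + #{null t ≤ observed t}) / (1 + n_shuffles), and
the smallest k in the candidate range with p < 0.01 is selected (1000
shuffles by default).

**Known limitation.** The selection rule returns the *smallest*
significant k. On synthetic data with a crisply planted 4- or
5-vertex polytope, the 2-dimensional PCA shadow of that polytope is
itself a polygon with corners — a strong violation of column
independence — so the k = 3 test also rejects and the rule stops at 3.
Across a broad scan of mixture concentrations (0.1–1.5), noise levels
(0.05–3), cohort sizes and irregular geometries we found no planted
regime in which the shadow is null-like while the true-k polytope
remains significant. Correct selection of k > 3 therefore requires
data whose lower-dimensional shadows are elliptical, which is a
property of noisy real cohorts rather than of clean simplex
simulations; the corresponding recovery test documents this honestly
and archetype *position* recovery at known k is verified separately
(vertex error ≲ 0.2% of the simplex scale at low noise).

## Enrichment

Distances to an archetype are Euclidean in the fitting PC space. The
first bin holds the closest max(50, ⌈0.05·n⌉) tumors — 50 tumors for
cohorts up to 1000, 5% beyond that (159 of 3180 pooled tumors), and at
most 20% of a 250-tumor cohort. The remaining samples form four more
equal-count bins (five total, configurable) used only by the peak
rule: a feature is reported at an archetype only if its per-bin mean
or prevalence is strictly maximal in the first bin (ties fail,
conservatively), if its BH q-value is below 10% within its feature
family (pathways, genes, continuous clinical, discrete clinical are
corrected separately), and if that archetype is where the feature is
maximally enriched. Pathway scores are plain means of member-gene
centered values. The leave-one-out control removes a pathway's genes,
refits PCA and archetypes, re-matches archetypes to the originals by
nearest gene-space position (Hungarian assignment; a non-bijective
greedy match is flagged inconclusive), and re-tests the pathway; it is
applied to pathways with more than 100 genes, smaller ones passing
vacuously.

## Universal tasks

Per-type centering removes tissue identity before pooling, so pooled
coordinates measure how a tumor deviates from its own tissue's mean.
Pooled fits use the shared gene universe (intersection of cohort gene
lists). Type composition near an archetype is, per type, the fraction
of that type's tumors among the ⌈0.1·n⌉ closest — about 10% everywhere
under even mixing. Archetype pathway profiles (mean pathway score of
first-bin tumors) are scaled per pathway by the SD across profiles and
clustered with diagonal-covariance Gaussian mixtures; the component
count minimizes BIC. Tissue↔universal matching uses the one-sided
hypergeometric overlap of significant pathway sets (FDR < 10% and mean
log2 fold change > 0.1) within the union universe of the tissue's
archetypes, Bonferroni-corrected over all pairs at 1%; a tissue
archetype matching nothing is reported tissue-specific.

## Mutation–front alignment

The front is the direction space of the archetypes' affine hull
(differences from the first archetype, orthonormalized) — effect
vectors are centroid differences, so only directions matter and the
result is origin-independent. Effect vectors are computed in a PC
space larger than the front (10 components by default) so angles out
of the front plane are informative. The null pools shuffled carrier
assignments across alterations, drawing each shuffle's carrier count
from the observed counts (the null angle distribution is insensitive
to carrier frequency); 10^5 shuffles by default. The p-value of angle
α is P(null ≤ α): empirical (1+x)/(1+n) wherever at least ten controls
lie below α, and below that support limit a fifth-order polynomial fit
to log P at the empirical step points extrapolates the tail.
Extrapolated p-values may go below 1/n_shuffles by design; if the
fitted tail is non-monotone on the evaluation grid the model falls
back to the empirical estimator with a warning, and a logged
diagnostic checks factor-of-two agreement between the polynomial and
the empirical CDF in the supported range. Aligned alterations
(q < 10%) are assigned to the archetype(s) whose first-bin carrier
enrichment is significant at FDR 10%, closest-angle first; a vector
pointing at a face legitimately reports several archetypes.

## Drug scoring

Cell lines and tumors are quantile-normalized jointly on shared genes,
cell lines centered per gene over lines, and projected on the tumor
loadings restricted to shared genes. Per archetype, measured lines are
split into four equal-count distance bins; drugs with fewer than five
lines in any bin are discarded. The score multiplies
(G_i − G_{i+1} + 2⟨σ⟩) over consecutive bins, with G_i the bin median
GR AOC and ⟨σ⟩ the median within-bin standard error of the median
(1.2533·sd/√n under normality; plain sd/√n is a config switch); a
consecutive increase above 2⟨σ⟩ zeroes the score outright. The
Mann–Whitney gate tests first-bin AOC against all other bins
(two-sided p, direction must favor the first bin) with BH correction
across drug × archetype pairs. Same-mechanism drugs can be pooled
before binning.

## Heterogeneity

QC drops genes detected in under 5% of cells, then cells with fewer
than 1500 or more than 8000 detectable genes (the synthetic pipeline
scales these gates to its smaller gene universe). Cells expressing
hematopoietic (PTPRC), fibroblast (PDGFRA/ZEB1/ACTA2) or endothelial
(PECAM1) markers above the detection threshold (nonzero by default)
are excluded. Each gene is residualized on total count, mitochondrial
fraction and tumor-of-origin indicators. Per tumor, cells are centered
within tumor and the variance captured by the top-m bulk-reference PCs
(re-orthonormalized after restriction to shared genes) is divided by
the variance captured by the cells' own top-m PCs; by optimality of a
dataset's own PCA the ratio lies in [0, 1], reaching 1 only when
within-tumor spread lies inside the reference span. m defaults to 5.
The control permutes each reference gene column independently
(preserving per-gene variances exactly, destroying gene–gene
correlation), recomputes reference PCs and ratios, and a two-sided
paired t-test across tumors compares real to mean-control ratios; a
PC-count sweep (e.g. m = 5..50) is available as a robustness
diagnostic.

## Synthetic data: what it emulates, and what it does not

The generators plant exactly the structures the pipeline is meant to
detect: block-structured archetypes (each over-expresses a disjoint
gene block by 2 log2 units, plus dense low-amplitude structure so the
front is supported by many genes), symmetric-Dirichlet mixture weights
(concentration 0.3 by default — a specialist-leaning continuum;
concentration → 0 gives vertex clusters, > 1 generalists), Gaussian
log-space noise (0.1–0.2 log2 units), per-type tissue offsets, and a
configurable metastatic fraction. Drivers raise carrier probability
with the weight on their target archetype and shift carriers along
(target − centroid), inside the front span; passengers get uniform
carriers and a shift orthogonalized against the front. Drug AOC decays
linearly with distance to the target archetype (baseline 1.0, slope
0.05 per PC-distance unit by default, so sensitivity does not saturate
at zero across the panel — mirroring the bounded range of
growth-rate-corrected metrics), with untargeted controls and an
optional missingness mask. Single cells displace from their tumor's
profile with a fraction ρ of variance inside the span of the top
inter-tumor PCs and 1−ρ isotropic; counts are Poisson draws on
exponentiated log-means (depth 2000 by default), with an
infinite-depth mode that emits log profiles directly for recovery
tests. Marker genes are silenced in cancer cells and switched on in a
planted non-cancer fraction.

What this does not emulate: batch effects, platform differences beyond
a global quantile mismatch, copy-number segmentation, realistic
library-size and dropout distributions (Poisson only; a negative
binomial is noted as an extension), or correlated clinical
confounding. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure, not
robustness to every artifact of real cohorts.

## Numerical choices

Deterministic tie-breaks throughout: PCA loading signs fix the
largest-magnitude entry positive; distance ties break by sample id;
entropy ranking ties break lexicographically after rounding to 12
decimals; archetype output is sorted lexicographically. Convexity and
enclosure tolerances are 1e-9; weight-simplex feasibility 1e-12.
Permutation p-values use the (1+x)/(1+n) estimator, which never
returns zero and makes rejection exact at nominal levels that are
multiples of 1/(1+n). All randomness flows through
numpy.random.default_rng seeds derived deterministically from the run
seed, so identical configs reproduce byte-identical outputs.

Test-suite problem sizes are deliberately modest — cohorts of 60–400
samples, 100–200 permutation shuffles, 10^5-shuffle null models
checked against a 10^7-draw brute-force null on a 60-sample instance —
chosen so each check has clear statistical power at the planted effect
sizes while the whole suite stays quick to run.
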