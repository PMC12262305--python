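# Methods

This note documents the statistical models, defaults and design choices
behind `stic_atlas`, in the spirit of a package vignette: what each stage
assumes, which knobs matter, and what the synthetic cohort does and does
not establish about real data.

## Preprocessing

AOI-level counts are variance-stabilised by upper-quartile size
normalisation followed by `log2(x + 1)`. The size factor of AOI *j* is its
Q3 of nonzero counts divided by the leave-one-out geometric mean of the
other AOIs' Q3s; this makes the factor exactly 1 for identical AOIs and
makes the transform exactly invariant to rescaling a single AOI's depth.
Batch (GeoMx-run) effects are removed per gene by subtracting each batch
mean's deviation from the overall mean — ordinary least squares with a
batch factor — which preserves the per-gene grand mean to machine
precision and is idempotent. We correct after stabilisation because the
least-squares model assumes roughly additive, homoscedastic errors, which
raw counts violate; the counts-first order remains available
(`--order batch-first`) for comparison with analyses that corrected raw
counts before transforming. Batch mixing is quantified by a kBET-style
rejection rate: for seeded random anchor AOIs, a chi-square goodness-of-fit
test of the k-nearest-neighbour batch composition against the global batch
frequencies, reporting the fraction rejected at α = 0.05 (0 = perfectly
mixed). This is a reimplementation of the rejection-rate idea, not a
bit-compatible port of the kBET package.

## Consensus NMF subtyping

Expression is factorised as `X ≈ WH` (Frobenius loss, multiplicative
updates, seeded uniform initialisation); batch-corrected values are shifted
by the global minimum and clipped at zero first, since batch removal can
produce small negatives. Each of `n_runs` (default 100) seeded runs labels
every AOI by the argmax row of `H` (ties to the lower index); the consensus
matrix holds pairwise co-assignment frequencies; final labels cut the
average-linkage tree of `1 − consensus` at the candidate rank.

Rank selection maximises the cophenetic correlation between consensus
distances and their dendrogram. Consensus entries are quantised at
`1/n_runs`, so cophenetic differences below that step are sampling noise,
not evidence; candidate ranks within `1/n_runs` of the maximum are treated
as tied and resolved by higher mean silhouette width (computed on
`1 − consensus` distances), then by the smaller rank. In practice the
silhouette is the sharper instrument near the true rank: on the default
synthetic cohort cophenetic is ≥ 0.99 at ranks 3–6 while the silhouette
peaks decisively at rank 4 (≈ 0.9 vs ≤ 0.75).

Dispersion (`mean 4(c − ½)²`, 1 exactly for a binary consensus) is
reported alongside but does not enter selection: it increases monotonically
with rank on block-structured data and cannot flag over-partitioning.

## Aneuploidy from locus counts

A sample's locus counts are normalised to fractions. The sample is matched
to the n = 7 panel members nearest in Euclidean distance between
locus-fraction vectors (ties broken by panel order). Each of the 39
non-acrocentric autosome arms is scored as
`Z = (Observed − μ_panel) / σ_panel`, where `Observed` is the summed locus
fraction over the arm; |Z| > 5 calls a gain (Z > 5) or loss (Z < −5).

μ and σ default to the **full** panel rather than the matched subset.
Measured on three independent panel realisations with 100 simulated
single-arm events each, matched-subset σ estimates produced arm-level
false-call rates of 0.7–1.8% versus 0.03–0.05% for the full panel at equal
(100%) sensitivity: the seven nearest members are by construction close to
the sample, so their spread understates the sampling variability and
inflates |Z|. `arm_stats="matched"` restores the subset reading. The
matched subset is still the reference for bin-level log2 ratios, where the
quantity of interest is a location (the mean fraction), not a scale.

Bin-level ratios use 50-kb half-open bins;
`log2((f_sample + p) / (f_panel + p))` with pseudocount `p = 0.5/n_loci`;
bins without loci are missing and excluded. Segmentation is a recursive
circular binary segmentation: within each segment the arc `(i, j)`
maximising the standardised mean-difference statistic is tested by a
seeded permutation test (default 1000 permutations, α = 0.01, minimum
width 2 bins); permutations run in vectorised blocks with early acceptance
once the exceedance count guarantees p ≥ α. No pruning/undo step is
applied; bit-compatibility with DNAcopy is a non-goal. A focal
amplification at 19q12, 19q13.2 or 8q24 requires an overlapping segment
with log2 > 0.25 spanning less than 90% of its arm ("sub-chromosomal";
the cutoff is our operationalisation). The aneuploidy index sums the
widths of bins whose segment-assigned log2 exceeds +0.25 or falls below
−0.25 (bin-level log2 available via `level="bin"`).

Heavily aneuploid genomes renormalise: a large gain depresses every other
arm's fraction, so shadow calls on unaltered arms (typically losses around
|Z| ≈ 5–7) are expected behaviour of fraction-based scoring, not a defect.

## Differential expression and enrichment

Per gene, a two-group comparison on stabilised expression with pooled
residual variance `s²` (df = n₁ + n₂ − 2). Variances are shrunk toward a
prior `s₀²` with prior df `d₀` estimated by method of moments on
`log s²` (digamma/trigamma matching; `d₀ = ∞` when the observed spread is
no wider than sampling alone), giving the moderated statistic
`t = log2FC / √(s̃²(1/n₁ + 1/n₂))` with `s̃² = (d₀s₀² + d s²)/(d₀ + d)` on
`d₀ + d` df. Significance: BH-adjusted p < 0.05 and |log2FC| > 0.5.
Per-subtype signatures take the top 50 significant upregulated genes by
moderated t from each subtype-vs-rest contrast, after removing genes
significant-up in two or more subtypes.

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hits
weighted by |score|^w, default w = 1). The null resamples gene sets of
equal size from the universe (seeded) rather than permuting phenotypes,
because subtype-vs-rest contrasts have small groups;
`p = (1 + #{same-sign |ES*| ≥ |ES|}) / (n_perm + 1)` and
`NES = ES / mean|same-sign ES*|`, BH across sets.

## Clinicopathological statistics

Cross-tabulations are tested by Pearson chi-square (no continuity
correction) when all expected counts are ≥ 5, otherwise by an r×c Fisher
exact test (probability-ordering two-sided definition): full enumeration
of the conditional table space when the grand total is ≤ 500, otherwise a
seeded Monte Carlo estimate using sequential multivariate hypergeometric
sampling, flagged in the result. Because published tables do not always
honour the expected-count rule, `associate()` reports the chi-square value
alongside the rule-selected Fisher test whenever the rule is borderline —
the bundled cohort's printed p-values (0.031, 0.017, 0.275) are chi-square
values even where expected counts dip below 5. H-score is
`Σ intensity × percent` over intensities 0–3 (range 0–300); the Ki67 index
maps to Low (< 5%), Intermediate (5–20%, both boundaries inclusive) and
High (> 20%).

## Synthetic cohort

The generator emulates the study's data structure, not its biology. Genes
have log-normal baselines (log2 mean 5, SD 1.5) and gene-specific
negative-binomial dispersions (log-normal around 0.25, a realistic
AOI-level overdispersion for targeted count assays); each of the four
subtypes upregulates 50 disjoint signature genes at mean log2FC 2 with
equal amplitude, so the clusters are symmetric and well separated — the
regime in which consensus rank selection is meaningful. Reference
centroids encode the progression geometry: normal tube epithelium (NFT)
expresses the dormant signature at 0.4 (tubal differentiation markers),
and the HGSC centroid loads 0.1/0.3/0.5/1.0 on the
dormant/mixed/immunoreactive/proliferative signatures, which places
dormant lesions nearest NFT and proliferative lesions nearest HGSC by
construction. Batch effects are additive per-gene log-scale shifts per
simulated run (SD 0.3 by default); per-AOI depth varies log-normally.

DNA: 20,000 loci placed uniformly (the repetitive-element anchoring of
real amplicons is out of scope) with log-normal amplification propensities
shared between samples and the 30-member euploid panel, per-sample
log-normal locus noise (SD 0.1), and multinomial reads at depth 500,000.
Copy-number events are fixed per subtype — recurrent 13q/17p/17q/22q
losses at log2 ≈ −0.7 (a clonal single-copy loss at ~80% laser-capture
purity), a 3q gain at +0.58, and focal 19q12/8q24 amplifications at +1.0
in the proliferative subtype — each jittered ±15% per patient. Genes
inside a patient's event regions shift their expression by the same log2
(dosage coupling, configurable). Covariates are drawn from
subtype-conditional multinomials defaulting to the bundled 166-lesion
cohort proportions.

The toy genome (default) has 22 autosomes of 10 Mb, p/q split at 4 Mb,
five acrocentric p-arms and named cytobands including the focal targets;
"hg" mode uses exact GRCh37 autosome lengths with approximate centromere
and target-band coordinates and generic filler bands elsewhere.

What passing tests show — and don't. Recovery results (ARI ≥ 0.9, rank 4,
signature recovery, CN–expression correlation) demonstrate that the
pipeline's machinery is correct and internally consistent under a
generative model with clean, disjoint signatures and subtype-deterministic
copy-number events. Real AOI data have correlated gene modules, gradient
rather than discrete subtype structure, segmentation-dependent purity, and
probe-level artefacts; none of these are simulated, so the synthetic
results bound implementation error, not real-data performance.

## Numerical and scale choices

Simulation sizes follow the package's default study conditions: 2,000
genes × 160 epithelial AOIs (40 per subtype from 10 patients × 4 AOIs),
100 consensus runs over ranks 2–6, 100-simulation batteries for arm calls
and CBS breakpoints. NMF runs cap at 300 iterations (tolerance 1e-5,
loss checked every 10 iterations) inside consensus, 500/1e-6 standalone.
CBS permutations stop early only to *accept* the null (never to reject),
so reported splits always rest on the full permutation count. Fisher
enumeration switches to Monte Carlo above N = 500. Degenerate inputs
(zero-count AOIs, zero-variance arms, constant consensus, empty gene-set
intersections) raise or warn explicitly rather than propagating NaNs; the
conventions are documented on each function.

## Known limitations

* CBS evaluates all O(n²) arcs per segment; chromosomes with thousands of
  bins (hg mode at 50 kb) are slow — the toy genome (200 bins per
  chromosome) is the intended simulation scale.
* The moderated-t prior fit uses moment matching, not the exact marginal
  likelihood; the two agree in the pooled-variance limit (tested) but can
  differ slightly at small gene counts.
* Fisher enumeration cost grows combinatorially with table size; large
  sparse tables fall back to Monte Carlo.
* The generator's subtype clusters are symmetric by design; rank selection
  on strongly nested or graded real cohorts will not behave this cleanly.
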