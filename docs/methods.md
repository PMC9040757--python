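# Methods

This note documents the statistical procedures, the synthetic-data
model they are validated against, the numerical choices, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

Community data live in a `CommunityTable`: a samples × taxa matrix of
counts (integers) or relative abundances (rows summing to 1 within
1e-9), tagged with kingdom (bacteria / fungi / oomycetes) and
taxonomic level (ASV / OTU / phylum / custom). Metadata rows carry the
six design factors of a two-field fertilization trial: field
(DEMO = NK/NPK plots, DOK = CONMIN/BIODYN plots), management, plot,
genotype, compartment (soil, rhizosphere, root) and stage (unplanted,
vegetative, reproductive); unplanted soil has genotype `none`.

## Rarefaction and diversity

Rarefaction draws each retained sample's row as a multivariate
hypergeometric sample of fixed depth from its count multiset (without
replacement), so retained row sums equal the depth exactly; samples
below depth are dropped and logged, never up-sampled. Default depths
follow the kingdom conventions of amplicon surveys at these marker
genes: 1000 (bacteria, 16S V5–V7), 10000 (fungi, ITS2), 2000
(oomycetes, ITS1).

The Shannon index `H = −Σ p_i ln p_i` uses the natural log (the common
ecology convention; the base is a parameter) and is reported as the
mean over 999 independent rarefactions; a sample whose total equals
the depth has no sampling variability and returns its exact index.

Bray-Curtis, PCoA, PERMANOVA and constrained PCoA are implemented
in-package (they are part of the package's subject matter), with
scikit-bio used as an independent oracle in the test suite:

* **PCoA** is classical metric scaling: eigendecomposition of the
  Gower-centered matrix `−½ J D² J`. Negative eigenvalues are reported
  but excluded from the proportion-explained denominator; no Cailliez
  or Lingoes correction is applied. Axis signs are fixed by making the
  largest-magnitude loading positive.
* **PERMANOVA** partitions `SS_total = Σ_{i<j} d²_ij / n` sequentially
  (Type-I) over the terms in the user-given order, via projection
  matrices built from full dummy codings; interactions are factor
  crosses (`A:B`). Pseudo-F uses the full-model residual. P-values
  come from free permutation of sample labels (no strata) with the
  add-one correction `p = (1 + #{F* ≥ F}) / (1 + n_perm)`, so p never
  equals 0. Whether marginal or sequential sums of squares (or
  permutation strata) better reflect common practice is genuinely
  open; sequential/free was chosen and the term order is the user's.
* **Constrained PCoA** (distance-based RDA) regresses the PCoA scores
  on all positive axes onto the constraint design, eigendecomposes the
  fitted configuration, and reports `SS_fitted / SS_total` with a
  row-permutation p-value.
* **Permutation tie handling.** Exceedance counts use a relative
  tolerance (`stat* ≥ stat·(1 − 1e-10) − 1e-12`) so that exact ties —
  e.g. the mirror relabeling of two equal groups, which reproduces the
  observed statistic up to floating-point jitter in the permuted
  path — are counted, keeping permutation p-values consistent with
  exhaustive enumeration.

Group comparisons use the two-sided Wilcoxon rank-sum
(Mann–Whitney) test for every group pair, Benjamini–Hochberg q-values
across all pairs, and a greedy insert-absorb compact-letter display
(groups sharing a letter have q ≥ α; ties broken by group order).
All-constant comparisons return p = 1 rather than an error.

## Stable/dynamic partition

Detection ("presence") is a nonzero count in the **rarefied** table by
default — the alternative (pre-rarefaction counts) is supported via
the `detection_table` argument, since which table prevalence should be
evaluated on is a genuine convention choice; rarefied is the default
because it equalizes detection effort across samples. A taxon is
stable in a compartment when its prevalence is **strictly** greater
than θ = 0.8 ("more than 80% of samples") among that compartment's
vegetative samples and among its reproductive samples, pooled across
managements and genotypes; an inclusive (≥) mode and per-stratum
prevalence are available as options.

The aggregated relative abundance (aRA) of a taxon set is the mean
over samples of the per-sample sum of the set's proportions, ×100.
(Mean-of-sums equals sum-of-means on complete tables; mean-of-sums is
used because it extends correctly when samples are subset.) The
stable-to-dynamic ratio is `aRA_stable / (100 − aRA_stable)`,
reported at 2 decimals alongside full precision, undefined at 0 and
100. Note the two published anchor values (0.65 at 39.35% stable,
4.13 at 80.49% stable) are both consistent only with stable/dynamic in
the numerator/denominator; a legend parenthetical suggesting the
inverse ("60.65%/39.35%") is arithmetically inconsistent with its own
stated result and is not followed. The symmetry
`ratio(x) · ratio(100 − x) = 1` is enforced by a property test.

Cross-compartment overlap of stable sets is reported as counts for
every inclusion-exclusion (Venn) region.

## Convergence analysis

Reference communities are the **mean** relative-abundance profile of
the defining sample set (median, renormalized, as an option): initial
= unplanted soil before sowing, final = reproductive-stage roots.
Every sample gets coordinates `(d_init, d_final)`, its Bray-Curtis
distances to the two references. The published phrasing of the 1-D
"distance distribution" admits several readings (norm of the 2-vector,
|d_init − d_final|, pairwise distances in the plane); the per-sample
Euclidean norm is emitted for display, while **inference** uses the
2-D centroid-separation statistic Δ = ‖c̄_A − c̄_B‖ with a label
permutation test — an unambiguous statistic in the same plane. The
level contrast runs the identical procedure on an ASV-level and a
phylum-level table over the same samples with the same seed, returning
(Δ_asv, p_asv, Δ_phylum, p_phylum).

## Taxa–metabolite covariation

Preprocessing: per compound, zeros are offset by half the smallest
positive value, then log₁₀, then range normalization to [0, 1]
(constant compounds map to 0 and are flagged). Log base 10 and the
half-minimum offset are conventions; a state flag prevents double
transformation.

Ranking: one random-forest regression per compound (compound ~ all
taxon RAs, taxa filtered to ≥10% prevalence first). Importance is the
permutation increase in out-of-bag MSE, computed per tree by
re-predicting the tree's OOB samples with one feature column permuted
(the unscaled regression-forest "%IncMSE"); sklearn provides the
forest, the OOB bookkeeping mirrors its bootstrap draw. A taxon's
score combines importances across compounds by **max** (default;
mean as an option — how multi-compound responses are combined is an
open convention), and the top K = 25 taxa are kept. Whether the
forest response should be individual compounds, their principal
coordinates, or a multivariate forest is likewise open; per-compound
with max-combination is implemented. Defaults n_trees = 500, sklearn
feature subsampling; all exposed.

Network: two-sided Spearman ρ for every (selected taxon, compound)
pair; edges require |ρ| > 0.5 **and** raw p < 0.05 (deliberately
unadjusted — the thresholds act jointly). Constant members are
skipped with a warning. Nodes carry the vegetative/reproductive
mean-abundance ratio (NaN when absent at both stages, ∞ when absent
only at the reproductive stage).

## OTU clustering

Greedy centroid clustering: sequences in decreasing abundance order
(ties lexicographic by id); a sequence joins the first centroid whose
global pairwise identity reaches the threshold (default 0.97), else
founds an OTU. Identity = matches / alignment columns under global
alignment with match +1, mismatch −1, gap −2 (all exposed); only the
97% threshold is a field convention, the scoring is this package's
stated choice. The ordering rule makes the result independent of
input file order.

## Synthetic data model

The generator emulates the field design: per plot, six unplanted soil
samples; per plot × stage, three bulk-soil samples and, per genotype,
six replicate plants each contributing a rhizosphere and a root
sample. Defaults: one plot each for NK and NPK, three each for CONMIN
and BIODYN, five genotypes.

Counts are Dirichlet-multinomial: condition composition π_c, sample
proportions ~ Dirichlet(α₀ π_c) with α₀ = 500 (moderate amplicon-like
overdispersion), counts ~ Multinomial(depth, ·) with depth ~
log-normal around 3× the kingdom's rarefaction depth (σ = 0.5), so
rarefaction drops a small, known fraction of samples (~1–2%).

Composition structure:

* Per-compartment baseline taxon weights are heavy-tailed
  (`exp(0.5 z_global + 1.5 z_compartment)`), giving realistic
  dominance spectra and distinct compartment communities that still
  share the taxon pool.
* The planted stable core (default 20 taxa; the rhizosphere core
  shares ~60% of the root core) gets a mild profile
  (`exp(0.3 z)`, stage-independent) scaled so the core carries exactly
  `core_mean_ra` (default 0.4) of the community at both planted
  stages — mild so that *every* core taxon keeps expected prevalence
  > 0.9 at rarefaction depth.
* Every non-core ("dynamic") taxon in rhizosphere and root has a
  preferred stage; away from it its weight is multiplied by 0.01, so
  dynamic taxa are abundant at one stage and rarely detected at the
  other. Soil has no stage structure of its own.
* Convergence: soil and rhizosphere phylum totals at stage s are
  pulled toward the reproductive-root phylum composition,
  `target = (1 − κ_s)·current + κ_s·final`, with κ_unplanted = 0,
  κ_veg = κ/2, κ_rep = κ (default 0.5), and the shift is broadcast
  proportionally to member taxa — so the host footprint is a
  phylum-level signal by construction, while within-phylum ASV
  composition is untouched.
* Small stage-constant log-normal effects for management (σ = 0.1),
  plot (0.05) and genotype (0.05) provide nuisance variation.

Metabolites (root samples only): compound j has
`log intensity = a_j·1[reproductive] + β·z(RA of linked taxon) + ε`,
ε ~ N(0, noise_sd), exponentiated to stay positive; stage effects
a_j ~ N(0, 1). The link acts on the **standardized** RA of one planted
core taxon per linked compound, making β an effect size per RA
standard deviation — under the Dirichlet-multinomial noise model the
raw RA of a core taxon has a standard deviation of well under 0.01, so
an unstandardized link of any plausible β would be undetectable and
the parameter would be meaningless as a dial. Defaults β = 5,
noise_sd = 0.1, 12 compounds, 3 links.

What the generator does **not** emulate: phylogenetic correlation
among taxa, raw-read artefacts (chimeras, primer bias), compositional
coupling between kingdoms, spatial autocorrelation beyond the plot
effect, and metabolite–metabolite covariance. Passing recovery tests
therefore shows that the analysis machinery is correct under the
stated generative assumptions, not that those assumptions hold for any
particular field dataset.

## Determinism and seeds

Every stochastic step takes an explicit seed. The pipeline's master
seed fans out via `numpy.random.SeedSequence(master, spawn_key=(i,))`
to one sub-seed per stage, so any stage is reproducible in isolation;
a rerun with the same master seed is byte-identical, which the test
suite verifies file-by-file.

## Problem sizes

The validation suites run at deliberately modest sizes chosen to make
the Monte-Carlo answers stable while keeping a full run fast on one
CPU: 20 simulations for stable-core recovery (30 root samples/stage,
150 taxa, 20-taxon core), 50 for convergence detection and 200 for its
null calibration (199 permutations where only the rejection rate at
α = 0.05 matters, 999 elsewhere), 50 for covariation link recovery
(48 root samples, β = 5) and 20 for its null edge rate, and 500 null
simulations at n = 20 for PERMANOVA type-I error. The demo bundle is
240 samples × 200 taxa × 3 kingdoms.

## Known limitations

* PERMANOVA supports free permutations only — no restricted
  (stratified) permutation for split-plot designs, and no mixed
  models.
* No phylogenetically informed metrics (UniFrac) or
  compositionality-aware correlation (SparCC-type); Spearman on RAs
  inherits compositional coupling, mitigated only by the |ρ| and K
  thresholds.
* The greedy OTU clusterer is quadratic in the number of centroids and
  intended for ASV sets of field-study scale, not for raw-read
  dereplication.
* Printed dataset-level quantities from any particular field study
  (stable OTU counts, exact aRA percentages, distance values) depend
  on that study's raw data and are out of scope here; the package
  reproduces the *procedures* and validates them on synthetic ground
  truth.
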