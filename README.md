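# rhizodyn

Analysis toolkit for the spatiotemporal dynamics of multi-kingdom
root-associated microbiota in field experiments — bacteria, fungi and
oomycetes profiled across soil, rhizosphere and root compartments at
unplanted, vegetative and reproductive sampling times, under
contrasting soil managements and host genotypes.

It is written for microbiome researchers who have amplicon count
tables (ASV or OTU level), sample metadata and optionally metabolite
intensity matrices, and who want a tested, scriptable implementation
of four analyses that are usually stitched together ad hoc:

1. **Diversity profiling.** Shannon alpha-diversity averaged over 999
   independent rarefactions; Bray-Curtis dissimilarity
   `BC(x, y) = Σᵢ|xᵢ − yᵢ| / Σᵢ(xᵢ + yᵢ)` on rarefied tables; PCoA;
   sequential (Type-I) PERMANOVA with free permutations; constrained
   PCoA (distance-based RDA); pairwise Wilcoxon rank-sum tests with
   Benjamini–Hochberg correction and a compact-letter display.
2. **Stable/dynamic partition.** A taxon is *stable* in a compartment
   if it is detected in more than θ = 80% of samples at **both** the
   vegetative and reproductive stages; all other observed taxa are
   *dynamic*. The partition is summarized by the aggregated relative
   abundance (aRA, in %) of the stable set and the stable-to-dynamic
   ratio `aRA / (100 − aRA)` — e.g. a stable aRA of 39.35% gives a
   ratio of 0.65, and 80.49% gives 4.13.
3. **Convergence analysis.** Every sample is located by its
   Bray-Curtis distances `(d_init, d_final)` to an *initial* reference
   community (mean profile of unplanted soil) and a *final* one (mean
   profile of reproductive roots). Group separation is the Euclidean
   distance between group centroids in this plane, tested by label
   permutation — run at ASV and phylum resolution on identical samples
   to localize the host's footprint on the community.
4. **Taxa–metabolite covariation.** Metabolite intensities are log₁₀
   transformed and range-normalized per compound; taxa are ranked by
   random-forest permutation increase in out-of-bag MSE (per compound,
   max across compounds), the top K = 25 retained; Spearman
   correlations with |ρ| > 0.5 and raw p < 0.05 become edges of a
   bipartite taxon–compound network, with nodes annotated by the
   vegetative/reproductive mean-abundance ratio.

A synthetic field-experiment generator (`rhizodyn.synthetic_data`)
plants all of this structure — a stable core with fixed aRA,
stage-specific dynamic shells, phylum-level convergence of strength κ
toward the reproductive-root composition, and taxon–lipid links of
effect size β — under a Dirichlet-multinomial count model, so every
analysis can be validated against known ground truth.

Also included: greedy centroid OTU clustering of ASV sequences at 97%
global-alignment identity, readers for QIIME-style TSV and BIOM-1.0
JSON tables, FASTA, taxonomy (per-rank or semicolon-joined) and
tab-separated metadata.

## Worked example

```sh
rhizodyn demo --out demo_run --seed 42
```

generates a reduced synthetic experiment (240 samples, 200 taxa per
kingdom, three kingdoms) and runs all seven pipeline stages. From the
run manifest and artifacts for bacteria:

```
n_samples_raw: 240        rarefaction depth: 1000
dropped below depth: 3    (so.unp.NK-1.1, so.veg.CONMIN-1.1, rh.veg.CONMIN-1.B73.2)
stable root taxa: 20      stable aRA: 40.2% (veg) / 40.4% (rep)
stable-to-dynamic ratio:  0.67 (veg) / 0.68 (rep)
convergence contrast:     delta_asv = 0.053 (p = 0.001)
                          delta_phylum = 0.103 (p = 0.001)
PERMANOVA:                compartment R² = 0.494, stage R² = 0.140 (both p = 0.001)
```

Read: rarefaction at depth 1000 dropped 3 of 240 samples; the
stability filter recovered exactly the 20-taxon planted core, whose
aggregated relative abundance (~40%) matches the generator's
`core_mean_ra = 0.4`, giving a stable-to-dynamic ratio near
0.4/0.6 ≈ 0.67; and the soil communities' stage separation is twice as
large at phylum as at ASV resolution — the planted phylum-level
convergence (κ = 0.5) — while compartment dominates the PERMANOVA
variance partition, as in real root-microbiota surveys.

Each artifact (rarefied tables, alpha/beta diversity, stability
partitions as JSON + tidy tables, convergence coordinates, the
covariation network as node/edge tables and GraphML) is written under
`demo_run/results/<kingdom>/`.

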