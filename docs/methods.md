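# Methods

This note documents the statistical procedures implemented in `microconet`,
the choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not establish.

## Design and data model

The package analyses a three-stratum paired design: controls (CTRL, one
sample each), patients at baseline (ERA-T0) and the same patients after
treatment (ERA-T1), paired by subject id. Counts are integer sample × taxon
matrices; clinical scores (e.g. DAS28, ESR, Treg/Th17 percentages) and
metabolite concentrations (short-chain fatty acids) enter as numeric
per-sample metadata. Counts are compositional: only relative information is
meaningful, which motivates the closure to relative abundances and the
simulation design below.

## Preprocessing

* **Rare-OTU filter** — a taxon is dropped when present in fewer than 2
  samples *or* carrying fewer than 10 reads in the whole cohort. The OR
  reading is the conservative one (removes more putative artifacts).
* **Rarefaction** — each sample is subsampled to 6,000 reads *without
  replacement* (a multivariate hypergeometric draw). With-replacement
  subsampling was rejected because it biases observed-richness counts.
  Samples under the depth are dropped and reported, not padded. The filter
  is applied before rarefaction by default; the order is configurable
  (`PipelineConfig.filter_before_rarefy`) since either convention is found
  in practice.

## Diversity

* Shannon is reported in **nats** (natural log) with a `base` parameter,
  since QIIME-lineage tools differ (log2 vs ln).
* Simpson is reported as **1 − D = 1 − Σ pᵢ²**, a probability in [0, 1]
  (larger = more diverse), matching the plotted convention of QIIME-style
  outputs.
* Unweighted UniFrac uses presence/absence only: shared branch length over
  spanned branch length, computed by a single postorder pass.
* PCoA performs classical scaling on the double-centred squared-distance
  matrix. Negative eigenvalues (possible for non-Euclidean dissimilarities)
  are reported but excluded from the percent-variance denominator, and no
  Lingoes/Cailliez correction is applied. Axis signs are fixed by making
  the largest-|coordinate| sample positive, so results are reproducible
  across platforms.
* PERMANOVA uses the distance-based sum-of-squares decomposition with
  `p = (1 + #{F* ≥ F}) / (n_perm + 1)` so p can never be zero; permutations
  are seed-reproducible. Default 1,000 permutations, so the smallest
  resolvable p is 1/1001.
* Rank tests use exact enumeration when the (nonzero) combined sample size
  is ≤ 12 with no ties, and the tie-corrected normal approximation
  otherwise; ties always receive average ranks. Zero paired differences are
  dropped with a warning; an all-zero vector is an error, not p = 1.

## Differential abundance

Taxa at ≥ 1% mean relative abundance in at least one stratum are tested:
Mann-Whitney U for CTRL vs ERA-T0 and CTRL vs ERA-T1, paired Wilcoxon for
T0 vs T1. BH-FDR is applied **within each contrast family** (the correction
scope was open; per-contrast is the least surprising for readers comparing
one contrast at a time), and both raw p and q are emitted. Relative
abundances are computed after rarefaction, consistent with the diversity
stage. Compositional DA methods (ANCOM/ALDEx2-style) are out of scope —
the pipeline is a rank-test design.

## Co-occurrence networks

Candidate edges per stratum are all pairs among screened species (mean
relative abundance ≥ 0.1% in ≥ 1 stratum) and all species × variable pairs.
An edge requires

1. `|ρ| > 0.6` (species-species) or `|ρ| > 0.5` (species-variable), read as
   **strict** inequalities, and
2. bootstrap p ≤ 0.05 with B = 1000.

**Bootstrap definition.** The literature the thresholds come from does not
pin down the bootstrap statistic, so the package uses the *sign-stability*
bootstrap common in co-occurrence practice: B paired resamples with
replacement, ρ* per resample, `p = 2·min(#{ρ* ≤ 0}, #{ρ* ≥ 0})/B` capped at
1 — equivalently, does the bootstrap distribution of ρ* stay on one side of
zero. Degenerate resamples (zero rank variance) are redrawn up to a retry
cap. A permutation-null alternative is available via
`bootstrap="permutation"`. The bootstrap is only computed for pairs already
passing the |ρ| threshold; other pairs can never become edges, so their
p is reported as NaN in the candidate table.

**Nodes.** Screened species are retained as nodes even when isolated
(configurable); variables appear only when they have at least one edge.

**Topology descriptors.** `edges`, `synergisms`, `exclusions` and
`edges_per_node` count species-species edges only; `avg_neighbors` is the
mean total degree *including* species-variable edges. This split is what
makes the two families of published descriptor internally consistent
(2·edges/nodes ≠ avg-neighbors unless variable edges count toward the
latter). `edges = synergisms + exclusions` is enforced as a construction
invariant. Printed values round to two decimals next to full precision.

**Modules.** The GLay community-detection plugin is Cytoscape-only; greedy
modularity maximisation (networkx, |ρ| weights) substitutes for it on the
positive-edge subgraph, keeping the ≥ 4-node reporting rule. Lexicographic
node insertion makes the partition deterministic.

**Hubs.** The "degree-based approach" of the source literature is not fully
specified; the rule adopted is total degree ≥ mean + 1 SD of the network's
degree distribution (species-species and species-variable edges both
counted). When all degrees are equal (SD = 0) there are no hubs, with a
warning. The rule is a parameter of `detect_hubs`, not a constant baked in.

**Betweenness** is unnormalised shortest-path betweenness on the unweighted
skeleton.

The model/results split follows statsmodels: `CooccurrenceModel(...)` holds
data and tuning parameters, `fit()` returns `CooccurrenceResults` carrying
the validated network, the full candidate-correlation table, and
`topology()/modules()/hubs()/betweenness()/summary()`.

## Synthetic cohorts

`generate_cohort` draws counts by a **logistic-normal–multinomial** scheme:
latent Gaussian log-abundances with a planted block correlation matrix
(checked positive semidefinite before sampling), softmax to a composition,
multinomial read sampling at a depth drawn uniformly in 8,000–20,000 (so
rarefaction at 6,000 is always exercised). A Dirichlet-multinomial cannot
encode arbitrary planted correlations, hence the logistic-normal choice.

Parameters of the stated world and their defaults:

| parameter | default | meaning |
|---|---|---|
| `n_ctrl`, `n_era` | 20, 19 | controls; patients with T0 and T1 each |
| `n_taxa` | 150 | OTUs in the community |
| `modules` | 6 taxa at ρ=0.85; 5 at ρ=0.75 | planted co-occurrence blocks |
| `diversity_deficit` | 0.5 | ERA-T0 latent mean is sharpened by ×1.5 |
| `restoration` | 0.7 | convex weight toward the control state at T1 |
| `module_mu` | 2.0 | elevated log-mean of module taxa (≈1.5% abundance) |
| `sigma` | 1.0 | latent log-abundance SD |
| `depth_range` | (8000, 20000) | uniform sequencing depth |
| `era_log_shift` | {} | per-taxon log-mean shift in patients |

The baseline **diversity deficit** is implemented as a temperature
sharpening of the patient latent mean (multiplying the log-abundance means
by 1 + deficit concentrates the softmax composition, lowering expected
Shannon/Simpson). The study being emulated reports the deficit as
significant at n ≈ 20 but does not quantify it; 0.5 was chosen once to make
it reliably detectable at that sample size and is config-exposed.
**Restoration** is modelled per subject — the T1 latent state is
`(1−r)·z(T0) + r·z(control-like)` — preserving the paired structure the
Wilcoxon tests rely on. **Variables** are noisy linear functions of the
standardised latent mean of a linked module (default: a disease-activity
score coupled negatively to module 1, a Treg percentage positively to
module 2) and the metabolite `propionic_acid` is additionally depressed by
40% in patients at both timepoints. Planted-module taxa receive an elevated
baseline (≈ 1.5% mean relative abundance) so that multinomial counting
noise does not destroy rank information — mirroring the real screen, which
only admits species above 0.1% abundance into networks.

`generate_tree` builds a random coalescent-style ultrametric tree
(exponential waiting times, random pair merges) purely as a UniFrac input.

**What the generator does *not* emulate:** taxonomic misassignment,
chimeras, read-level error, overdispersion beyond the logistic-normal,
zero-inflation beyond multinomial sampling, and any real phylogenetic
signal in the planted correlation structure. A green recovery test
therefore establishes that the inference machinery recovers the stated
latent structure under idealised compositional noise — not that it would
recover it from real 16S data.

## Numerical and degenerate-input conventions

* Spearman with zero rank variance is NaN with a warning, never an edge.
* Exact-test paths require no ties; discrete data silently falls back to
  the tie-corrected approximation.
* Rarefaction errors out when no sample reaches the depth.
* PCoA eigenvalues below `1e-10·|λ₁|` are treated as zero.
* All stochastic steps (rarefaction, bootstrap, permutations, simulation)
  take explicit integer seeds; the pipeline derives per-stage seeds from
  one master seed, so reruns are byte-identical.

## Known limitations

* Spearman co-occurrence on relative abundances is subject to
  compositional closure bias; SparCC/SPIEC-EASI-style corrections are
  deliberately out of scope (the pipeline reproduces a rank-correlation
  design). The null-calibration tests bound the practical false-edge rate
  under the simulated world (≤ 2% per pair at n = 20), not under arbitrary
  real communities.
* PERMANOVA assumes exchangeability under the null; with the paired T0/T1
  strata it is only applied to between-subject contrasts.
* The sign-stability bootstrap p is granular at 2/B and slightly
  conservative for |ρ| near the threshold at small n.
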