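# microconet

Analysis toolkit for paired case-control gut-microbiome studies: from a
sample × taxon count table plus clinical and metabolite metadata to
α/β-diversity comparisons, nonparametric differential abundance, and
bootstrap-validated Spearman co-occurrence networks with module, hub and
topology summaries.

The intended user is a microbiome bioinformatician analysing a three-stratum
design — healthy controls sampled once (CTRL), patients at baseline (T0) and
the same patients after treatment (T1) — and asking (i) whether the patient
microbiota is less diverse and compositionally distinct at baseline, (ii)
which taxa differ, (iii) how the *interaction structure* of the community
(who co-occurs with whom, and with which clinical variables) differs between
strata, and (iv) whether treatment restores it.

## Methods at a glance

**Preprocessing.** Taxa present in < 2 samples or with < 10 reads total are
removed as artifacts; samples are rarefied (uniform subsampling without
replacement) to a common depth of 6,000 reads; compositions are closed to
relative abundances.

**Diversity.** Per sample, Shannon `H = -Σ pᵢ ln pᵢ`, Simpson `1 - Σ pᵢ²`
and observed richness; between samples, Bray-Curtis dissimilarity and
unweighted (presence/absence) UniFrac on a phylogeny. Ordination is
classical PCoA; group separation is tested by PERMANOVA with 1,000 label
permutations, and the paired baseline→endpoint shift by a Wilcoxon
signed-rank test on the first principal coordinate.

**Differential abundance.** Taxa at ≥ 1% mean relative abundance in at least
one stratum are compared by Mann-Whitney U (CTRL vs patients) and paired
Wilcoxon (T0 vs T1), with Benjamini-Hochberg FDR within each contrast.

**Co-occurrence networks** (the core). Per stratum, every pair of screened
species (≥ 0.1% mean abundance in some stratum) and every species × variable
pair is scored by Spearman rank correlation ρ. An edge requires
`|ρ| > 0.6` (species-species) or `|ρ| > 0.5` (species-variable) *and* a
sign-stability bootstrap p ≤ 0.05 over B = 1000 paired resamples. Positive
edges are synergisms, negative ones exclusions. The fitted graph yields
topology descriptors (nodes, edges, edges/node, synergism/exclusion ratio,
mean neighborhood size), positively-connected modules (greedy modularity,
clusters of ≥ 4 nodes), degree-based hubs (degree ≥ mean + 1 SD) and
betweenness centrality, and exports SIF/GraphML for Cytoscape.

**Synthetic cohorts.** `microconet.cohort` simulates the whole design with
planted ground truth (logistic-normal–multinomial counts with
block-correlated latent log-abundances, a baseline diversity deficit
partially restored at T1, coupled clinical/metabolite variables), so every
inferential claim of the pipeline can be validated by recovery and null
calibration tests. See `docs/methods.md`.

## Worked example

```python
from microconet import (CohortSpec, generate_cohort, filter_rare_otus, rarefy,
                        to_relative_abundance, alpha_diversity, bray_curtis,
                        permanova, build_network)
from microconet.io import CountTable, strata, variable_columns

data = generate_cohort(CohortSpec(), seed=42)          # 20 CTRL + 19 patients x 2
table = rarefy(filter_rare_otus(data.table), depth=6000, seed=1).table
alpha = alpha_diversity(table)
groups = strata(data.meta)
print({g: round(alpha.loc[idx, "shannon"].mean(), 3) for g, idx in groups.items()})

idx = groups["CTRL"].union(groups["ERA-T0"])
dm = bray_curtis(CountTable(table.data.loc[idx]))
res = permanova(dm, data.meta.loc[idx, "group"], n_perm=1000, seed=2)
print(f"PERMANOVA CTRL vs ERA-T0: pseudo-F = {res.pseudo_f:.2f}, p = {res.p_value:.4g}")

rel = to_relative_abundance(table)
vars_ = variable_columns(data.meta)
net = build_network(rel, data.meta, "CTRL", variables=data.meta[vars_],
                    variable_kinds={"propionic_acid": "metabolite"},
                    n_boot=1000, seed=3)
print(net.summary())
```

Output:

```
{'CTRL': 3.625, 'ERA-T0': 2.641, 'ERA-T1': 3.527}
PERMANOVA CTRL vs ERA-T0: pseudo-F = 5.12, p = 0.000999
Co-occurrence network: CTRL
  samples: 20, species screened: 114
  thresholds: |rho| > 0.6 (species-species), > 0.5 (species-variable), p_boot <= 0.05 (B = 1000)
  Nodes: 114
  Edges: 57
  Edges/node ratio: 0.5
  Synergisms: 44
  Exclusions: 13
  Syn/Escl ratio: 3.38
  Average number of neighbors: 1.23
  modules (>=4 nodes): 6
  hubs (degree >= mean+SD): DAS28, OTU_0000, OTU_0001, ...
```

Reading it: patients at baseline show a Shannon deficit (2.64 vs 3.63 nats)
largely restored after treatment (3.53); their composition separates from
controls (PERMANOVA p ≈ 0.001, the smallest value 1,000 permutations can
resolve); and the control network recovers the planted modules — the listed
hubs include all six members of the strongest planted module (OTU_0000–0005)
and the variables coupled to it.

## Command line

```sh
microconet simulate --out cohort/ --seed 7            # synthetic paired cohort
microconet rarefy   --counts cohort/counts.tsv --out rarefied.tsv --seed 1
microconet diversity --counts rarefied.tsv --metadata cohort/metadata.tsv \
    --tree cohort/tree.nwk --out div/ --seed 2
microconet daa      --counts rarefied.tsv --metadata cohort/metadata.tsv --out daa.tsv
microconet network  --counts rarefied.tsv --metadata cohort/metadata.tsv \
    --group CTRL --out net_ctrl --seed 3
microconet run      --config pipeline.json            # everything, with a manifest
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates a default cohort from the given seed and runs the complete
pipeline end to end (preprocessing, diversity and PERMANOVA, differential
abundance, the three stratum networks with B = 1000 bootstraps), then writes
the results JSON to the requested path.
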