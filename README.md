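# soilphylo

Phylogenetic community structure along edaphic gradients.

Amazonian terra-firme forests sit on a strong soil gradient: clayey soils
with high exchangeable base-cation concentration (Ca+K+Mg+Na, cmol(+)/kg)
versus loamy, cation-poor soils. Plant lineages respond to this gradient not
only in how many species they place at a site, but in *which branches of
their phylogeny* those species come from: habitat filtering concentrates
close relatives on the soils their clade is adapted to. `soilphylo` is a
pipeline for quantifying that structure from three inputs — a site × species
presence/absence matrix, a per-site soil table with a geological-formation
factor, and one or more rooted, dated phylogenies (a posterior sample in
Newick, one tree per line).

It is aimed at community ecologists and phylogeneticists who want the full
chain — metrics, null models, posterior-tree aggregation, ordination,
gradient regressions — reproducible from the shell or from Python, plus a
synthetic-data generator with known truth so every stage can be validated
offline.

## What it computes

**Alpha (per site), on presence/absence:**

- `S` — species richness;
- `PD` — Faith's phylogenetic diversity, root-excluded: total branch length
  of the minimal subtree spanning the community, with no edge above the
  community's MRCA counted (undefined for S < 2);
- `MPD` — mean pairwise patristic distance, `2/(S(S−1)) Σ_{i<j} d_ij`;
- `MNTD` — mean nearest-taxon distance, `1/S Σ_i min_{j≠i} d_ij`;
- `VPD` (Λ⁺) — variance of the `S(S−1)/2` pairwise distances (population
  variance over pairs). VPD is reported raw and never standardized.

**Standardized effect sizes.** `SES = (obs − mean_null)/sd_null`; negative =
phylogenetic clustering. For PD/MPD/MNTD the null is the *independent swap*
(random 2×2 checkerboard flips preserving every site's richness and every
species' occupancy; 999 null matrices per tree at full scale), run
separately for each tree of the posterior sample, with the per-site median
of SES across trees as the headline value.

**Beta (per site pair):** Sørensen dissimilarity `(b+c)/(2a+b+c)` and
PhyloSor, the proportion of branch length not shared between the two
communities' subtrees (pooled-pair MRCA rooting). `SES.PhyloSor` uses a
*tip-shuffle* null: the community matrix is fixed and each tree's tip labels
are permuted (10 shuffles × 100 trees = 1000 pooled null values per pair at
full scale), with pairs tagged within/between geological formation.

**Gradient analysis:** PCoA of either dissimilarity matrix (Gower double
centering, negative eigenvalues reported, not corrected) with Pearson
correlation arrows for soil variables, and linear + quadratic OLS
regressions of any metric on log10 base-cation concentration with adjusted
R² and the model F-test (`p < .05` display flag).

**Synthetic designs.** `soilphylo.synthetic.generate(scenario, seed)` builds
a 40-site survey (9 Solimões / 12 Içá / 19 terrace sites; stratum cation
means 7.59 / 0.16 / 0.37 cmol(+)/kg), a Yule phylogeny with evolved Gaussian
edaphic niches, Bernoulli niche-filtered communities
`P(presence) = p_max·exp(−(x−μ)²/2τ²)`, and a jittered posterior-like tree
sample. Scenarios: `fern_like` (rich-adapted majority, narrow niches),
`palm_like` (poor-adapted majority, broad niches), `clustered` (one young
clade filtered to poor soils), `neutral` (no gradient or phylogenetic
effect). Each dataset carries a full truth record and regenerates
byte-identically from its seed.

## Worked example

```bash
soilphylo all --scenario fern_like --seed 1 --n-trees 10 \
    --n-null-alpha 99 --n-null-beta 10 --out runs/fern
```

writes the dataset plus `alpha.tsv`, `ses_alpha.tsv`, `sorensen.csv`,
`phylosor.csv`, `ses_phylosor.tsv` (+ stratum summary), PCoA scores/arrows,
`regressions.tsv` and a JSON-lines run log into `runs/fern`. The same
pipeline as a narrative sequence lives in `analysis/01…06`; running them in
order prints, among other lines:

```
fern_like : mean S by formation Solimoes=37.2, Ica=11.7, Terrace=8.9
fern_like : median SES.MPD poor=-0.69 Solimoes=+0.40 (99 nulls x 10 trees)
fern_like  sorensen : axis1 26%, r(log10 cations, axis1) = +0.97
fern_like : S slope +15.4 (p=2.6e-13), significant at .05: ['S', 'SES.MPD']
palm_like : S slope -12.2 (p=2.1e-12), significant at .05: ['S']
neutral   : S slope +0.6 (p=0.56), significant at .05: []
```

i.e. the fern-like design yields richness increasing with soil cations and
phylogenetic clustering on the poor soils where its minority poor-adapted
lineages concentrate, the palm-like design the opposite richness trend, and
the neutral control neither — with the first PCoA axis of compositional
turnover tracking the cation gradient wherever a gradient was built in.

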