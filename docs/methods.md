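# Methods

## Metrics and conventions

All metrics are computed on presence/absence data; abundances are out of
scope. Distances are patristic (sums of branch lengths, in Ma), never node
counts, and nothing assumes ultrametric trees.

- **PD** is root-excluded: the spanning subtree of the community's species is
  rooted at their own MRCA and no edge above it is counted. A single-species
  community therefore has *undefined* PD (NaN), not 0 — the alternative
  fabricates diversity for S = 1 sites. MPD, MNTD and VPD are likewise NaN
  for S < 2, and missing values propagate explicitly (sites are dropped from
  regressions with a log entry, never zero-filled).
- **VPD (Λ⁺)** divides by the number of pairs S(S−1)/2 (population variance
  over the pair multiset), matching its definition as the average squared
  deviation of pairwise distinctness. It is insensitive to sampling effort
  and is deliberately never standardized against a null model; the pipeline
  refuses to compute SES.VPD.
- **PhyloSor** measures each community's branch-length total to the MRCA of
  the *pooled pair* of communities, so that
  `shared = BL_A + BL_B − BL_{A∪B}` is exact and non-negative and single-tip
  communities are well defined. This differs intentionally from the
  root-excluded PD used in the alpha metrics: with per-community MRCA
  rooting the shared-branch decomposition is ill-defined. On a star tree
  with equal tip branches PhyloSor reduces exactly to Sørensen.

Internally each tree is compiled once into a tips × edges boolean incidence
matrix with an edge-length vector; PD, cophenetic distances and PhyloSor are
set algebra on its columns, which is what makes 10⁵–10⁶ null-model metric
evaluations tractable in pure numpy.

## Null models and SES

- **Independent swap** (alpha metrics): repeated random 2×2 checkerboard
  flips, preserving all row and column sums. Effort is counted in
  *successful* swaps — default 1000 per null matrix, attempt cap
  100 × (rows × cols) — so chain mixing is comparable across matrix shapes;
  both knobs are configurable and logged. A matrix with no checkerboard is
  returned unchanged with one warning. The species pool is all taxa of the
  aligned matrix; subclade analyses are done by subsetting taxa and
  re-aligning before any null runs.
- **Tip shuffle** (beta): labels are permuted uniformly on a fixed topology
  with fixed branch lengths; the community matrix stays as observed.
- **SES** uses the sample standard deviation of the null replicates
  (ddof = 1); cells with null sd = 0 or missing observed values are missing,
  with the degenerate case noted: two *identical* communities have PhyloSor
  0 under every relabeling, so their SES.PhyloSor is undefined rather than
  negative.
- **Cross-tree aggregation**: nulls are generated independently for every
  tree of the posterior sample (a `share_nulls` flag reuses one null set
  across trees as a documented speed-up with changed semantics). The
  per-site summary across trees is the median of the *standardized* values;
  the cross-tree median of the raw observed metric is reported alongside for
  median-of-raw analyses, since either reading of "median across the
  phylogenies" is defensible. The same median convention is applied to
  PhyloSor (configurable to mean).
- **RNG**: one master seed; per-tree/per-replicate streams derive from
  numpy `SeedSequence` spawning, and the numba swap kernel is seeded per
  null matrix, so outputs are byte-identical for identical config + seed
  regardless of evaluation order.

## Ordination and regression

PCoA eigendecomposes the double-centered −½D² (Gower). Negative eigenvalues
— expected for Sørensen-type input — are reported, not corrected (no
Cailliez/Lingoes), which is the common default and lets users judge the
distortion; requesting more axes than positive eigenvalues truncates with a
warning. Axis signs follow a fixed rule (largest-magnitude score positive)
for reproducible plots. Environmental arrows are plain Pearson correlations
of each (transformed) variable with axes 1–2.

Regressions use OLS with predictor x = log10(base cations) by default (raw
scale available, since the figure-level transform choice is not decidable
from the source material); the quadratic model is fit on centered x for
conditioning and coefficients are reported in the raw basis. Significance
for the display flag comes from the model F-test by default, with the
highest-order-coefficient t-test as an option. Quadratic R² ≥ linear R²
holds by construction on raw R²; adjusted R² may reverse.

## Synthetic designs

The generator reproduces the study layout this pipeline targets: 40 sites in
three geological strata (9 Solimões, 12 Içá, 19 terraces), with base-cation
concentrations log-normal per stratum. The log-normal is calibrated from a
printed mean and range: σ from the range read as a central 95% interval,
μ = ln(mean) − σ²/2 so the *arithmetic* mean is exact (7.59, 0.16,
0.37 cmol(+)/kg); the implied 95% intervals then approximate, rather than
reproduce, the printed ranges — the pair (mean, range) over-determines a
two-parameter family. Covariates (P, Al, pH) are noisy monotone functions of
the cation axis; they exercise the ordination arrows and carry no
independent truth.

Trees are pure-birth (Yule) — adequate for metric validation, where tree
shape realism is not the target — rescaled to an exact crown age (330 Ma /
140 tips for the fern-like pool, 106 Ma / 60 tips for the palm-like one,
100 Ma / 60 otherwise). Posterior-like samples multiply each branch by
i.i.d. log-normal noise with mean 1 and configurable CV (default 0.1),
topology fixed.

Niche optima μ on the log10-cation axis evolve by Brownian motion or by a
two-state poor/rich preference character (CTMC with rates q_pr, q_rp) with
state-conditional optimum distributions; communities assemble by independent
Bernoulli draws from `p_max·exp(−(x−μ)²/2τ²)`. Scenario parameters were
chosen so each preset *robustly realizes its stated design*, which is what
the qualitative tests consume (directions only, never magnitudes):

- `fern_like`: poor→rich transitions four times commoner than the reverse
  (q_pr = 0.012, q_rp = 0.003/Ma, poor root), narrow τ = 0.35, p_max = 0.4 —
  a majority rich-adapted pool with poor specialists concentrated in few
  lineages; richness rises with cations and single-formation specialists are
  commoner than in the palm preset.
- `palm_like`: majority poor-adapted pool (q_pr = 0.008, q_rp = 0.05, poor
  root — fast relaxation keeps the poor majority stable across seeds rather
  than hostage to one deep-branch event), broader τ = 0.6, p_max = 0.6;
  richness falls with cations.
- `clustered`: the youngest clade within 0.85–1.3× of 30% of the tips
  (clade age normalized by log size, the Yule scaling, so small clades are
  not systematically favoured) gets a tight poor-soil niche (μ ≈ −0.65,
  τ = 0.3, p_max = 0.8) against a background centred on richer soils
  (μ = 0.5, τ = 1.0, p_max = 0.3). Both choices matter: the
  occupancy-preserving swap null reabsorbs much of a clade signal, and with
  an old, loose clade or a diffuse background the poor-site SES.MPD sign is
  unstable across seeds.
- `neutral`: μ i.i.d. uniform on (−1.2, 1.2) with τ = 6, so presence
  probabilities are effectively flat across the gradient — the calibration
  control with no built-in effect.

What the generator does **not** emulate: real occupancy/abundance
distributions, spatial autocorrelation along the river, dispersal
limitation, dating uncertainty beyond branch jitter, or non-Yule tree shape.
Passing tests therefore demonstrate correctness of the *computations* and
direction-level recovery of built-in assembly signals — not that any real
fern or palm system behaves like the presets.

## Problem sizes and numerical choices

Interactive and test defaults are scaled down — 10 trees × 99 nulls, 40
sites, 60–140 taxa — with full-scale settings (100 trees, 999 swap nulls per
tree, 10 shuffles per tree) behind `--full-scale` and exercised for effort
accounting on reduced data. The SES calibration battery runs 20 sites × 199
nulls × 200 replicates. Metric-oracle comparisons use 50 random trees of ≤ 8
tips over every taxon subset against naive path/pair enumeration at 1e−10
relative tolerance; tiny negative variances and distances from floating
point are clipped at zero. Ties in the observed-vs-null quantile rank count
half.

## Known limitations

Sequential swap chains (no perfect/trial-swap sampling); no abundance
weighting; no turnover/nestedness partition of Sørensen; PCoA without
negative-eigenvalue correction; taxon merging is a manual pre-processing
utility (which taxa to merge is user input).
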