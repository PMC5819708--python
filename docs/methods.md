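# Methods

## Overview

`netheat` chains four statistical stages: rank-product differential
expression, insulated heat-diffusion module discovery on PPI networks,
hypergeometric functional filtering, and eigengene/Kendall phenotype
evaluation. Each stage is a pure function of its inputs and a derived seed,
so a full run is reproducible from the master seed alone.

## Differential expression

Unpaired contrasts build all n_A × n_B pairwise sample log-ratios; when
more than `max_pairs` (default 30) exist, a seeded subsample without
replacement is used. Paired contrasts use one per-subject post−pre
difference per subject, which keeps the comparison columns statistically
independent. Ranks use average tie-breaking; the rank product is the
geometric mean of ranks across comparisons, separately for the up and down
directions.

Permutation p-values shuffle each comparison's rank column independently
and pool the permuted rank products of all genes:
p = (1 + #{RP* ≤ RP}) / (1 + n_perm·G), so p > 0 always and
−log10 heat stays finite. Defaults: n_perm = 1000; both the permutation
count and the BH adjustment (rather than a pfp-style error rate) are
recorded in output headers.

Calibration notes, verified by simulation in the test suite:

- Under a paired pure-noise contrast the directional p-values are uniform
  (mean Kolmogorov–Smirnov distance ≈ 0.03 at G = 500, 200 permutations).
- The two-sided summary 2·min(p_up, p_down) is mildly anticonservative
  because the two directional p-values are not perfectly antithetic.
- For unpaired contrasts the pairwise comparisons share samples, which
  correlates the columns and fattens the null tail of the FDRs — a known
  property of the all-pairs rank-product recipe. The downstream module
  stage tolerates this: heat is a monotone transform of FDR, and the
  δ-calibration and permutation significance see the same tail under the
  null. It does mean isolated background genes can carry non-trivial heat,
  which is why module extraction, not per-gene thresholding, is the unit of
  inference.

## Heat diffusion and module extraction

Heat h = −log10(max(FDR, 1e−10)); the cap keeps heat finite when a
permutation FDR underflows. The diffusion operator F = β(I − (1−β)W)⁻¹ is
built by a dense solve after removing isolated nodes (W is
column-normalized adjacency; the system is strictly diagonally dominant for
β ∈ (0,1), so it cannot be singular). β defaults to 0.4, the standard
restart probability for PPI-scale networks; columns of F sum to 1 to within
1e−10 (heat conservation), which the tests check against both the analytic
identity and a truncated power-series evaluation.

The exchanged-heat matrix E = F·diag(h) is thresholded at δ; the strongly
connected components (scipy's compiled SCC, cross-checked against a
brute-force reachability oracle in tests) of size ≥ `min_size` (default 3)
are the modules.

**δ selection.** For each of `n_perm` (default 20) heat permutations we
find, by bisection over the sorted distinct entries of the permuted E, the
minimal δ at which the largest strong component has size ≤ `l_max`; δ is
the median of these minima. `l_max` defaults to `min_size` = 3: the null
components must be kept below the smallest reportable module size,
otherwise δ lands below the scale that separates concentrated heat from
background and adjacent hot neighborhoods merge. (Calibrating instead to
l_max ≈ 10 produced merged 20+-gene components in planted-module
simulations; l_max = 2 over-fragments. Both remain available in config.)

**Significance.** With δ fixed, each of `n_perm_sig` (default 100) heat
permutations is re-extracted and the number of components of size ≥ k is
compared with the observed count X_k for k = 2..k_max:
p_k = (1 + #{count*_k ≥ X_k}) / (1 + n_perm). A module of size s is
reported significant when p_k < 0.05 for some k ≤ s. Count statistics are
granular: with a single true module the test has ~80% power in simulations,
with several modules (the study regime) it is near-certain. Heat-label
permutation preserves topology; full network-permutation nulls are out of
scope for runtime reasons.

**Consensus.** Two genes are linked once per network whose significant
modules contain both; links present in ≥ ⌈n_nets/2⌉ networks survive and
connected components of size ≥ min_size become consensus modules, annotated
with their supporting networks.

## Functional filter

Over-representation only (enriched, not depleted, terms), hypergeometric
upper tail via scipy. The universe defaults to the genes present on the
harmonized networks — modules can only contain network genes — with a
config switch to the array-wide universe. BH runs per module across its
tested terms. A module passes iff some term has adjusted p < 0.05 and ≥ 2
module genes in the term. Terms come from the supplied GMT as-is; no
ontology-graph propagation.

## Evaluation

Module submatrices are standardized per gene (zero mean, unit variance
across samples; zero-variance genes dropped with a warning) before the
principal decomposition — intensities have gene-specific scales, so the
correlation-based decomposition weights genes equally. Eigengene signs are
fixed by aligning each component with the mean standardized module profile,
making orientation reproducible across runs. The first three components and
their variance fractions are reported.

Associations use Kendall tau-b with tie correction, pairwise-complete
deletion and the n used reported per row. The p-value is exact (scipy's
permutation recursion) for n < 10 without ties, otherwise the tie-corrected
normal approximation. The selection rule is the raw dual threshold
|ρ| ≥ 0.4 and p < 0.05; a BH-FDR column across the screen is reported for
transparency but does not gate selection. Disease-effect contrasts screen
per-sample values over the contrast's samples; training-effect contrasts
screen per-subject post−pre differentials of both eigengenes and phenotype
variables.

## Synthetic studies

The generator emulates the target study design: preferential-attachment
interactomes (heavy-tailed degree distribution), 15 + 12 subjects × two
timepoints, log2-scale Gaussian expression (baseline N(7, 1.5), subject
effect SD 0.3, residual SD 0.5), planted connected modules with additive
log2 effects, and phenotype variables that are monotone functions of module
activity plus noise whose SD is bisected (on a large calibration sample) to
hit a target population Kendall tau within ±0.02.

Presets: `disease-effect` (four COPD-specific modules of 6–10 genes, effect
2.0, couplings to VO2_peak and BODE_index at |tau| = 0.5),
`training-effect-healthy`, `training-effect-copd`, and `global-null`. Each
preset uses 1000 genes and three interactome variants (one base graph plus
two copies with 15% of non-module edges rewired, mimicking partially
overlapping curated PPI databases). These sizes keep a full pipeline run
around ten seconds while preserving the degree structure and group sizes of
a real training study.

Two realism constraints keep the planted truth identifiable: modules grow
avoiding the top-decile hubs (hubs belong to no single functional module),
and planted modules keep a one-edge buffer from each other — two adjacent
equally-hot modules are a single heat neighborhood that no diffusion method
could split, so they would be ill-posed ground truth.

What the generator does **not** model: probe-level artifacts, batch
effects, non-Gaussian intensity noise, correlated phenotype panels beyond
the specified couplings, or biased/incomplete interactome coverage. Passing
tests therefore demonstrate correctness and calibration of the chain under
its stated model, not performance on real microarray data.

## Numerical choices and degenerate inputs

- Probe→gene collapsing keeps the probe with the highest mean intensity;
  ties break lexicographically by probe id (deterministic).
- Dense linear solve for F; harmonized networks here are ≤ ~2·10⁴ nodes.
- δ bisection operates on the exact sorted distinct entries of E; when even
  the largest entry leaves an oversized component, the next float above it
  is returned.
- Empty networks, modules disjoint from all terms, all-constant modules and
  sub-minimum sample counts raise explicit errors or return empty results
  with warnings; see the per-function docstrings.
- Per-stage seeds derive from CRC32 of "master:stage-tag", so stages can be
  re-run in isolation and remain below 2³¹.

## Known limitations

- The unpaired rank-product null is anticonservative at the gene level (see
  above); per-gene FDRs from unpaired contrasts should not be interpreted
  as calibrated error rates — they are heat scores.
- Module significance is a count test over component sizes; it is weak for
  single small modules on small dense graphs.
- The consensus rule is topology-free (co-membership voting); it does not
  re-diffuse on a merged network.
- No edge weights, directed interactions, or alternative module algorithms.
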