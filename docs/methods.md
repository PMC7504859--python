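# Methods

This note documents the statistical models implemented in `coexrewire`,
the choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and known limitations.

## Data model

An analysis compares exactly two sample groups of one expression matrix
(genes × samples, real-valued, no missing cells). The design file declares
which condition is the **baseline** (condition 1), so "decreased" always
means baseline → perturbed. Each condition needs ≥ 3 samples; Pearson
correlation on fewer is meaningless. Missing values are rejected at load
time rather than imputed — every downstream statistic assumes complete
pairs. Transcript-level matrices are collapsed to genes by keeping the
transcript with the maximum cross-sample median (ties: first in file
order). Low-expression genes are removed by a cross-sample-median
percentile filter (upper-interpolation empirical quantile, strict-below
removal; 0.25 is typical for microarray, 0.50 for RNA-seq). Note that an
empirical percentile filter is *not* idempotent on distinct values: the
kept top half again has a lower half. Apply it once, to the raw matrix.

## Pathway compendium

Gene sets from several curated sources are reduced to a low-redundancy
compendium in three deterministic steps:

1. **Name merging.** Identically named sets (case-insensitive,
   whitespace-normalized) are merged: the largest set is the base, and each
   other member (visited in decreasing size) contributes its extra genes
   only if it already shares > 70% of its genes with the current base;
   otherwise it is dropped. All qualifying secondaries contribute, not just
   the first — merging is monotone in evidence.
2. **Overlap ablation.** Scanning in decreasing size (ties by name), the
   smaller of any pair with |intersection| / |smaller| > 0.70 is discarded.
   The denominator is the smaller set — the discard rule targets sets that
   are mostly contained in a larger one, and the bound is scale-free.
   Equal-sized pairs treat the lexicographically later name as "smaller",
   making the result independent of input order.
3. **Restriction and bounds.** Sets are intersected with the measured genes
   and kept only at sizes within [5, 250]; the lower bound keeps the
   eigenvector weights meaningful, the upper bound excludes near-genome
   "pathways" that would swamp the crosstalk population.

## DCL calling (limit fold change)

The link universe is selected at a per-condition density ρ = 0.1: the
cutoff t_c is the (1 − ρ) empirical quantile of all pairwise |r| (upper
interpolation, so quantile ties are included and realized density is ≥
target), and a pair is a link if it passes in *either* condition — a link
that exists in only one condition is exactly the interesting case.

Same-signed links get `x = max(|r₁|,|r₂|)` and
`fold = x / max(min(|r₁|,|r₂|), 1e-4)`. Pairs are split into B equal-count
bins by x (B = ⌈n/50⌉ capped to [1, 20]); within each bin the top-q folds
(q = 0.1 a priori) mark the selection boundary, and the per-bin boundary
cutoffs (largest unselected fold, at the bin's median x) are fitted with a
power law `y = a·xᵇ` by least squares in log space. A pair is a DCL iff
its fold strictly exceeds the fitted envelope (clipped at ≥ 1, so an
equal-magnitude pair can never be selected). With one usable bin the
envelope degenerates to that bin's constant cutoff, which makes the small-n
behavior a plain top-⌈q·n⌉ selection — the oracle used in tests. The
magnitude stratification exists because the fold statistic explodes as
min(|r|) → 0; binning forces strong and weak pairs to compete separately.

Sign-switching pairs are DCLs directly when both |r₁| ≥ t₁ and |r₂| ≥ t₂;
sign-switch pairs below the dual cutoff are not DCLs at all (they do not
enter the LFC route). This is a consequential choice: a pair moving from
+0.5 to −0.05 is excluded even though it plainly decohered. It is kept
because the fold statistic is not meaningful across a sign change, but see
*Limitations* — it halves the detection rate for planted decoherence whose
perturbed correlation is symmetric noise around zero.

DCGs: for a gene with k incident links and d incident DCLs,
`p = P(X ≥ d)`, `X ~ Binomial(k, π)` with π the global DCL fraction of the
same link set; BH adjustment across tested genes; DCG iff q < 0.1. Genes
with no incident links are not tested.

## Pathway rewiring test

Within a pathway, `A = |r|` with zeroed diagonal; the weight vector is the
dominant eigenvector of A (power iteration, relative tolerance 1e−10, ≤
10⁴ iterations, Perron–Frobenius sign fix), scaled so Σw = pathway size.
The statistic is `d_obs = Σ|w₁ − w₂|`; significance is the add-one
estimator over label permutations preserving group sizes,
`p = (1 + #{d_perm ≥ d_obs}) / (1 + n_perm)`, so p ≥ 1/(n_perm+1). Each
pathway's permutation stream is seeded from the global seed plus a CRC32
of the pathway name: results are reproducible and pathway-parallelizable,
and adding a pathway never shifts another pathway's p-value.

Two properties worth knowing:

- The weights are scale-invariant (`A` and `cA` have the same dominant
  eigenvector). A perfectly uniform attenuation of an exchangeable block
  changes the correlation *level* but barely the weight *profile*; power
  against such attenuation comes from the noisier eigenvector at low ρ and
  from any non-exchangeable structure (e.g. a hub). With the generator's
  default planted hub the test rejects ρ 0.8 → 0.2 at p < 0.05 in ≈ 95% of
  replicates (15 genes, 50 samples/condition); without any hub this drops
  to ≈ 87%.
- Genes with zero variance in either condition are dropped per pathway
  (correlation undefined); a pathway reduced below 3 usable genes is
  skipped with a status flag and contributes p = 1 to meta-analysis.

The hub is the max-weight gene (ties: lexicographically smallest). The
wiring network is MST₁ ∪ MST₂ over distances 1 − |r| (Kruskal, ties broken
by (distance, gene_a, gene_b); MST₂ built on the complete graph minus
MST₁'s edges), giving 2(p−1) edges; for p = 3 only MST₁ exists.
Dissolution: over intra-pathway DCLs, decreased = {|r₂| < |r₁|} plus
sign-switches with |r₂| ≤ |r₁|; dissolved/consolidated by strict majority,
maintained on exact ties (a tolerance parameter exists, default 0) —
including the zero-DCL case, where the classifier simply has no evidence.

## Meta-analysis and focused pathways

Fisher's combined probability: `χ² = −2Σln pᵢ` against chi-square with 2k
df. Permutation p-values are never 0 (add-one estimator), so the statistic
is finite; a floor is applied defensively for externally supplied zeros.
Datasets that skipped a pathway contribute p = 1 — conservative, and it
keeps df constant across pathways. Focused pathways: per-dataset p < 0.01
in ≥ 2 datasets AND aggregate p < 0.01, ordered by aggregate p. The
per-dataset "significantly rewired" lists for overlap/reporting use a
looser p < 0.05 (configurable). List agreement uses the hypergeometric
upper tail `P(X ≥ k)`; top-k agreement scans k = 5, 10, …, 150 with ties
at rank k broken by pathway name.

## Hub dynamics

Constancy = fraction of focused pathways with hub₁ = hub₂. Retention is
bookkept **per gene** over all pathways: the denominator is the set of
distinct baseline hubs flagged DCG; a gene is retained if it is also the
perturbed-condition hub of at least one pathway it hubbed at baseline;
vanishing hubs are the rest. Two lower-tail permutation nulls
(`p = (1 + #{rate_perm ≤ rate_obs}) / (1 + n)`):

- **Label shuffling** recomputes hubs and DCGs on relabeled samples. The
  focused-pathway *identity* stays fixed — recomputing the focused rule
  per permutation would require nested permutation p-values.
- **Annotation shuffling** redraws every pathway's gene set uniformly from
  the measured universe (without replacement within a pathway, overlaps
  between pseudo-pathways allowed — the weakest reading that preserves the
  size profile); DCG calls are annotation-free and reused.

## Crosstalk

The scaffold is the set of correlation-decreased DCLs
(`decreased_positive` plus `diff_signed` with |r₂| < |r₁|). For a pathway
pair, shared genes are removed from both sides (a link inside the overlap
is not crosstalk); with A′, B′ the remaining sets, the observed count of
scaffold edges spanning A′×B′ is tested against a hypergeometric null:
population = all C(n, 2) pairs of the scaffold universe, successes = all
scaffold edges, draw = |A′|·|B′| slots. `P(X ≥ observed)`; raw p < 0.05 by
default (BH optional, off — consistent with reporting raw crosstalk maps).
The all-pairs population (rather than scaffold-touching genes only) is the
default; it is the natural exchangeability null for "edges land uniformly
among pair slots" and is closed-form. Simulated type-I error at 0.05 on
random scaffolds is ≈ 0.03 (discreteness makes the test conservative).

## Synthetic data generator

The generator emulates the statistical regime the pipeline assumes —
*not* realistic RNA-seq counts. Per condition, samples are drawn from a
zero-mean multivariate normal whose correlation matrix has:

- within-pathway blocks at a class-specific ρ pair, e.g. attenuated
  (0.8 → 0.1) or null (constant) — defaults follow the regime the analysis
  targets: 15 genes/pathway, 50 samples/condition, unit marginal SD;
- a hub gene per block whose correlation to members is ρ + 0.2, capped at
  the closed-form positive-definiteness bound
  `h ≤ sqrt((1+(p−2)ρ)/(p−1))` minus a margin;
- optional cross-pathway couplings: a bipartite block of (default 3×2)
  non-hub genes at ρ_between. A literal "coupled genes correlate across
  pathways, zeros elsewhere" target has **no valid correlation matrix**
  once ρ_between exceeds ≈ 0.35: cross-correlation requires a shared
  latent factor. The generator therefore uses the factor-model completion
  — coupled genes also correlate among themselves at ρ_within + ρ_between
  — which is positive definite by construction and is what a latent-factor
  simulation would produce anyway;
- uncorrelated background genes.

Targets are repaired to the nearest positive-definite matrix by eigenvalue
clipping with diagonal renormalization; generation fails loudly if the
repair moves any entry by more than 0.02 — an infeasible stated world is
an error, not a silent approximation. Fixed seeds give byte-identical
output; `make_null_copy` reshuffles condition labels for type-I suites.

**What the generator does not emulate**, and hence what a green test does
not establish: real transcriptome correlations skew positive and attenuate
broadly across the transcriptome, not only inside annotated pathways.
Under the generator, cross-pathway pairs are sign-symmetric pure noise, so
the noise pairs admitted by the perturbed-condition density cutoff yield
direction-symmetric DCLs. Two consequences, measured at desk scale
(15 replicates, six attenuated 15-gene pathways, 50 samples/condition):

- the pooled decreased-positive DCL share plateaus near 0.70 (observed
  0.707), well short of the ≈ 0.85 dominance seen on real globally
  decohering data — the shortfall is exactly the noise-pair DCLs;
- detection power for a planted 3×2 decoherence (0.5 → 0) through the full
  DCL→scaffold→hypergeometric chain is ≈ 0.22 over 50 replicates: ~58% of
  planted pairs flip sign in the perturbed condition (excluded by the
  sign-switch rule) and only ≈ 21% survive to the scaffold, against 6
  possible slots.

Both are properties of the stated synthetic world and the frozen LFC
definition, not tunables; the corresponding acceptance checks are left
failing with this analysis rather than weakened. Planted-pathway
*dissolution* recovery (0.967) and hub recovery (1.00), by contrast, are
robust at desk scale.

## Numerical choices

- Pearson correlations via `numpy.corrcoef`; diagonals pinned to 1.
- Quantiles: upper interpolation ("higher") wherever a threshold must
  include ties on the kept side.
- Envelope fitting: `numpy.polyfit` on (log x, log y); bins with every
  pair selected contribute a floor cutoff of 1.
- Permutation estimators are add-one on both tails; p-values never 0.
- All RNG is `numpy.random.default_rng` seeded from the config; per-unit
  streams (pathway hash, scheme index) decouple parallel components.
- Matplotlib (Agg backend) only at the reporting edge; the analysis is
  headless.

## Limitations

- Pearson-only; no partial correlations, no soft thresholding.
- The sign-switch exclusion under-counts decoherence through zero; an LFC
  route for sign-switch pairs would be a natural extension.
- The crosstalk null ignores the scaffold's degree structure; a
  degree-preserving rewiring null would be stricter.
- Pooling designs, batch effects, and count noise are upstream of this
  package's model and must be handled before loading.
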