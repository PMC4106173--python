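# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `teamcross`. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Setting

Two heterotic groups of fully homozygous inbred lines are genotyped at
multiallelic SSR loci and crossed in an incomplete partial diallel; the
resulting single-cross hybrids are grown for grain yield (t·ha⁻¹) in
multi-environment trials laid out as incomplete blocks with two
replicates. The goal is to predict and rank all crosses the panel admits,
including the untested ones, and to quantify how far that predictive
ability transfers.

## Models

### Two-group diallel model

Plot yield is decomposed as

y = Xβ + Z₁a₁ + Z₂a₂ + Z₃d + Z₄i₁ + Z₅i₂ + Z₆w + ξ

where X carries the intercept, environments, replicates within
environments and blocks within replicates (all fixed; dummy coding with a
greedy full-rank reduction ordered environment → replicate → block, so
collinear trailing block columns are dropped); a₁/a₂ are group-wise
general combining abilities, d the cross-specific combining abilities,
i₁/i₂/w their environment interactions, and ξ ~ N(0, σ²I). All random
terms are homoscedastic with one variance each. With a single environment
the interaction terms are dropped (logged). A hybrid's genotypic value is
the BLUP sum GCA(parent1) + GCA(parent2) + SCA(cross).

Entry-mean heritability is computed at the trial's replication level:

h² = σ²_g / (σ²_g + σ²_g×E / E + σ² / (E·r)),

with σ²_g the sum of the three combining-ability components and σ²_g×E
the sum of their interaction components; E environments, r replicates.
This is the standard entry-mean basis; it is a choice (the quantity is
reported without a formula in most trial reports) and is isolated in one
function.

### TEAM marker model

The combining-ability designs are replaced by marker designs built from
parental genotypes:

* additive matrix A (hybrids × alleles): λ = 2 if both parents carry the
  allele, 1 if exactly one does, 0 otherwise. Per genotyped marker a row
  sums to exactly 2.
* dominance matrix Δ (hybrids × allele pairs): ϕ = 1 in the single column
  keyed by the unordered pair of parental alleles (a homozygous pair when
  the parents share the allele). Columns exist only for pairs realized in
  the cross set, so the dominance dimension k is cross-set dependent.
  Allele-pair keys are stored unordered — the underlying combination of
  parental gametes is symmetric.

TEAM1 fits y = Xβ + Aa + ξ; TEAM2 adds Δd. Each term has one common
variance (ridge-regression BLUP), and marker-by-environment interaction is
deliberately confounded with the residual: estimating an effect per
allele × environment cell is disproportionate to the information a trial
of this size carries, and the residual absorbs it at the cost of
inflating σ².

Any hybrid is predicted by α_i = A⁽ⁱ⁾a and δ_i = Δ⁽ⁱ⁾d. Allele pairs
absent from training have no estimated effect; they contribute the ridge
prior mean of zero and the per-hybrid `dominance_coverage` (fraction of
markers whose realized pair was trained) is reported so low-coverage
predictions can be filtered. Predictions are genetic values only; fixed
effects are excluded, making rankings invariant to environment means.

The marker-associated genetic variance is recovered as

σ²_a = (Σⱼ aⱼ² + tr(W_n⁻¹)·σ²) / n,  σ²_d = (Σⱼ dⱼ² + tr(W_k⁻¹)·σ²) / k,
σ²_g = n·σ²_a + k·σ²_d,

with W_n⁻¹, W_k⁻¹ the diagonal blocks of the inverse mixed-model
coefficient matrix belonging to the additive and dominance equations.

### Missing genotypes

A marker missing in either parent contributes nothing to that hybrid's
additive or dominance row and is excluded from the row-sum invariants.

## Estimation

### Mixed-model equations

For fixed variance components the Henderson equations are solved after
absorbing the fixed effects: û solves (Z'MZ + Λ)û = Z'My with
M = I − X(X'X)⁻¹X' and Λ the diagonal of ratios λ_u = σ²/σ²_u; β̂ follows
by back-substitution. The same factorization yields the diagonal blocks
of the inverse coefficient matrix (needed for the EM traces and the
marker-variance recovery) and the restricted log-likelihood.

Two algebraically equivalent backends exist. The `direct` backend
factorizes the (q × q) absorbed system. The `cells` backend exploits that
every random design in these models is constant within
(hybrid, environment) cells: with cell incidence P and cell covariance
H = Σ_u σ²_u Zc_u Zc_u', the phenotypic covariance is V = σ²I + PHP' and
Woodbury identities reduce every quantity — BLUEs, BLUPs, block traces,
log-likelihood — to (C × C) factorizations, where C is the number of
cells (58 hybrids × 7 environments = 406 for the diallel model; 58 for
TEAM models, whose designs do not vary within hybrid). Since q reaches
~850 (diallel) to ~2700 (TEAM2) while C ≤ 406, this is roughly
(q/C)³-fold cheaper per iteration. `method="auto"` chooses by size; the
test suite verifies both backends agree to ~1e-8 and match an independent
V-inverse GLS oracle.

### EM-REML

Variance components are estimated by expectation-maximization REML:

σ²_u ← (û_u'û_u + σ²·tr(C^{uu})) / q_u
σ²  ← (ê'ê + σ²·[(p + q) − Σ_u λ_u·tr(C^{uu})]) / N

where C^{uu} is the u-th diagonal block of the inverse coefficient matrix,
p = rank(X), q = Σ q_u. The residual update is the exact EM M-step
(conditional expectation of e'e); the frequently quoted fixed-point form
σ² ← y'(y − Xβ̂ − Zû)/(N − p) shares the stationary point but can
overshoot in early iterations and transiently decrease the restricted
likelihood, which we observed on real instances. With the M-step form the
likelihood is non-decreasing, and `reml_em` asserts this at every
iteration as a self-check (a decrease raises, signalling an
implementation bug).

Numerical choices:

* initialization: every component at var(y)/(q_terms + 1);
* convergence: maximum relative change of any component < 1e-8
  (default), capped at 2000 iterations; a capped fit is returned flagged
  `converged=False` with a warning, never silently discarded. EM is
  sublinear when a component approaches zero, so caps are typically hit
  in exactly those runs; the affected component is then numerically
  negligible.
* variance floor 1e-10·var(y); components finishing at the floor are
  flagged and should be read as zero;
* the generalized residual sum y'(y − Xβ̂ − Zû) is evaluated through the
  identity ê'ê + û'Λû (two non-negative sums of squares) rather than by
  subtracting cross-products, which loses all precision when σ² is tiny;
* fixed-effect rank reduction is greedy in column order with one
  re-orthogonalization pass (tolerance 1e-8 on the residual norm).

## Synthetic data

The generator defines the study conditions under which everything is
tested; its defaults are fixed once:

* 27 + 24 lines, 79 markers; allele counts per locus drawn as
  2 + Binomial(18, p) with p chosen so the mean is 8.05 (range 2–20);
  each line draws one allele per locus uniformly from the locus pool —
  the allele-frequency spectrum of the real panel is unknown, uniform is
  the configurable assumption;
* 58 between-group crosses sampled uniformly without replacement from the
  648 admissible pairs;
* 7 environments × 2 replicates, one plot per hybrid per replicate,
  plots of a replicate partitioned at random into incomplete blocks of 10;
  fixed environment/replicate/block effects drawn once per simulation
  with spreads 1.0 / 0.25 / 0.25 t·ha⁻¹ (not reported for the real
  trials; chosen as typical multi-location spreads);
* generating variances (t²·ha⁻²): GCA₁ 0.055, GCA₂ 0.077, SCA 0.063;
  combining-ability × environment 0.225 + 0.225 + 0.23 (the reported
  GCA×E total split equally between groups); residual 0.136 (making the
  interaction total five times the residual, as reported); grand mean
  9.0 t·ha⁻¹, a realistic southern-Brazil maize trial mean;
* `diallel-truth` mode draws GCA/SCA effects directly — the generating
  model matches the diallel analysis, the right substrate for
  variance-component recovery;
* `marker-truth` mode draws one effect per allele column and per realized
  allele-pair column. Column variances are scaled (default
  `effect_scale="per-hybrid"`) by the average squared row loads so the
  realized per-hybrid genetic variance equals the preset total — this is
  what keeps simulated heritability at the study's magnitude. The
  alternative `effect_scale="index"` spreads the total as
  n·σ²_a + k·σ²_d = total (the scale of the recovery formula); because a
  hybrid carries only a small subset of the 636-odd allele columns, that
  convention leaves per-hybrid genetic variance an order of magnitude
  smaller than the preset and is not the default.
* genotype-by-environment effects are independent draws per
  (effect, environment) cell. `reuse_truth` re-grows the same genetic
  truth in new environments (fresh layout, G×E and residual draws),
  emulating a second-year regional assay; crosses absent from the first
  trial get fresh SCA draws (diallel-truth) or are composed from the
  same marker effects (marker-truth).

### What the generator does not emulate

* Linkage and recombination: lines are fixed homozygotes, and linkage
  groups are carried as labels only. Irrelevant for crossing homozygous
  parents, but the simulated loci are statistically independent, unlike
  real SSR panels with linked markers.
* Realistic allele-frequency spectra (real panels have few common and
  many rare alleles; uniform sampling makes alleles more even, which
  raises the realized allele count slightly and makes dominance pairs
  more dispersed).
* Year-structured G×E. Interaction draws are iid across *all*
  environments, so the genetic correlation between two independently
  grown trials of the same hybrids is 1 and their expected agreement is
  √(h²₁·h²₂) — close to h² itself. Real multi-year data can show
  agreement far below h² (rank changes between years); reproducing that
  would require a genotype-by-year variance component, which the
  generator deliberately does not include. Consequently, passing the
  cross-year degradation checks here demonstrates dilution by noise and
  finite training, not year-level rank reversal.

## Validation machinery

* **Jackknife CV**: per draw, all plots of k randomly chosen hybrids are
  removed, the TEAM model is refit on the remainder, and the removed
  hybrids' predicted genetic values are correlated with their observed
  values. "Observed" means fixed-effect-adjusted means: each held-out
  plot's environment/replicate/block estimate (from the refit, matched by
  column label; levels unseen in training contribute zero) is subtracted
  and the residuals averaged per hybrid. Monte-Carlo draws (seeded)
  rather than one fixed partition: distribution summaries need many
  draws, and 58 is not divisible by most k. When the number of distinct
  k-subsets is at most the requested draws the enumeration is exhaustive.
  Draws whose refit does not converge, or whose correlation is undefined,
  are skipped and logged — never imputed. Note that k = 2 yields
  degenerate two-point correlations (±1), and hybrids whose dominance
  pairs are untrained are structurally unpredictable even without noise;
  meaningful CV settings keep k ≥ 3 and training sets that identify the
  effects.
* **Correlation summaries**: mean, median, and mode as the argmax of a
  Gaussian kernel density (Silverman bandwidth) on a 512-point grid over
  [−1, 1]; a constant sample's mode is that constant.
* **Selection loss**: the top ⌈fraction·N⌉ (default 20%) by predicted and
  by observed ranking are compared; correct rate = share of
  observed-selected captured; wrong rate = share of predicted-selected
  that the observation discarded (the alternative denominator, observed
  discards, is also reported). Ties are broken by hybrid identifier,
  stable. By construction correct rate + missed rate = 1.
* **Per-parent fits**: within each parental family with at least 4
  crosses, a linear regression of observed on predicted measures
  line-specific credibility.
* **External validation**: regional plot yields are reduced to adjusted
  hybrid means (fixed effects estimated by OLS with hybrid dummies
  appended so hybrid contrasts are not absorbed), joined to predictions
  on hybrid identity, and compared by linear and quadratic R², Pearson
  correlation, and selection loss.

## Problem sizes used in tests and the acceptance script

The parameter-recovery experiment runs 50 replicates at the full
replication scale (51 lines, 58 crosses, 812 plots, ~850 random effects);
with the cell backend each EM fit takes seconds and the experiment a few
minutes on one CPU. Cross-validation and oracle tests use smaller panels
(6–30 hybrids, 5–12 loci) where exhaustive enumeration and dense-inverse
oracles are feasible; these sizes were chosen so every oracle comparison
is exact, and the full-scale behaviour is covered by the recovery and
external-validation experiments.

## Known limitations

* EM-REML convergence is slow near variance boundaries; the iteration cap
  governs runtime there and capped estimates of near-zero components
  remain slightly positive.
* The dominance design covers only training-realized allele pairs; for
  candidate sets far from the training crosses, predictions lean on the
  additive term (coverage is reported per hybrid).
* Heritability and adjusted means assume the entry-mean basis and
  homoscedastic residuals across environments.
* The Mantel test permutes one matrix whole; it does not stratify by
  heterotic group.
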