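# Methods

This note records the statistical conventions psychnet implements, the
choices made where several defensible options existed, and what the
synthetic-data validation does and does not establish.

## Estimation: nodewise EBIC-LASSO mixed graphical model

Each variable is regressed on all others.  Continuous targets use linear
least squares; categorical targets use multinomial logistic regression
with dummy-coded predictors (first declared level as reference).
Continuous predictors and continuous targets are z-scored within each
nodewise fit, so linear coefficients are standardized and comparable
across edges; dummy columns stay on their 0/1 scale.

The L1 path has `n_lambda` (default 100) log-spaced penalties from
`λ_max` — the smallest penalty giving an empty model, computed per node
from the null-model score equations — down to `λ_max × 10⁻³`.  Model
selection uses the extended BIC with `k log n + 2 γ k log p_cand`, where
`p_cand` counts predictor columns after dummy expansion and γ defaults to
0.25 (γ = 0 recovers BIC; the usual range is 0–0.5).

**Relaxed scoring.** The path is used only to propose supports.  Every
distinct support is refit without penalty (OLS, or unpenalized
multinomial logistic), and both the EBIC log-likelihood and the reported
coefficients come from the refit.  Two consequences motivated this
choice: selection no longer depends on how densely the λ grid samples
the region where a weak predictor enters, and reported edge weights are
free of shrinkage bias — on all-continuous data they estimate the
generating partial correlations directly, which is also what makes
percentile bootstrap intervals on edge weights approximately calibrated
(the test suite measures ~94% empirical coverage at a 95% nominal level).
A penalized-likelihood scoring variant would select slightly denser
models and carry downward-biased weights.

EBIC ties are broken toward the sparser model (largest λ).  `k` counts
regression coefficients only, not intercepts or the residual variance.

**Edge assembly.** Under the default AND rule an edge exists only if both
endpoints select each other; its weight is the mean of the two
per-neighbor aggregates (mean absolute coefficient over the neighbor's
dummy/class block).  The OR rule (available by flag) requires one
selection and averages the two aggregates including the zero.  For
continuous–continuous pairs the weight carries the shared sign of the two
coefficients; on a sign conflict (possible only in near-degenerate fits)
the edge is zeroed with a logged warning.  Edges with a categorical
endpoint have no meaningful sign: they are stored as magnitudes and
flagged `sign_defined = False`.

## Nonparanormal transform

Skewed continuous margins violate the Gaussian working assumption of the
linear nodewise fits.  The rank-based transform replaces x by
`s · Φ⁻¹(T_δ(F̂(x)))` with `F̂` the average-rank empirical CDF,
winsorization into `[δ_n, 1−δ_n]`, `δ_n = 1/(4 n^{1/4} √(π log n))`, and a
final rescale to unit sample SD.  By default columns with moment-ratio
|skewness| > 1 are transformed (`mode="skewed"`); `all` and `none` are
available.  The transform is monotone, tie-preserving, and idempotent up
to numerical tolerance.

## Centrality, bridges, pathways

Strength is `Σ|w|`; expected influence is the signed sum.  Bridge
variants restrict the sums to edges whose endpoints belong to different
communities (one questionnaire = one community, declared in the variable
spec).  Unsigned edges contribute their magnitude to the signed sums —
there is no sign to respect — which can diverge from implementations
that assume all edges are signed; the flag travels with the network so
the convention is auditable.

Shortest pathways default to Dijkstra on `d = 1/|w|` (strong conditional
association = short distance); a literal hop-count metric is available.
Equal-distance ties resolve to the lexicographically smallest node
sequence, making path reports deterministic.

Domain screening retains a factor domain if and only if its domain
network (symptoms + that domain) contains at least one nonzero
factor–symptom edge; the integrated models are built from retained
domains only.

## Bootstrap robustness

The case-dropping bootstrap subsamples without replacement at drop
proportions 0.05–0.75 (step 0.05 by default), re-estimates the network,
and correlates each centrality index with the full-sample values.  The
CS coefficient is the largest proportion p such that the empirical 5th
percentile of the correlations is ≥ 0.7 at every proportion up to p —
the "for all q ≤ p" guard prevents a non-contiguous pass region from
inflating the value.  Replicates with empty networks or constant index
vectors have undefined correlations; they count as 0 (a failure) and are
logged, a deliberately conservative convention.  Edge accuracy uses
full-size resamples with replacement and percentile 2.5/97.5 bounds,
zeros included when an edge is unselected.

Per-replicate seeds derive from `SeedSequence(master, spawn_key=(stage,
replicate))`, so results are reproducible bit-exactly and invariant to
execution order; replicates could run concurrently without changing any
number.

## Group contrasts

The medication-group severity contrast uses the tie-corrected
Kruskal–Wallis H referred to χ²(groups−1), with Dunn's z on pooled ranks
for pairwise follow-ups and Bonferroni adjustment over all pairs.  Dunn's
test was chosen over pairwise rank-sum tests because it reuses the pooled
ranking, keeping the post-hoc consistent with the omnibus statistic.

## Synthetic cohort generator

The generator exists so every stage can be checked against known truth:
patient questionnaire data of this kind are rarely shareable.

A latent vector is drawn from a multivariate normal whose precision
matrix encodes a chosen sparse graph: unit diagonal, off-diagonal
`−ρ_ij` for each planted partial correlation, positive-definiteness
checked at construction.  Each coordinate then passes through a monotone
discretization `clip(round(a·z + b))` onto its integer scale; `(a, b)`
are solved per variable so the discrete mean and SD hit their targets
(mean prioritized; solver tolerance |mean error| < 0.05).  Because the
maps are monotone, the latent conditional-independence structure is
exactly what a rank-aware estimator should recover.

The `paper_like` preset emulates a depressed-patient cohort of n = 791:
seven insomnia items (0–4), personality, interpersonal-distress,
childhood-trauma and social-support subscale totals, two
depression-severity totals, age, plus gender and medication-group
categorical covariates.  Margins are calibrated to published cohort
descriptives (insomnia total 10.99 ± 6.49 with 67% at or above the
cutoff of 8, neuroticism 18.16 ± 4.66, severity-17 17.51 ± 7.47, age
22.06 ± 4.72, 75.9% female).  Subscale totals are generated directly as
discretized latents; only the insomnia items are item-level.  The
planted graph echoes the qualitative structure such cohorts show —
strong within-insomnia edges, a neuroticism bridge into the insomnia
community, weak single-symptom edges from distress and support, no
trauma–insomnia edges, and a medication→severity shift applied on the
latent scale (group offsets probability-weighted to ≈0 so the severity
margin stays calibrated).  The within-insomnia base partial correlation
(0.11) was fixed once so the insomnia-total SD lands near its target
under discretization.  This preset is a demonstration and validation
aid; it makes no claim to reproduce any study's fitted edge weights.

`chain` (three unit normals, partials 0.3 on 1–2 and 2–3) and
`independent` (six unit normals) are the recovery and null benchmarks.

**What passing tests show — and don't.** The copula cohort has exactly
Gaussian latents, exactly monotone margins, complete cases, and
homogeneous participants.  Real questionnaire data add measurement
error, differential item functioning, floor effects beyond what the
margins encode, and missingness.  Recovery and coverage results here
validate the machinery, not the substantive correctness of any network
estimated from real data.

## Numerical conventions and degenerate inputs

- SD uses the n−1 denominator; skewness is m₃/m₂^1.5; kurtosis is the
  non-excess m₄/m₂² (normal → 3), matching the conventions of the cohort
  tables the generator is calibrated to.
- Constant columns, out-of-range cells, undeclared category codes and
  non-numeric cells are fatal, typed errors — never coerced.  Missing
  rows are removed listwise with a logged count (the complete-case
  convention); no imputation is offered.
- Logistic non-convergence or separation aborts the fit naming the node.
- Networks are exactly symmetric with zero diagonal by construction;
  every reported edge passes the AND-rule audit (both nodewise
  aggregates nonzero).

## Problem sizes used in validation

The test suite exercises: oracle equivalence on 2,000 random graphs of
≤ 7 nodes; chain recovery at n = 2000 over 20 seeds; CI coverage over 50
datasets at n = 1000 with 200 resamples; stability at 100 replicates per
drop proportion.  These sizes make the full suite run in a few minutes
on one core while keeping Monte-Carlo error well inside the asserted
margins.

## Known limitations

- Only Gaussian and categorical node types; no Poisson/Ising nodes and
  no moderated (three-way) interactions.
- The OR-rule weight convention (average including the zero) halves
  single-sided aggregates; comparisons across rules should use the same
  rule throughout.
- The case-dropping bootstrap re-estimates the full network per
  replicate; with many nodes and the default 1000 replicates this is the
  dominant cost.  Reduce the grid or replicate count for exploratory
  runs.
- Bridge indices are 1-step only.
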