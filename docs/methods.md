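# Methods

This document records the statistical model behind `speechnet`, the
estimator and algorithmic details, the defaults and why they were chosen,
what the synthetic generators do and do not emulate, and known limitations.

## 1. Model

Let x ∈ ℝᵖ collect the per-subject features (linguistic, psychopathological,
cognitive). We model x as multivariate Gaussian with precision matrix
Θ = Σ⁻¹. In a Gaussian graphical model (GGM), θᵢⱼ = 0 exactly when xᵢ and
xⱼ are conditionally independent given all other variables, so the support
of Θ is an undirected conditional-independence graph. Edge weights are
partial correlations

ρᵢⱼ·rest = −θᵢⱼ / √(θᵢᵢ θⱼⱼ),

which lie in (−1, 1), vanish with θᵢⱼ, and carry the sign of the direct
association.

Assumptions this inherits: joint Gaussianity (features are z-standardised
first, which fixes location/scale but not shape), i.i.d. subjects within a
group, and a single shared graph per group. Deviations (skewed ratios,
floor effects in symptom scores) distort edge weights; the group-difference
machinery is permutation-based and so keeps its validity under exchangeable
nulls even when Gaussianity is imperfect.

## 2. Estimation

### 2.1 Graphical lasso

Θ̂ maximises the ℓ₁-penalised Gaussian log-likelihood
log det Θ − tr(SΘ) − λ‖Θ‖₁,off, with S the sample correlation matrix and
the diagonal unpenalised. The solver (`speechnet._glasso`) is the standard
block coordinate descent in the covariance parameterisation: each column is
updated by an inner lasso regression; Θ̂ is recovered from the regression
coefficients, so coefficients that the inner lasso sets to zero yield
*exact* zeros in Θ̂ (edge counts need no thresholding). Convergence is
declared when the mean absolute change of the off-diagonal working
covariance falls below `tol` × mean |S_offdiag| (`tol = 1e-7` for
standalone fits). Kernels are numba-compiled; a full 100-λ path at p = 8
runs in about a millisecond, which is what makes the permutation and
bootstrap layers affordable.

The implementation is verified two ways: against
`sklearn.covariance.graphical_lasso` as an independent oracle on random
problems, and against the p = 2 closed form, where the solution is exactly
the soft-threshold sign(s)·max(|s| − λ, 0) on the correlation; the latter
agrees to machine precision (see `scripts/acceptance.py`).

### 2.2 EBIC model selection ("EBICglasso")

λ is selected by the extended Bayesian information criterion

EBIC(λ) = −2L(Θ̂λ) + E log n + 4 E γ log p,

with L = (n/2)(log det Θ̂ − tr(SΘ̂)) and E the number of nonzero
off-diagonal pairs. Defaults: γ = 0.5 (the conventional conservative
choice; γ = 0 reduces to BIC and yields denser graphs), a log-spaced grid
of 100 λ values from λ_max = max |S_offdiag| (the empty graph) down to
0.01·λ_max, descending with warm starts. Ties are broken toward larger λ,
i.e. the sparser model.

At study scale (planted random graph, p = 10, chain, partial correlation
0.3, n = 2000), EBICglasso recovers the planted edge set with mean
sensitivity and specificity both above 0.9 over 20 replicates
(`tests/test_acceptance.py`).

### 2.3 Missing data

Features that are undefined for a subject (e.g. noun/verb ratio with zero
verbs) are NaN. Correlation uses listwise deletion by default; pairwise
deletion is available but can produce an indefinite matrix, which is then
repaired by the smallest diagonal ridge that restores positive
definiteness (and flagged in metadata).

## 3. Stability: bootstrap and pruning

`bootstrap_edge_intervals` resamples subjects with replacement B times
(default 1000), re-runs the *entire* estimation (correlation → λ selection
→ partial correlations) per resample, and reports percentile intervals
(default 95%). Resamples with a zero-variance column are redrawn (up to
10·B attempts, counted in the result). `prune_edges` removes edges whose
interval covers zero — a conservative display rule, not a formal test.

**Coverage caveat (measured, by design).** Percentile intervals of an
ℓ₁-penalised estimator are centred on a *shrunken* quantity. In a
calibration experiment (chain GGM, p = 6, planted partial correlation 0.4,
n = 400, B = 200, 200 replicates) the mean estimate at a true edge was
≈ 0.37 and interval coverage of the *true* value was 0.805, while coverage
of the estimator's own finite-sample mean was 0.97 — consistent with
nominal once the shrinkage bias is accounted for. The test suite therefore
asserts calibration with respect to the estimator's sampling distribution
and separately asserts that the shrinkage bias is present
(`tests/test_stability.py::test_sampling_calibration`). Bootstrap
intervals here quantify *stability*, not unbiased uncertainty about the
population partial correlation; this matches how such intervals are used
in the applied network literature.

## 4. Centrality and edge structure

Shortest-path metrics use edge lengths 1/|wᵢⱼ| (stronger edges are
shorter). Betweenness is Brandes' unnormalised count of geodesics through
a node; closeness is 1/Σ d(u, v) over reachable nodes (0 for isolated
nodes); strength is Σⱼ |wᵢⱼ|; expected influence is the signed sum Σⱼ wᵢⱼ.
Implementations sit on networkx and are verified against an exhaustive
path-enumeration oracle for p ≤ 7 and hand-computed fixtures (a 3-node
path with weights 0.5 gives center closeness 1/4 and betweenness 1).
`classify_edges` counts within-domain vs cross-domain edges from the node
domain labels.

## 5. Group comparison

### 5.1 Network Comparison Test (NCT)

For groups a, b with estimated (unpruned) weight matrices W_a, W_b:

- **M** = maxᵢⱼ |W_a − W_b| (edge-difference statistic),
- **S** = |Σ|W_a| − Σ|W_b|| (global strength difference),
- edgewise statistics |ΔWᵢⱼ| for every edge nonzero in at least one
  observed network; Bonferroni correction uses that count as m.

The null distribution comes from permuting group labels: pooled rows are
canonicalised by lexicographic sort, the first min(n_a, n_b) permuted rows
form one group, making every statistic exactly symmetric in the group
order even with unequal sizes. Each permutation re-runs the full
EBICglasso estimation. P-values use the add-one estimator
(1 + #{perm ≥ obs}) / (1 + n_perm), so they are never zero and never
understate uncertainty. Defaults: 1000 permutations, γ = 0.5.

Calibration: under an exact null (both groups drawn from the same chain
GGM, p = 8, n = 300 per group, 250 permutations, 200 replicates) the
measured type-I error of M at α = .05 is ≈ 0.03–0.04, inside the
acceptance band [0.01, 0.10]. Power: a single precision entry perturbed by
0.45 at n = 500 per group is detected in ≥ 80% of replicates
(`tests/test_comparison.py`).

`frobenius_distance` (ℓ₂ norm of upper-triangle weight differences) is a
descriptive complement; it satisfies the metric axioms and is reported per
contrast by the pipeline.

### 5.2 Classical group statistics

`speechnet.groupstats` provides one-way ANOVA with η² (hand-computed sum of
squares, F p-value from scipy), Kruskal–Wallis, and Cramér's V (without
Yates correction, so V = 1 for a perfect 2×2 association). `choose_test`
switches to Kruskal–Wallis when any group fails Shapiro–Wilk normality or
Levene homoscedasticity at α = .05; post-hoc pairwise tests are
Bonferroni-corrected.

## 6. Linguistic features

Countable tokens exclude UPOS `PUNCT`, `SYM`, `X`. The default registry
(18 features):

- **Lexical**: type–token ratio over case-folded lemmas (surface-form
  fallback), mean length of utterance in countable tokens.
- **POS ratios**: noun, verb, adjective, adverb, pronoun, auxiliary,
  interjection shares; noun/verb ratio (nouns = NOUN ∪ PROPN; missing when
  no verbs); open/closed-class ratio (missing when no closed-class
  tokens).
- **Fluency**: filled-pause ratio against a configurable inventory
  (defaults to German: äh, ähm, öh, öhm, hm, mh, mhm).
- **Syntax**: mean dependency distance |head − dependent|, syntactic
  complexity (mean maximum tree depth), simple-sentence ratio (no clausal
  dependents; clausal deprels csubj, ccomp, xcomp, advcl, acl, parataxis,
  matched on the base relation before `:`).
- **Coherence**: mean and SD of cosine similarity between consecutive
  sentence embeddings.

Undefined values propagate as NaN and are handled at the correlation
stage. A note on a tempting "invariant": TTR is *not* monotonically
non-increasing in transcript length — appending a new type increases it
whenever types < tokens ((d+1)/(n+1) > d/n iff n > d). The property-based
tests assert the true invariants instead (the running type count is
non-decreasing with unit increments).

## 7. Synthetic data

Generators plant a known truth so every pipeline stage can be validated
end to end:

- `planted_precision`: chain (θᵢ,ᵢ₊₁ = −ρ gives partial correlation
  exactly ρ; positive definite iff |ρ| < 0.5), hub, and Erdős–Rényi random
  structures (repaired to positive definiteness by diagonal inflation).
- `two_group_design`: two samples from the same GGM, optionally with one
  precision entry perturbed in group b; the perturbed edge and the implied
  partial-correlation difference are returned as ground truth.
- `synth_transcript`: transcripts with Zipf-distributed vocabulary,
  Poisson utterance lengths, i.i.d. filled-pause insertion at a planted
  rate, sequential-attachment dependency trees, and embedding sequences
  rotating by a fixed drift angle θ so that consecutive cosine similarity
  is exactly cos θ.
- `study_shape_features`: a full study-scale feature matrix — 372 subjects
  in four groups (178/119/27/48) over 44 variables in three domains
  (28/10/6) — drawn from a planted random GGM. These problem sizes are the
  package's reference scale for bookkeeping and performance tests.

What these generators deliberately do **not** emulate: realistic grammar or
semantics (trees are random, words carry no meaning), within-subject
utterance dependence beyond the embedding drift, non-Gaussian marginals,
missing-data mechanisms, or any group-specific feature shift unless
explicitly planted. They validate the statistical machinery, not the
linguistics.

## 8. Pipeline

`run_pipeline` estimates seven network variants (all subjects, pooled
patients, each group, and all subjects excluding the psychopathological
domain), bootstraps and prunes each, computes centralities and edge
classification, and runs four default contrasts (controls vs pooled
patients and all pairwise patient contrasts). Stage seeds are derived from
the config seed by fixed offsets so bootstrap and NCT streams are
independent yet reproducible; the manifest records config, stage seeds,
and all summary numbers. Re-running a config byte-identically reproduces
the manifest.

## 9. Numerical choices

- Exact zeros in Θ̂ come from the lasso coefficients, not thresholding.
- Inner lasso: up to 200 sweeps at tolerance 1e-10; outer tolerance 1e-7
  (1e-5 inside bootstrap/permutation loops, where speed matters and only
  summary statistics are consumed).
- EBIC log det via Cholesky; non-PD candidates get EBIC = +inf.
- Positive-definiteness repairs use the smallest ridge in
  {1e-8, 1e-7, …} that restores PD, recorded in metadata.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; derived seeds stay below 2³¹.

## 10. Limitations

- Edges are regularised partial correlations: shrunken toward zero
  (Section 3) and only interpretable causally under strong, untestable
  assumptions.
- EBIC with γ = 0.5 is conservative; weak true edges (|ρ| ≲ 0.1 at
  n ≈ 400) are often missed. Sensitivity claims hold at the stated
  simulated scales only.
- Groups of very different sizes (e.g. 27 vs 178) give unequal estimation
  error; the NCT remains valid but loses power.
- Listwise deletion discards subjects with any missing feature; pairwise
  deletion trades that for possible indefiniteness.
- The feature inventory targets dependency-parsed speech with
  UD-style tags; filled-pause detection is lexical and
  language-specific (defaults are German).
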