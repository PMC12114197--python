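# Methods note

Definitions, defaults, and numerical choices for every method in `soilemf`.
Where a definition admits variants, the choice made here is stated explicitly
and is a deliberate package decision.

## 1. Ecosystem multifunctionality (EMF)

Given a plots × indicators matrix `X` (raw measurement scale):

* Orientation: each indicator has a direction in {+1, −1} (default +1).
  Direction −1 negates the column before standardization so that
  "less is better" measurements contribute positively.
* Min–max standardization across **all plots jointly** (not per treatment):
  `f_ij = (X_ij − min_j) / (max_j − min_j)`; every retained column attains
  both 0 and 1.
* Constant columns (`min = max`) are undefined under this formula. The
  default policy is `drop` with a warning; `zero` and `error` are available.
  Rationale: silent zeros bias the EMF mean downward.
* `EF_g(i)` = mean of the standardized members of group `g` for plot `i`.
  Default groups: `EF-C = {SOC, MBC, EOC, DOC}` (carbon storage); the
  pipeline also defines `EF-enzyme = {S-ALP, S-CAT, S-CL, S-UE, S-SC}`.
* `EMF(i)` = mean of **all** retained standardized indicators for plot `i`
  (the averaging method). EF and EMF are therefore in [0, 1] by
  construction, and both are invariant to positive affine rescaling of any
  raw indicator (verified to 1e-12 in tests).

`MultifunctionalityIndex` is an sklearn-style transformer: `fit` learns the
column extrema (training data), `transform` applies them to new plots.

## 2. Alpha diversity

All estimators are computed from raw integer counts (no rarefaction):

* Shannon `H = −Σ p_i ln p_i` in **nats** (base e).
* Simpson is reported as the **dominance** form `D = Σ p_i²` (lower =
  more diverse), not `1 − D`.
* Chao1, **bias-corrected** form: `S_obs + F1(F1 − 1) / (2(F2 + 1))`, where
  `F1`/`F2` are singleton/doubleton counts. Defined even when `F2 = 0`.
* ACE with the conventional rare/abundant cutoff at 10 individuals. When
  estimated sample coverage of the rare group is 0 (all rare taxa are
  singletons), ACE is undefined and the implementation falls back to the
  bias-corrected Chao1, matching common practice.

All four were verified to agree exactly with an independent reference
implementation (scikit-bio) on hand-built and random tables; the reference is
used in the test suite as an oracle only, not at runtime.

## 3. Co-occurrence networks

* Optional taxon filtering: prevalence (fraction of samples with a nonzero
  count, default ≥ 0.2) then top-N by total count (stable order).
* Pairwise **Spearman** correlation on counts (average ranks;
  t-approximation p-values), requiring ≥ 4 samples. Constant taxa are
  removed with a warning. p-values are Benjamini–Hochberg adjusted across
  all retained pairs.
* Edges: `|rho| ≥ 0.6` and adjusted `p < 0.05` (defaults). Each edge stores
  `rho`, `sign`, `weight = |rho|`, and `p_adj`. The graph contains only
  nodes incident to at least one edge.
* Numerical tolerance: scipy can return `1 − 1e-16` for a perfectly
  monotone pair, so the rho threshold is applied as
  `|rho| ≥ threshold − 1e-12`.
* Topology battery: nodes, links, positive/negative links, positive-link %,
  average degree `2L/N`, graph density `2L/(N(N−1))`, and Newman modularity
  of the partition found by greedy modularity maximization
  (Clauset–Newman–Moore via networkx) on `|rho|` weights. This community
  algorithm is deterministic; the `seed` argument exists only for API
  stability. Empty networks report NaN for ratio metrics and modularity.
* Per-treatment networks require ≥ 4 samples per treatment; smaller groups
  are skipped with a warning.

## 4. Driver statistics

* **ANOVA + Tukey HSD**: scipy one-way F-test, statsmodels `pairwise_tukeyhsd`
  at `alpha = 0.05`, followed by a hand-implemented insert-and-absorb
  compact letter display anchored so that the highest group mean gets "a".
  Groups sharing a letter are not significantly different.
* **PCA**: scikit-learn PCA on relative abundances (counts are closed to
  proportions first); explained-variance percentages sum to 100 over all
  components.
* **Mantel test**: Spearman (default) correlation of the off-diagonal
  entries of two distance matrices; significance by joint row/column
  permutation with `p = (1 + #{r_perm ≥ r_obs}) / (1 + B)` (one-sided,
  add-one), `B = 999` by default, seeded and reproducible. Community
  distance is Bray–Curtis on relative abundances; indicator distance is
  Euclidean on z-scored columns. The grid of (indicator × kingdom) tests is
  BH-adjusted. The permutation scheme and p formula were cross-checked
  against scikit-bio's Mantel statistic in tests.
* **Permutation random-forest importance**: 3-fold cross-validation; in each
  fold a `RandomForestRegressor` is fit on the training split and each
  predictor is permuted in the **held-out** split, with importance = mean
  percent increase in held-out MSE. Held-out (rather than training-set)
  permutation is deliberate: training-set permutation inflates the apparent
  importance of pure-noise predictors because the forest memorizes them.
  Null predictors therefore score near 0 with symmetric sign.
* **Path analysis**: standardized observed-variable path model. The directed
  graph must be acyclic; all variables are z-scored; each endogenous
  variable is regressed on its parents by least squares, giving
  standardized coefficients, standard errors, t-based p-values, and per-
  equation R². A condition number above 1e8 raises a collinearity error; so
  does `n ≤ p + 2` per equation. This is deliberately *not* a latent-
  variable SEM: with observed composites the equations decouple and OLS per
  equation gives the standardized path coefficients exactly.

## 5. Synthetic data generator

`ExperimentDesign` describes a randomized design: treatments × replicates,
indicator baselines, multiplicative treatment effects, two count tables
(bacteria/fungi) with planted correlation blocks, and a sequencing depth.

* **Indicators** are log-normal around baseline × effect with a specified
  coefficient of variation (`sigma² = log(1 + cv²)`); pH is additive normal
  (`baseline = (mean, sd)`) since pH is already a log scale.
* **Counts**: a log-normal latent abundance layer, where members of a
  correlation block of magnitude `m` share a latent factor
  (`log-noise = sign·√m·F + √(1−m)·ε`; negative blocks alternate member
  signs), followed by a multinomial draw at fixed depth (default 50,000).
  Spearman correlations on the resulting counts track the planted targets:
  at n = 30 samples and magnitude 0.8 the default edge criterion recovers
  ≥ 80% of block pairs with a background edge rate an order of magnitude
  below the nominal 5%.
* **Taxonomy** assigns phyla with proportions typical of agricultural soil
  (e.g., Proteobacteria, Acidobacteria, Actinobacteria dominate bacteria;
  Ascomycota dominates fungi).
* `default_study_design()` encodes a 5-treatment (CK, T1–T4) × 3-replicate
  trial with 15 indicators whose effect sizes increase with organic dose
  (e.g., yield × 1.10 and SOC strongly elevated at T4).

What the generator **does not** emulate: spatial structure or field-plot
autocorrelation; compositional artifacts beyond the multinomial draw (no
zero-inflation model); treatment effects on community *diversity* — planted
structure is correlational only, so diversity contrasts between treatments
are null by design; and any dependence between indicators and counts (driver
relationships are simulated separately by `simulate_path_data`).

## 6. Determinism and seeds

A master seed is split into independent stage seeds via
`numpy.random.SeedSequence` (all below 2³¹). The pipeline writes a
`manifest.json` with configuration, stage seeds, and SHA-256 hashes but no
timestamps; a rerun with the same inputs and seed is byte-identical.

## 7. Problem sizes

Defaults used throughout tests and the acceptance script are the package's
own choices, selected for desk-scale runtimes on one CPU: 15 plots × 15
indicators; 60–200 taxa per kingdom at depths of 10,000–50,000; Mantel
B = 999; random forests of 100–500 trees; path-model samples n = 500;
property batteries over 20 seeds.
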