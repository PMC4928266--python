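# Methods

This note documents the models, numerical choices and design decisions
behind `paridmorph`, and what the synthetic-data tests do and do not
establish about real data.

## Superimposition

**Model.** A landmark configuration is a `(k, 2)` point set; shape is what
remains after removing position, scale and orientation. We use full
Procrustes superimposition: every configuration is centred, scaled to unit
centroid size (`CS = √Σᵢ‖xᵢ − x̄‖²`), and rotated onto the consensus by the
proper (determinant +1) rotation from the 2×2 SVD. Reflections are
disallowed because outlines are digitised in a single orientation; a mirror
image is a genuinely different shape.

**GPA.** The consensus is initialised as the renormalised mean of the
centred/scaled inputs (a symmetric function of the sample, so permuting the
input order permutes the output exactly), then alternates rotate-all /
re-mean steps. Convergence: consensus RMS change < 1e-8, cap 200 iterations
(an error, never a silent stop). Re-running GPA on its own output converges
in one iteration, which the tests assert.

**Sliding semilandmarks.** Each semilandmark may move along the chord
between its neighbours on its outline curve (the two beak profiles for the
21-point scheme; for other configurations the point order is treated as one
curve and must be anchored by fixed endpoints). With the default
Procrustes-distance criterion the optimal displacement is the orthogonal
projection of the consensus point onto the tangent line — exact, per point,
because each point owns its own coordinates. A per-specimen guard rejects
any slide that would increase that specimen's distance to the consensus
after re-normalisation, and the consensus update is the SS-minimising
renormalised mean, so the total Procrustes sum of squares is provably
non-increasing across outer iterations — the invariant the tests check.
Slid points are *not* re-projected onto the outline polyline: re-projection
can break the monotone-descent guarantee, and for the small displacements
typical of dense semilandmark schemes the difference is far below
digitising noise. A thin-plate-spline bending-energy criterion is available
(`criterion="bending"`), solving the small tangent-displacement system
against the bending-energy matrix of the consensus; it is not the default
because it couples all points and offers no comparable monotonicity
guarantee.

**Tangent space.** Aligned shapes (unit vectors in configuration space) are
projected orthogonally to the consensus direction: `x ↦ x − (x·c)c`. The
consensus maps to the origin and Euclidean distances approximate Procrustes
distances to first order (relative error ~1e-6 at distances below 0.05 in
the tests — beak-shape variation in songbird-scale data sits well inside
this regime).

## Multivariate statistics

* **Log transform / standardization.** Natural logs; standardization to unit
  sample variance (n−1). Missing values stay flagged: multivariate stages
  (CVA, PCA) drop incomplete rows, univariate stages (per-trait ANOVA) keep
  every available value, so sample sizes legitimately differ across tables.
* **PCA.** SVD of the column-centred (optionally scaled) data. Sign
  convention: the largest-magnitude loading of each component is positive.
  Body-morphology PCA runs on standardized species means (covariance of
  standardized data = correlation matrix); shape PCA runs on the covariance
  of tangent coordinates of species mean shapes (means of aligned
  coordinates, no re-superimposition — deviations are second order).
* **CVA / Mahalanobis.** Shape coordinates are rank-deficient after
  superimposition and sliding, so the data are first reduced to the
  principal components of the total covariance with eigenvalues
  > 1e-10 × the largest, capped at the within-group rank (n − g) and backed
  off further if the pooled within-group covariance is still numerically
  singular. Canonical axes are eigenvectors of W⁻¹B; Mahalanobis distances
  use W in that subspace and are invariant (checked to 1e-6) under any
  invertible linear transform of the input.
* **Procrustes ANOVA.** Goodall-style: between/within sums of squared
  deviations summed over all coordinates, degrees of freedom multiplied by
  the shape dimension (2k − 4 for k 2-D landmarks; overridable, e.g. 1 for a
  univariate embedding, in which case F equals the classical ANOVA F
  exactly). Size uses a classical one-way ANOVA on log centroid size.
  p-values are parametric by default; a permutation p (label shuffles) is
  available and calibrated in the tests (type-I error 0.05 ± 0.02).
  Zero within-group variation yields an infinite F with a warning rather
  than an exception.
* **Regression.** OLS via the standard slope t-test; a constant response is
  a legal degenerate fit (slope 0, r² 0) rather than an error. Size
  correction = per-trait residuals of log trait on log body weight.

## Phylogenetic comparative methods

All methods consume the BM covariance `C` (shared root-to-tip path lengths)
of a rooted tree with branch lengths; tip/trait matching is by exact label
and any unmatched tip is a hard error (silent pruning hides bugs).

* **Blomberg's K**: observed MSE₀/MSE (deviations from the GLS mean, raw vs.
  C-weighted) divided by its expectation `(tr C − n/Σ(C⁻¹))/(n−1)` on the
  same tree. Significance: tip permutation, default 999 shuffles,
  `p = (#{MSE_perm ≤ MSE_obs}+1)/(n_perm+1)`.
* **Pagel's λ**: off-diagonal scaling of C, profiled ML over the mean and
  variance, bounded scalar search on [0, λ_max] (λ_max keeps C_λ positive
  definite, ≥ 1 on ultrametric trees, found by bisection and capped at 5);
  endpoints are compared explicitly so boundary optima are never missed.
  p from the χ²₁ likelihood-ratio test against λ = 0.
* **PGLS** assumes the BM correlation (λ = 1) by default, matching common
  practice when the residual structure is not itself under study; joint ML
  estimation of λ is available via a flag. Slope inference: t with n − 2 df.
* **Squared-change parsimony** minimises Σ(Δ)²/branch length — solved
  exactly as a weighted Laplacian linear system, whose solution equals the
  BM ML ancestral means (the root equals the GLS mean; asserted). Nodes
  joined by zero-length internal branches are merged and share a value.
* **Phylomorphospace**: tips at their observed ordination scores, internal
  nodes at the squared-change-parsimony reconstruction per axis.

K, λ, PGLS and ancestral-state values are cross-checked in the test suite
against independent reference implementations (R's phytools, nlme and
fastAnc) on a frozen 4-taxon fixture, and calibrated by simulation
(500 replicates on a 16-tip tree: K mean in [0.9, 1.1] and λ median ≥ 0.8
under BM, λ median ≤ 0.2 after tip shuffling; PGLS slope unbiased within
2 Monte-Carlo SE).

## Overlap and Mantel

`D_O = O_AB/(S_A + S_B − O_AB)`; distance `D_AB = 1 − D_O`, applied to
geographic areas and altitudinal intervals alike. Degenerate point
intervals: distance 0 if equal, 1 otherwise (documented convention). Missing
pairwise overlap entries are treated as 0 with a logged note — an absent
polygon intersection means disjoint ranges.

The partial Mantel statistic is the Pearson correlation of the off-diagonal
vectors of A and B after each is residualized on the control matrix C;
significance comes from joint row/column permutations of the residualized A
matrix (Legendre's residual-permutation scheme, chosen over raw-matrix
permutation for its better type-I control), one-tailed for positive
association by default with a two-sided option, +1-corrected, default
10,000 permutations. The statistic matches the independent vegan
implementation to 1e-10 on a fixture, reduces exactly to the simple Mantel
test when C is constant, and its type-I error calibrates to 0.05 ± 0.02.

## Synthetic studies

The generator emulates the statistical structure the analyses assume:

* a pure-birth (Yule) tree, rescaled to unit depth, tips `sp01…`;
* a latent log body size evolving by BM (default rate σ² = 0.2 per unit
  depth — tip SD ≈ 0.45 on the log scale, i.e. roughly a 10–40 g spread
  around a 15 g ancestor, the range typical of tits);
* five length traits = base + (1/3) × log size (cube-law allometry)
  + independent BM deviations (σ² = 0.02) + altitude clines (default
  5×10⁻⁵ per metre on log body weight and log culmen, ≈16 % across a
  3,000 m gradient) + within-individual log-normal noise (SD 0.05, ≈5 % CV,
  typical of avian linear measurements);
* beak outlines from a three-parameter profile model (length, depth,
  curvature; two quadratic Bézier profiles whose bow grows linearly with
  curvature and whose nine semilandmarks sit at equal arc length measured on
  a 512-sample polyline), with BM-evolving species parameters, per-specimen
  parameter noise, landmark digitising noise and a random similarity
  transform that the superimposition stage must undo;
* ranges as equal-width sliding bands: adjacent bands offset by
  `(1 − overlap) × length`, so overlap level 1 gives identical ranges and 0
  gives disjoint ones, with jitter that vanishes at both endpoints to keep
  the exact cases exact; altitudinal intervals (default span 1,500 m inside
  400–4,400 m) use the same scheme, and each individual's altitude is
  uniform within its species interval (the simplest defensible choice — the
  truth record keeps every draw);
* one root RNG per study with deterministically derived per-stage
  substreams: one seed ⇒ byte-identical output.

**What passing tests do and do not show.** The generator matches the
*assumptions* of the methods (BM, log-normal noise, linear clines,
interval-shaped ranges). Real museum data violate them in ways the synthetic
studies deliberately do not: unequal and small per-species samples, sexual
dimorphism and age classes, measurement-protocol drift, non-BM selection
regimes, and ranges that are not one-dimensional bands. Green tests
therefore certify the correctness and calibration of the computations, not
the adequacy of the models for any particular dataset.

## Problem sizes and known limitations

* The default end-to-end study is 14 species × 20 individuals; the full
  pipeline (GPA + sliding on 280 outlines, all ordinations, 999-permutation
  signal tests, 4 × 10,000-permutation Mantel tests) completes in well under
  a minute on one CPU, and the calibration experiments use 500 replicates
  (signal and Mantel) and 50 studies (integration recovery) — sizes at which
  the Monte-Carlo error of each check is several times smaller than its
  tolerance.
* ML λ̂ on trees of ~14 tips is intrinsically noisy: even for pure BM data
  about one replicate in six gives λ̂ < 0.8. Recovery claims at that tree
  size should be phrased in medians (as the 16-tip calibration is), not in
  per-run thresholds.
* The Goodall F reports its own degrees of freedom, `(g−1)s` and `(n−g)s`
  with `s` the shape dimension; since F is a ratio of mean squares, `s`
  affects only the p-value.
* An ANCOVA step and Bayesian tree estimation are out of scope: the tree is
  consumed as Newick input, and the pipeline's regressions are OLS/PGLS
  only. Repeating a deterministic regression and averaging the replicates is
  a no-op and is not implemented.
* Within-species altitude regressions need individual altitude records; the
  designated intraspecific species defaults to the best-sampled one and is
  configurable.
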