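# Methods

## Model

A random dot product graph (RDPG) attaches to each vertex a latent vector
`X_i ∈ ℝ^d` drawn i.i.d. from a distribution `F`, and connects vertices
`i, j` independently with probability `P_ij = ⟨X_i, X_j⟩`.  We work
exclusively with finite mixtures of point masses, so every model is a
(positive-semidefinite) stochastic blockmodel; expectations over `F` are
exact finite sums over the atoms, and no quadrature is ever used.
Blockmodels are specified by a Gram matrix `B` of block connection
probabilities, factored as `B = VΛVᵀ` with atoms the rows of `VΛ^{1/2}`;
any factorization is equivalent because the model is identifiable only up
to an orthogonal rotation.

A collection of `m` graphs on one aligned vertex set shares the latent
positions; a symmetric matrix `R` with unit diagonal prescribes the
per-edge correlation `ρ_{k1,k2}` between graphs.  Constructive samplers
exist for two families, and the package implements exactly those (plus
arbitrary `ρ` for pairs, realised as a single conditional step):

- **forward (sequential) chain** — graph `ℓ+1` is redrawn edgewise from
  graph `ℓ`: `Bern(P + ϱ(1−P))` where an edge was present,
  `Bern(P(1−ϱ))` where it was absent.  This preserves the RDPG marginal
  and yields `ρ_{k1,k2} = Π ϱ_{k,k+1}` over the intervening steps.
- **single generator** — every graph is redrawn from one background graph
  `A^(0)` with its own retention parameter `ν_ℓ`, giving
  `ρ_{ℓ1,ℓ2} = ν_{ℓ1}ν_{ℓ2}`.

Correlation matrices outside these families (and negative correlations,
which the estimand admits but no sampler realises) are rejected rather
than approximated.  A flat-`ρ` collection with `m > 2` is sampled via the
generator family with `ν = √ρ·1`.

Randomness: one root `numpy` seed spawns independent child streams per
graph, so any collection is bit-reproducible from a single integer
regardless of `m`.

## Generalized omnibus embedding

The omnibus matrix `𝔐 ∈ ℝ^{mn×mn}` has blocks
`𝔐(k,ℓ) = Σ_q c_q^{(k,ℓ)} A^(q)` subject to three constraints: each block
is a convex combination of the graphs, the matrix is symmetric, and in
block-row `k` the cumulative weight `α(k,k) = Σ_ℓ c_k^{(k,ℓ)}` strictly
exceeds `α(k,q)` for every `q ≠ k`.  Its expectation is `J_m ⊗ P`, which
is rank `d`, so a single `d`-dimensional adjacency spectral embedding
(ASE) of `𝔐` yields `m` blocks of latent-position estimates in a common
basis — no pairwise Procrustes step.  Implemented designs:

| design      | off-diagonal block                                  |
|-------------|-----------------------------------------------------|
| classical   | `(A^(k)+A^(ℓ))/2`                                   |
| total average | `Ā` (the sample mean graph)                       |
| weighted    | `(w_k A^(k)+w_ℓ A^(ℓ))/(w_k+w_ℓ)`                   |
| dampened    | `(w_k A^(k)+A^(ℓ))/(w_k+1)`, `k>ℓ`, `w` increasing  |
| forward     | `((i−1)A^(j)+A^(i))/i`, `i>j` (1-based)             |
| pair-preserving | consecutive pairs averaged, other blocks pass through the smaller-index graph (`m` even) |

The dampened and forward builders transcribe each printed block and then
*assert* symmetry of the result rather than assuming it.  A validator
reports the first violated constraint (convexity, symmetry, dominance)
for arbitrary coefficient tensors.

ASE numerical choices: the spectrum is ordered by eigenvalue magnitude
and scaled by `|λ|^{1/2}` (the `|A|` construction); a negative eigenvalue
among the retained ones and a magnitude tie at the cut are each flagged
with a warning, not an error, because both legitimately occur in
weak-signal regimes; each eigenvector's largest-magnitude entry is made
positive for reproducibility; matrices up to a few hundred rows use a
full symmetric eigendecomposition, larger ones a Lanczos solver on the
top `d+1` magnitudes.  Everything is dense — the intended scale is
`mn ≲ 20 000`.

## Limit theory

With `Δ = E[X₁X₁ᵀ]` (required full rank) the single-graph kernel is

    Σ(x) = Δ⁻¹ E[(xᵀX₁ − (xᵀX₁)²) X₁X₁ᵀ] Δ⁻¹.

For a design with weight profile `α` and correlation `R`, the
`√n`-scaled residual of block `s` is asymptotically Gaussian with
covariance `(1/m²)[Σ_q α(s,q)² + 2Σ_{q<l} α(s,q)α(s,l)ρ_{q,l}]·Σ(x)`;
the two bracket terms are exposed separately as the *method* (induced)
and *model* (inherent) coefficients.  The difference of blocks `s1, s2`
has covariance `2(1−ρ(s1,s2))·Σ(x)` where, with
`d_q = α(s1,q) − α(s2,q)`,

    ρ(s1,s2) = 1 − Σ_q d_q²/(2m²) − Σ_{q<l} d_q d_l ρ_{q,l}/m².

Both printed algebraic forms of the difference covariance are evaluated
and asserted to agree (they coincide exactly because α rows sum to `m`;
the guard trips if a hand-built profile violates this).  Closed forms for
the named families (classical `3/4 + ρ/4`; total average `1 − 1/m² +
ρ/m²`; equal-weight pair `1 − ((m−1)w+1)²(1−ρ)/(m²(1+w)²)`; pair
preserving `1 − (1−ρ)(m−1)²/m²`) are implemented independently and
tested against the general formula over randomized parameters — the
central anti-regression oracle.  The long closed-form sums for the
dampened design with `w_ℓ = ℓ` are not a library feature; they live in
the test suite as a transcription oracle for the general formula.

**Averaged estimator and effective sample size.**  Averaging `m`
flat-`ρ` correlated estimates (separately embedded and aligned, or
omnibus blocks) gives limiting covariance

    [(1−ρ)/m + ρ]·Σ(x) = Σ(x)/m_eff,   m_eff = m/(1+ρ(m−1)),

the network analogue of the covariance of the sample mean of correlated
observations.  A tempting alternative is to compose the *difference*
covariance kernel `2(1−·)Σ(x)` at level `(1−ρ)/m + ρ`, but that form is
inconsistent with the effective-sample-size interpretation (it does not
reduce to `Σ(x)/m` at independence) and simulation rejects it: empirical
variances at `m = 4, n = 400` track `Σ(x)/m_eff` across
`ρ ∈ {0, …, 0.75}` and move in the opposite direction from the
composition.  `averaged_estimator_covariance` therefore computes
`Σ(x)/m_eff`.
`m = 1` is rejected rather than special-cased; use `Σ(x)` directly.

## Empirical estimation

Edge-probability estimates use the spectral reconstruction
`P̃ = X̂D̂X̂ᵀ` (signs of the top-`d` eigenvalues in `D̂`) trimmed to
`[ε, 1−ε]`, default `ε = 10⁻⁴`.  Both graphs in the plug-in correlation
estimator share one user-supplied `d`.  The plug-in estimator
standardises each edge indicator by its (estimated or true) Bernoulli
moments and averages over the `n(n−1)/2` vertex pairs; the Pearson
estimator correlates the raw vectorised upper triangles and is exact for
homogeneous Erdős–Rényi pairs.

The Monte-Carlo embedded-correlation driver tracks vertex 0, whose latent
position is pinned to the first atom via deterministic block memberships
(largest-remainder apportionment of `n` over the mixture weights, first
block first).  Each replicate aligns the full stacked embedding to the
true positions with one orthogonal Procrustes rotation, as in the
theory's orthogonal-sequence formulation.  The reported correlation is
defined on the scale the theory uses: `ρ̂ = 1 − Var(√n(r₁−r₂))/(2Σ(x))`
per coordinate, averaged, with a bootstrap SE over replicates.  The raw
across-replicate Pearson correlation of residuals is also returned, but
it converges to a different quantity (the cross-covariance over the
*block* variance, e.g. `3/(m+3)` for the classical design) and is not
comparable across designs; this distinction is deliberate and tested.

## Experiments

*Community detection* draws correlated two-block SBM pairs with Gram
`[[0.5, 0.5], [0.5, 0.5+ε]]` and compares three latent-position
estimates — omnibus block average, ASE of the mean graph `Ā`, and the
average of separately embedded, Procrustes-aligned ASEs — clustered into
two groups by a Gaussian mixture.  Cluster error is the
permutation-minimal misclassification rate (exhaustive search, `K ≤ 6`).
The `ε = 0` boundary keeps two coordinates (one of them null) so `d = 2`
embeddings remain well-defined at chance-level separation.

*Effective sample size* measures the variance of the averaged estimator
over a `ρ` grid against `Σ(x)/m_eff`.

*Time-series pipeline* chains joint embedding → between-block Frobenius
distance matrix (no alignment needed) → classical MDS (double-centered
`−½D²`, root-eigenvalue scaling, negative eigenvalues truncated with a
warning) → BIC-selected Gaussian-mixture clustering, mirroring an
Mclust-style analysis; the number of components is capped by the number
of graphs.  A scree-elbow selector (two-group Gaussian profile
likelihood) is provided for choosing embedding dimensions from eigenvalue
magnitudes.

Clustering uses `sklearn.mixture.GaussianMixture` with BIC over both the
component count and the covariance structure (full/tied/diag/spherical),
`n_init = 3`, fixed `random_state` — a deliberate stand-in for
model-based clustering à la Mclust; exact cluster labels can differ from
other GMM implementations, so only structural properties (a singleton
anomaly cluster, a single cluster for identical graphs) are asserted.

## Default problem sizes and what the tests show

Monte-Carlo checks run at `n` in the hundreds with hundreds of
replicates (e.g. induced correlation at `n = 300`, 500 replicates;
dampening at `n = 800`, 300 replicates; ESS at `n = 400`, 200
replicates), which keeps every asymptotic within a few percent of its
limit while staying desk-scale.  Orderings in the community-detection
study are asserted with two standard errors of slack (SE = SD/√reps).
The synthetic generator emulates exchangeable, edge-independent
(conditional on latent positions) binary graphs with known alignment; it
does not emulate weighted edges, within-graph edge dependence, degree
heterogeneity beyond the block structure, vertex misalignment, or
non-stationary latent positions.  Passing tests therefore certify the
correlation calculus and samplers under the model's own assumptions, not
robustness to those violations.

## Known limitations

- Only nonnegative pairwise correlation structures with constructive
  samplers (forward / generator / arbitrary pairs) can be drawn.
- Dense `mn × mn` assembly; no sparse/matrix-free eigensolver path.
- Indefinite omnibus spectra: magnitude ordering with a warning is a
  convention, not a theory-backed prescription, when the top-`d` set
  includes negative eigenvalues.
- The inverse problem — choosing weights to induce a *prescribed*
  correlation structure — is out of scope.
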