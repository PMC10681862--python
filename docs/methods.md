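# Methods

## Model

Each of the d compositional vectors (domains) observed on a sample — say
p₁ bacterial and p₂ fungal taxa — is modeled as the closure of a latent
absolute-abundance vector.  Stacking logs over domains, lnY ~ N_p(μ, Ω⁻¹)
with p = Σ pᵢ, and the observation is lnX = lnY − RW where R is the p × d
block-indicator matrix and W holds the per-domain log-totals.  W is not
observed; marginalizing it out of the joint normal yields the likelihood
implemented in `gmcoda.likelihood`:

    L(Ω) = −ln|Ω| + ln|RᵀΩR| + Tr(S[Ω − ΩR(RᵀΩR)⁻¹RᵀΩ]),

up to additive constants, where S is the sample covariance of lnX.
Because only P lnX (P = I − R(RᵀR)⁻¹Rᵀ, the per-block centering
projection) is identified, L is invariant to per-sample, per-block
rescaling of the underlying abundances — the compositional identifiability
premise.  Absolute values of L are convention-dependent (constants are
dropped); all internal comparisons use differences and identities, plus
one fixed anchor: at S = I, Ω = I, L = Σᵢ ln pᵢ + (p − d) exactly.

The estimator is Ω̂ = argmin L(Ω) + λ‖Ω‖₁ over positive-definite Ω.  The
L1 norm includes the diagonal by default, matching the objective as
defined; `penalize_diagonal=False` is exposed because the common
graphical-lasso convention excludes it, which aids cross-checking.

## Optimization

`gmcoda.solver` minimizes f(Ω) = L(Ω) + λ‖Ω‖₁ by
majorization–minimization.  With

    S_Ω = [I − R(RᵀΩR)⁻¹RᵀΩ] S [I − ΩR(RᵀΩR)⁻¹Rᵀ] + R(RᵀΩR)⁻¹Rᵀ,

the surrogate g(Ω|Ωₖ) = −ln|Ω| + Tr(Ω S_Ωₖ) + λ‖Ω‖₁ + ln|RᵀΩₖR| − d
satisfies g(Ωₖ|Ωₖ) = f(Ωₖ) and g ≥ f, so each step

    Ωₖ₊₁ = argmin −ln|Ω| + Tr(Ω S_Ωₖ) + λ‖Ω‖₁

is a graphical-lasso problem and the sequence f(Ωₖ) is non-increasing.
The inner problem is delegated to scikit-learn's coordinate-descent
graphical lasso; the diagonal penalty is folded in exactly by passing
S_Ωₖ + λI (for PD Ω, λ|Ωᵢᵢ| = λΩᵢᵢ).  The test suite asserts the inner
solution's KKT stationarity and agreement with an independent ADMM solver
rather than trusting the delegation.

Numerical choices:

- Initialization: Ω₀ = (S + εI)⁻¹ with ε = 0.1·mean(diag S) when that
  inverse is well-conditioned, else the identity.  The likelihood is
  evaluated through Cholesky factorizations only; RᵀΩR (d × d, tiny) is
  solved directly and no p × p inverse is ever formed.
- Convergence: relative objective change below `mm_tol = 1e-4`
  (|Δf| / (|f| + 1)), at most `max_mm_iter = 100` steps; values chosen so
  the closed-loop benchmark is stable and fast.  Every iterate is
  symmetrized after the inner solve.
- Because the inner solver is inexact, a step that would increase f is
  discarded and the loop stops at the previous iterate, so the recorded
  objective path is non-increasing by construction.
- Degenerate data (a constant log column, so S is singular on the
  diagonal) triggers a warning and a small ridge on S.

## Tuning

`gmcoda.selection` fits a log-spaced decreasing λ grid (default 15 points,
λ_min = 0.01·λ_max) from λ_max = max off-diagonal |S|, warm-starting each
fit at the previous solution, and selects λ by

    BIC(λ) = n·L(Ω̂) + ln(n)·k,   k = #{i<j : |Ω̂ᵢⱼ| > 1e-6}.

The total negative log-likelihood of the sample is (n/2)·L up to
constants, so n·L equals 2·NLL and this is the standard BIC; the edge
threshold 1e-6 matches the threshold the evaluation module uses to call
edges, keeping selection and scoring consistent.  At λ_max the solution is
diagonal for the plain graphical lasso; under the MM surrogate an
occasional stray off-diagonal entry can survive (the surrogate's
off-diagonals can slightly exceed S's), which is why the grid's top point
is treated as "essentially empty", not exactly empty.  BIC ties resolve to
the larger (sparser) λ.

## Synthetic data

`gmcoda.networks` generates the six ground-truth topologies with fixed
edge strengths:

| topology  | construction | strengths | density ≈ |
|-----------|--------------|-----------|-----------|
| random    | pairs connected w.p. 0.1 | ±0.15 | 0.1 |
| neighbor  | union-symmetrized 8-NN of uniform planar points | ±0.15 | 9.8/p |
| band      | \|i−j\| = 1..5 | 0.4, 0.2, −0.2, −0.1, −0.1 | 9.6/p |
| hub       | 4 hubs: hub–hub w.p. 1, hub–other w.p. 0.75 (0.1); others w.p. 0.05 (0.15) | 0.1 / 0.15 | 0.05+5.5/p |
| block     | 8 near-equal blocks: within w.p. 0.45 (0.2), between w.p. 0.05 (0.15) | 0.2 / 0.15 | 0.09 |
| scalefree | preferential attachment ∝ degree², 5 edges per arriving node from a 6-clique core | uniform on {−0.8, −0.5, 0.5, 0.8} | 9.6/p |

Positive definiteness is enforced by setting a *common* diagonal equal to
|λ_min(off-diagonal part)| + 0.2: a uniform diagonal preserves the sign
pattern of the implied partial correlations and makes the true ρ directly
computable, and the 0.2 margin keeps the latent covariance
well-conditioned.  In the neighbor network, kNN ties break toward the
lower index and the directed relation is symmetrized by union; in the
scale-free network "edges added per step" is counted in endpoints (5
undirected edges per node), which is what makes its density land at the
same ≈10/p as the band network.  In the block network the first p mod 8
blocks receive the extra node.

`gmcoda.simulate` draws latent logs from N(μ, Ω⁻¹) with μ entries i.i.d.
Uniform(−0.5, 0.5) redrawn per replicate, and closes each block to
proportions.  The latent draw depends only on (μ, Ω, n, seed) — never on
the block structure — so merged-vs-split analyses share identical latents.
Compositions are generated exactly (no zeros, no sequencing noise), which
is what the benchmark conditions specify; `multinomial_counts` adds
count-level multinomial resampling as an optional post-step for exercising
the count-table pipeline.  What this generator does **not** emulate:
zero inflation, overdispersion beyond log-normality, uneven sequencing
depth, or taxon-specific amplification bias — passing benchmarks therefore
demonstrate correctness of the estimator under its own model, not
robustness to real-data artifacts.

## Benchmark and evaluation

`gmcoda.evaluate` scores an estimate against the truth over strict
upper-triangle pairs: FPR, TPR (recall), precision, F1, plus two
estimation errors over ordered off-diagonal pairs,
d1 = mean |ρ̂ − ρ| and dF = mean (ρ̂ − ρ)² (the mean square itself, not its
root).  Degenerate conventions: precision = 1 with no predictions,
recall = 1 with no true edges, F1 = 1 only when both sides are empty.
AUC integrates the (FPR, TPR) points of the λ path with (0,0) and (1,1)
appended.  `run_benchmark` runs the full loop — truth, μ, data, path, BIC,
scores — with per-replicate seed streams spawned from one master seed, 20
replicates by default at p = 50, blocks (25, 25), n ∈ {100, 300}.

## Real-data pipeline

`gmcoda.io` reads one count table per domain (samples × taxa, TSV/CSV),
then: (1) drops taxa with > 80% zeros across samples, (2) drops samples
with > 80% zeros across the remaining taxa — both per domain, "more than
80%" read strictly — then (3) intersects sample IDs across domains.  A
pseudocount (default 0.5) is added to **all** counts before per-domain
closure: uniform addition preserves within-sample rank order; the value is
a flag.  The permutation null shuffles each taxon's counts independently
across samples, destroying between-taxon dependence while preserving
marginals, and reruns the *entire* pipeline including λ re-selection per
permutation (a full-pipeline null), reporting the mean selected-edge count
over 20 permutations as the false-discovery estimate.

## Known limitations

- The BIC constant and the λ-grid shape are conventions; different
  choices move the selected operating point along the path (the path
  itself, and AUC, are unaffected).
- Observed zeros are handled by pseudocount imputation, which assumes
  they are sampling zeros; structural zeros violate the model.
- The MM loop's inner delegation converges slowly for λ near λ_max; such
  subproblems are accepted on a KKT-residual check (≤ 1e-3) rather than
  the solver's own dual-gap criterion.
- Runtime is O(p³) per inner iteration; the implementation targets
  p up to a few hundred, not thousands.
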