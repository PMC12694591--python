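# Methods

## Model and estimation

The package analyzes a samples × taxa count table `C` with library
sizes `N_i`.  Each taxon `j` is modeled through its negative log
relative abundance `t_ij = −log(C_ij/N_i)`, right-censored at
`log N_i` when `C_ij = 0`: a zero cell is read as "below the detection
limit `1/N_i`", which is exactly the information the library size
carries (it reflects sequencing effort, not microbial load).  The
censored response follows an accelerated failure time regression

    τ_ij = γ_j − X_i·β_j + α_i + ε_ij

on centered covariates without an intercept column.  `γ_j` absorbs the
taxon's true baseline log abundance and its multiplicative measurement
bias; `α_i` is the per-sample normalization treated as a random
effect.  Because any component of `α` along the covariate span shifts
every taxon's estimate by the same amount, differences of coefficients
across taxa — and only differences — are identified free of both the
normalization and the bias.  All reported coefficients are on the log
relative-abundance scale (internally the fit is on the τ scale, where
the sign is reversed).

Estimation is by the Gehan rank estimating function

    S(β) = Σ_i Σ_i' Δ_i 1{e_i <~ e_i'} (X_i − X_i'),   e_i = τ_i − X_i β,

with tie-splitting indicator `1{a<~b} = (1{a<b}+1{a<=b})/2`, chosen for
its robustness at the 60–95% censoring typical of microbiome taxa.  The
estimate minimizes the convex piecewise-linear objective
`G(β) = Σ_{i,i'} Δ_i max(0, e_i' − e_i)`; between kinks the slope of
`G` equals `+S`, so the minimizer solves `S(β̂) ≈ 0` (up to one jump of
the step function).  Minimization is exact and deterministic:

* one free coefficient — the subgradient along the coefficient is a
  nondecreasing step function; its kinks are sorted and walked to the
  sign change; a flat optimal interval is resolved to its midpoint;
* several free coefficients — `G` is rewritten over the `Δ_i = 1`
  pairwise differences as a least-absolute-deviations problem (the
  linear remainder of `max(0,u) = (|u|+u)/2` is absorbed by one
  pseudo-observation with response `10·(Σ|d_p|+1)`), solved by median
  quantile regression and polished by exact coordinate line searches
  (2 sweeps).

No randomness enters estimation.  An optional intercept estimate is
the Kaplan–Meier median of the residuals.

## Testing

Inference is by score tests, because the rank score is a step function
whose derivative (needed for Wald tests) would require smoothing.  The
score variance uses the rank estimator

    σ̂² = N⁻¹ Σ_i (R_{i+} − R_{+i})²,    V̂ = σ̂² (X−X̄)ᵀ(X−X̄),

where `R_ii' = Δ_i 1{e_i <~ e_i'}` is evaluated at the restricted
estimate; this matches the permutation variance of `Σ_i a_i X_i` for
fixed rank scores `a_i = R_{i+} − R_{+i}`.  For a composite null
`H0: Γβ = b` (`Γ` d×K of full row rank, nuisance directions spanned by
the orthonormal rows of `Λ`, `ΓΛᵀ = 0`), the restricted estimate
minimizes `G` over the affine family `β = Γ⁻b + Λ⁻λ`, and

    T = S_γᵀ [V̂_γγ − V̂_γλ V̂_λλ⁻¹ V̂_λγ]⁻¹ S_γ,   S_γ = ΓS,

is referred to `χ²_d`; with no nuisance directions it reduces to
`Sᵀ V̂⁻¹ S` on K degrees of freedom.  The statistic carries no extra
`1/N` normalization — the scaling was fixed by requiring the simulated
null distribution of `T` to match `χ²_d`, which the suite verifies by
a Kolmogorov–Smirnov test over 1000 null replicates (observed KS
p ≈ 0.8, type I error 0.047 at α=0.05).  Moore–Penrose inverses use a
relative singular-value tolerance of 1e-12; inversion of the nuisance
block warns above condition number 1e10.

## Compositional reference

Each taxon is tested against `b = Γβ̃(m)`, where `β̃(m)` is the median
over taxa of the unrestricted projections `Γβ̂_j` — the coefficient of
a typical null taxon under the sparsity-of-signal assumption (fewer
than half the taxa associated).  For d=1 this is the ordinary sample
median (even counts: average of the central pair); for d>1 the
Hettmansperger–Randles affine-equivariant spatial median, computed by
the transformation–retransformation fixed point (tolerance 1e-8, max
500 iterations, componentwise-median fallback with a warning).  Only
taxa with converged fits contribute; at least 3 are required and a
warning is issued below 50, because the reference is treated as a
fixed parameter in every test and its own sampling noise is ignored.
The modal reference used by some related methods is deliberately not
implemented (the config key reserves it).

## Pipeline defaults

* library-size filter: remove samples with `N_i < 3000` (strictly
  below; a flag switches to `≤` for datasets described that way);
* prevalence filter: keep taxa present in ≥ `min_presence_frac` of
  samples (default 0.10 for real-data analysis; the simulation studies
  here use 0.06); applied after the sample filter by default;
* library sizes are *not* recomputed after taxon filtering: the
  censoring bound `log N_i` must reflect sequencing depth, not the
  post-filter subtotal (a config switch recomputes);
* binary covariates are coded 0/1 by sorted level order (logged, since
  the coefficient sign depends on it), multi-level factors expand to
  treatment dummies; all columns centered;
* taxa whose fits fail are reported with missing p-values and excluded
  from the BH family size (a config switch counts them);
* detection at BH-adjusted q ≤ `fdr_threshold` (default 0.05).

## Synthetic communities

The simulator generates study replicates whose statistical anatomy
matches sparse 16S surveys.  Baseline composition: `π⁰ ∝ exp(Z)`,
`Z ~ N(0, σ_tail²)`, sorted descending; the default `σ_tail = 5.5` was
calibrated once so that the default study realizes a mean zero
fraction of ~0.86 (band 0.80–0.90, matching filtered gut templates).
Library sizes are resampled from a log-spaced pool on [3000, 50000],
respecting the depth filter floor.  Covariates are two balanced binary
factors (n/4 per cell).  Causal taxa are drawn from the 50 most
abundant baseline taxa; the standard split assigns 5 to both
covariates, 5 to x2 only, and the rest to x1 only.  The sampling
composition of sample `i` is

    π_ij ∝ ω_j^b · exp(β_j1 x_i1 + β_j2 x_i2 + ε_ij) · π⁰_j,

with bias factors `ω_j ~ U(2, 10)`, bias exponent `b ∈ {0,1,2}`, and
per-cell dispersion `ε_ij ~ N(0, 1)`.  The dispersion term is the
logistic-normal-multinomial device: without it an abundant taxon's
relative abundance is reproduced almost noiselessly in every sample,
which no real community shows and which would make the fixed-reference
approximation misleadingly fragile; σ=1 is a typical log-scale residual
spread for 16S genus-level data.  Counts are multinomial given the
library size, drawn by per-read inverse-CDF lookup so that studies
sharing a seed are read-for-read coupled across bias and effect
settings (used by the paired bias-robustness tests).  What the
generator does *not* emulate: taxon–taxon correlation beyond the
compositional constraint, longitudinal structure, and template-derived
baselines (a user-supplied `baseline` and `library_size_pool` can
stand in for a real template).  Passing tests therefore speak to
marginal effects under realistic sparsity and dispersion, not to
correlated-community behavior.

## Scale of the simulation studies

The replicated studies in the test suite and the acceptance script use
50 replicates of n=100, J=300 (type I error / FDR), 50 replicates of
n=500, J=200 (effect recovery), and 1000 single-taxon replicates for
the null calibration — sizes chosen so the whole suite completes in a
few minutes while keeping Monte-Carlo standard errors a small fraction
of the nominal levels; all checks state their tolerances in MC SE
units.

## Known limitations

* The fixed-reference approximation ignores the sampling noise of
  `β̃(m)`; with few analyzed taxa (warned below 50) p-values for the
  most precisely estimated taxa can be anticonservative.
* The paired-seed rank correlation of per-taxon p-values across bias
  settings is capped by sequencing-read noise (null-taxon p-values
  regenerate whenever the composition changes); the meaningful
  bias-robustness guarantee is the invariance of error rates, which
  the suite verifies.
* The score statistic's χ² calibration degrades only at extreme
  sparsity (fewer than ~7 uncensored observations); the prevalence
  filter keeps analyzed taxa above that regime at the default n.
* Wald and likelihood-ratio tests, Buckley–James estimation, and the
  Cox-model variance of the score are intentionally absent; the rank
  variance is the supported estimator.
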