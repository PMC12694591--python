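# caft — compositional AFT differential abundance analysis

`caft` identifies microbial taxa whose relative abundance is associated
with covariates of interest in sparse, compositional count tables (16S
or shotgun profiles), without pseudocounts and robustly to taxon-specific
multiplicative measurement bias.

## The model

For counts `C_ij` of taxon `j` in sample `i` with library size
`N_i = Σ_j C_ij`, a zero count only says the relative abundance is below
the detection limit `1/N_i`.  The negative log relative abundance

    τ_ij = −log(C_ij / N_i)   if C_ij > 0,
    τ_ij =  log N_i           if C_ij = 0   (right-censored, Δ_i = 0)

is therefore a censored response, and the log-linear model for relative
abundance becomes an accelerated failure time (AFT) regression

    τ_ij = γ_j − X_i·β_j + α_i + ε_ij ,

with centered covariates `X` (no intercept column), a taxon intercept
`γ_j` absorbing the bias factor, and a per-sample normalization `α_i`
treated as a random effect.  Each taxon's `β_j` is estimated by the
rank-based Gehan estimator: minimizing the convex piecewise-linear
objective `G(β) = Σ_{i,i'} Δ_i max(0, e_i' − e_i)` of the residuals
`e_i = τ_i − X_i β`, which performs well even at the extreme censoring
levels of microbiome data.

Only differences `β_j − β_j'` are identified in a compositional model,
so each taxon is tested against the (spatial) median `β̃(m)` of all
taxa's estimates — the coefficient of a typical null taxon when fewer
than half the taxa are truly associated.  The test of
`H0: Γβ_j = Γβ̃(m)` is a restricted score test: the Gehan score at the
null-restricted fit, normalized by the rank variance estimator
`V̂ = σ̂²(X−X̄)ᵀ(X−X̄)` with `σ̂² = N⁻¹ Σ_i (R_{i+} − R_{+i})²`, giving a
`χ²_d` statistic.  P-values across taxa are adjusted by
Benjamini–Hochberg.

A community simulator (`caft.simulate`) generates sparse studies with
heavy-tailed baselines, per-cell biological dispersion, multiplicative
bias factors `ω_j^b`, and multiplicative covariate effects, together
with ground truth for scoring detections.

## Worked example

```python
from caft import RunConfig, SimSpec, run_caft, simulate_study

spec = SimSpec(n_samples=100, n_taxa=300, n_causal=10, beta1=1.5, seed=42)
table, covariates, truth = simulate_study(spec)
res = run_caft(table, covariates, interest=["x1"], adjust=["x2"],
               config=RunConfig(min_presence_frac=0.06, fdr_threshold=0.05))
print(res.table[res.table["detected"]][["taxon_id", "beta.x1", "qvalue"]])
```

Running `python examples/01_simulate_and_analyze.py` prints:

```
study: 100 samples x 300 taxa, 90.7% zero cells
analyzed 57 taxa; reference (null) x1 coefficient: +0.029
taxon_id  beta.x1       pvalue       qvalue
      T5 1.591993 1.391088e-08 7.929202e-07
      T7 1.601213 3.921745e-08 1.117697e-06
     T14 1.581446 1.150536e-07 2.186019e-06
     T48 1.337953 6.879022e-05 9.802606e-04
truly x1-causal: ['T14', 'T38', 'T48', 'T5', 'T7']
```

Four of the five truly associated taxa are recovered at FDR 5% with no
false detections, and the effect estimates sit near the simulated value
of 1.5 relative to the reference, which is near zero (the fifth causal
taxon, T38, is too sparse in this draw).  The other example
scripts walk through the censoring transform (`02`), the score test on
a two-observation instance you can check by hand (`03`), and a small
operating-characteristics benchmark (`04`).

A thin CLI mirrors the library: `caft run` (analyze a count table +
metadata), `caft simulate` (write a synthetic study), and
`caft benchmark` (simulate–analyze–score loop).

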