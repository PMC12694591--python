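"""Small simulate -> analyze -> score loop (a 5-replicate benchmark).

Averages type I error, empirical FDR and sensitivity over five
simulated studies; the full-scale version of this loop is what
``scripts/acceptance.py`` and ``caft benchmark`` run.
"""

from caft import RunConfig, SimSpec, evaluate_performance, run_caft, simulate_study

pairs = []
for seed in range(1, 6):
    spec = SimSpec(n_samples=100, n_taxa=300, n_causal=10, beta1=1.0, seed=seed)
    table, covariates, truth = simulate_study(spec)
    res = run_caft(table, covariates, ["x1"], ["x2"],
                   config=RunConfig(min_presence_frac=0.06))
    pairs.append((res, truth))

summary = evaluate_performance(pairs, alpha=0.05, fdr_target=0.05)
print(f"replicates   : {summary.n_replicates}")
print(f"type I error : {summary.type_i_error:.3f}  (nominal 0.05)")
print(f"empirical FDR: {summary.fdr_empirical:.3f}  (BH target 0.05)")
print(f"sensitivity  : {summary.sensitivity:.3f}")
# type I error counts x1-null taxa with p <= 0.05; FDR is the average
# false-discovery proportion among BH detections; sensitivity is the
# fraction of truly x1-associated taxa detected.
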