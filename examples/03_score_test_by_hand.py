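"""The rank score test on a two-observation instance, by hand.

With residuals e=(0,1), both uncensored, and a centered binary
covariate (-0.5, +0.5), every quantity of the test is small enough to
verify on paper: the Gehan comparison matrix, the score, the rank
variance, and the chi-square statistic.
"""

import numpy as np

from caft import (
    CensoredTaxon,
    DesignMatrix,
    contrast_complement,
    gehan_score,
    rank_matrix,
    rank_sigma2,
    rank_variance,
    score_test,
)

taxon = CensoredTaxon(tau=np.array([0.0, 1.0]), delta=np.array([1, 1]))
X = np.array([[-0.5], [0.5]])

R = rank_matrix(taxon.tau, taxon.delta)
print("comparison matrix R:\n", R)                      # [[0.5, 1], [0, 0.5]]
print("score S(0) =", gehan_score(np.zeros(1), taxon, X))  # [-1.0]
s2 = rank_sigma2(R)
print("rank variance scale sigma^2 =", s2)              # 1.0
print("variance V =", rank_variance(s2, X))             # [[0.5]]

res = score_test(taxon, DesignMatrix(X), contrast_complement(np.array([[1.0]]), b=[0.0]))
print(f"T = S V^-1 S = {res.statistic:.1f} on {res.df} df, p = {res.p_value:.4f}")
# T = (-1)^2 / 0.5 = 2.0; the sample with the higher covariate value has
# the larger residual, one pair's worth of evidence against beta = 0.
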