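"""The detection-limit view of zero counts.

Builds a tiny count table by hand and shows the censored negative log
relative abundance for one taxon: positive counts map to -log(C/N),
zeros map to the censoring bound log N (the detection limit 1/N on the
relative-abundance scale).
"""

import numpy as np

from caft import CountTable, to_censored, zero_fraction

table = CountTable(
    counts=np.array([[9, 1], [1, 9], [0, 10], [5, 5]]),
    sample_ids=np.array(["s1", "s2", "s3", "s4"]),
    taxon_ids=np.array(["A", "B"]),
)
print(f"zero fraction of the table: {zero_fraction(table):.2f}")
ct = to_censored(table, "A")
for sid, c, n, t, d in zip(table.sample_ids, table.counts[:, 0],
                           table.library_sizes, ct.tau, ct.delta):
    status = "observed" if d else f"censored at log N = {np.log(n):.3f}"
    print(f"  {sid}: count {c:2d}/{n}  tau = {t:.3f}  ({status})")
# s3 has a zero count: its relative abundance is below 1/10, so tau is
# right-censored at log 10 rather than imputed with a pseudocount.
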