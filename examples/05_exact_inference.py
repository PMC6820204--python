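"""Exact Wilcoxon signed-rank inference for N = 8 hemispheres.

With eight paired observations the null has exactly 2^8 = 256 equally likely
sign patterns, so p-values are discrete multiples of 2/256. The smallest
attainable two-sided p (all differences one sign, W = 0) is 0.0078 -> 0.008.
"""

import numpy as np

from hgalpha.stats import exact_signed_rank, r_equivalent

print("minority ranks ->  W      p      r_e")
for minority in [(), (1,), (2,), (3,), (3, 4), (7, 8), (1, 7, 8)]:
    d = -np.arange(1.0, 9.0)
    for r in minority:
        d[r - 1] = r
    res = exact_signed_rank(d)
    print(f"{str(minority):>14} -> {res.statistic:4g}  {res.p_value:.4f}  "
          f"{res.effect_size:.3f}")
# Every group-level p the pipeline can report is one of these quantiles;
# r_e converts the one-tailed p to an equivalent correlation at df = 7.
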