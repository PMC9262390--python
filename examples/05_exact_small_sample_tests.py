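"""Exact small-sample inference for per-embryo comparisons.

Published comparisons of mean division angles use a handful of embryos per
genotype, where the exact Mann-Whitney null matters: under complete
separation the two-sided p equals 2 / C(n1+n2, n1), the smallest value the
test can produce at those sizes.
"""

import math

from mitopolar import stats

print("complete separation, exact two-sided Mann-Whitney:")
for n1, n2 in [(7, 10), (5, 5), (4, 4), (5, 6), (8, 3)]:
    x = list(range(1, n1 + 1))
    y = list(range(n1 + 1, n1 + n2 + 1))
    res = stats.mann_whitney(x, y)
    print(f"  n1={n1:2d}, n2={n2:2d}: p = {res.p_two_sided:.3g} "
          f"(= 2/C({n1 + n2},{n1}) = 2/{math.comb(n1 + n2, n1)})")

# with ties or larger samples the test switches to the corrected
# normal approximation automatically
res = stats.mann_whitney([1, 2, 2, 3] * 8, [2, 3, 3, 4] * 8)
print(f"tied large samples: method = {res.method}, p = {res.p_two_sided:.3g}")
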