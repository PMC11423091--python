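"""The kernel menu and the mixture-of-chi-square null distribution.

Builds each genotype-similarity kernel on a toy region, shows the score
statistic and its null eigenvalues, and compares the exact (Davies) and
moment-matching (Liu) p-values.
"""

import numpy as np

from recwas import (KERNEL_NAMES, build_kernel, davies_pvalue,
                    fit_null_model, liu_pvalue, null_mixture_weights,
                    score_statistic, simulate_genotypes)

rng = np.random.default_rng(3)
ds = simulate_genotypes(300, 6, seed=0)
w = rng.normal(size=6)
Y = rng.standard_normal(300)          # null trait: no genetic effect
null = fit_null_model(Y)

print(f"{'kernel':20s} {'Q':>10s} {'#eig':>5s} {'davies p':>10s} "
      f"{'liu p':>10s}")
for name in KERNEL_NAMES:
    K = build_kernel(ds.matrix, w, name)
    Q = score_statistic(null, K)
    lam = null_mixture_weights(null, K)
    p_d = davies_pvalue(Q, lam)
    p_l = liu_pvalue(Q, lam)
    print(f"{name:20s} {Q:10.1f} {lam.size:5d} {p_d:10.4f} {p_l:10.4f}")

print()
print("Under the null the p-values hover away from 0; Davies is the exact")
print("characteristic-function inversion, Liu a chi-square moment match —")
print("they agree closely at moderate p and diverge only in the far tail.")
print(f"chi2_1 5% point check: P(chi2_1 >= 3.841459) = "
      f"{davies_pvalue(3.841459, [1.0]):.4f}")
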