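"""Noiseless phase transition: NE versus rho at fixed undersampling.

Sweeps the sparsity ratio rho = s/n at delta = n/p = 0.5 on an independent
synthetic genotype matrix with h^2 = 1 and {-1,+1} coefficients, then locates
the largest rho at which the median normalized coefficient error (NE) is
still below 0.5 and compares it with the theoretical L1 recovery boundary.
Below the boundary the lasso recovers essentially the whole support; above
it, recovery collapses.
"""

import warnings

import numpy as np

import csgwas as cg
from csgwas.phaseplane import detect_transition, run_experiment, theoretical_boundary

warnings.simplefilter("ignore")

n, p = 600, 1200  # delta = 0.5
gm = cg.simulate_genotypes(n, p, maf_spec=(0.05, 0.5), seed=1)

rhos, medians = [], []
print(f"delta = {n / p:.2f}  (n = {n}, p = {p}, h2 = 1, 3 replicates per point)")
for i, rho in enumerate((0.2, 0.3, 0.35, 0.4, 0.45, 0.55)):
    s = round(rho * n)
    pt = run_experiment(gm, n=n, s=s, h2=1.0, reps=3, seed=10 + i)
    rhos.append(s / n)
    medians.append(pt.aggregates["ne"])
    print(f"  rho = {s / n:.3f}  (s = {s:3d})   median NE = {medians[-1]:.3f}")

crossing = detect_transition(np.array(rhos), np.array(medians), criterion="ne")
bound = theoretical_boundary(n / p)
print(f"\nempirical critical rho (NE < 0.5): {crossing.critical:.3f}")
print(f"theoretical L1 boundary rho_L1({n / p:.2f}) = {bound:.3f}")
print("-> the empirical transition tracks the asymptotic curve; sparse signals")
print("   with s/n below this ratio are fully selectable from noiseless data.")
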