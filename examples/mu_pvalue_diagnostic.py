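"""The muP-value: an observable phase-transition diagnostic.

NE, PPV and FPR need the unknown true coefficients, so they cannot be
computed on real data.  The median marginal-regression p-value of the
selected markers (muP-value) can: it rises while selection is poor, then
collapses once the sample is large enough for complete selection.  This
example sweeps sample size at h^2 = 0.5 and shows the muP-value transition
coinciding with the (oracle) PPV convergence.
"""

import warnings

import numpy as np

import csgwas as cg
from csgwas.phaseplane import detect_transition, run_experiment

warnings.simplefilter("ignore")

p, s = 1200, 12
gm = cg.simulate_genotypes(1100, p, maf_spec=(0.05, 0.5), seed=2)

ns = (150, 300, 450, 600, 750, 900, 1050)
mus, ppvs = [], []
print(f"h2 = 0.5, s = {s}, p = {p}, 3 replicates per point")
for i, n in enumerate(ns):
    pt = run_experiment(gm, n=n, s=s, h2=0.5, reps=3, seed=20 + i)
    mus.append(pt.aggregates["mu_pvalue"])
    ppvs.append(pt.aggregates["ppv"])
    print(f"  n = {n:4d}   muP-value = {mus[-1]:9.3g}   PPV = {ppvs[-1]:.2f}")

res = detect_transition(np.array(ns, float), np.array(mus), criterion="mu")
print(f"\nnormalized muP-value drops below 5% of its maximum and stays there at n = {res.critical:.0f}")
print("-> a steep, sustained muP-value decline across growing subsamples signals")
print("   that the dataset has reached the sample size for accurate selection,")
print("   without ever knowing the true support.")
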