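"""L1-penalized selection versus standard marginal regression on one dataset.

Simulates a noisy polygenic trait, runs (i) the warm-started lasso path down
to the theoretical penalty and (ii) a per-marker GWAS scan thresholded at
p < 1e-8, then compares the two selections against the truth.
"""

import warnings

import numpy as np

import csgwas as cg
from csgwas.mr import mr_scan, mr_select, selection_overlap

warnings.simplefilter("ignore")

gm = cg.simulate_genotypes(2500, 1000, maf_spec=(0.05, 0.5), seed=3)
model = cg.make_true_model(cg.EnsembleSpec.signs(50), gm.markers, h2=0.5, seed=4)
real = cg.simulate_phenotype(gm, model, seed=5)

# lasso with the compressed-sensing penalty (sigma_e2 = 1 - h2)
path = cg.lasso_path(gm, real.y, cg.LassoConfig(sigma_e2=0.5, seed=6))
l1 = cg.select(path)
l1_metrics = cg.evaluate_selection(gm, real.y, real.x, l1.x_hat)

# marginal regression at the genome-wide threshold
scan = mr_scan(gm, real.y)
mr_sel = mr_select(scan, 1e-8)
_, mr_ppv, _, mr_tp = cg.confusion_metrics(set(model.support), set(mr_sel), gm.p_markers)

print(f"true nonzeros: {len(model.support)}   (h2 = 0.5, n = 2500, p = 1000)")
print(f"per-marker effect variance: h2/s = {0.5 / 50:.3f} -> marginal t ~ 5, near the 1e-8 cutoff")
print(f"lasso:    {l1_metrics.n_selected:3d} selected, {l1_metrics.n_true_positive} true "
      f"(PPV = {l1_metrics.ppv:.2f}, FPR = {l1_metrics.fpr:.4f}, muP = {l1_metrics.mu_pvalue:.2g})")
print(f"marginal: {mr_sel.size:3d} selected, {mr_tp} true (PPV = {mr_ppv:.2f})")
print("overlap:", selection_overlap(l1.support, mr_sel))
print("-> at this sample size the L1 path recovers more of the support than the")
print("   strict marginal threshold, while keeping precision comparable.")
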