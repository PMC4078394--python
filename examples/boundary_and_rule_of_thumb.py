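"""The theoretical L1 boundary and the sample-size rule of thumb.

Evaluates the asymptotic signed-coefficient weak-recovery curve rho_L1(delta)
and turns an empirical noisy-case critical ratio (rho ~ 0.03 at h^2 ~ 0.5)
into the minimum sample size for a hypothesized number of causal markers.
"""

from csgwas.phaseplane import minimum_sample_size, theoretical_boundary

print("noiseless L1 recovery boundary rho_L1(delta):")
for delta in (0.05, 0.1, 0.19, 0.25, 0.5, 0.75, 0.9):
    print(f"  delta = {delta:4.2f}   rho_L1 = {theoretical_boundary(delta):.3f}")
print("(any study design with s/n below the curve at its n/p recovers the")
print(" full support from noiseless phenotypes, with probability -> 1)")

rho_crit = 0.03  # empirical noisy-case critical ratio at h2 ~ 0.5
for s in (400, 1200):
    n_min = minimum_sample_size(s, rho_crit)
    print(f"\nwith rho_crit = {rho_crit} and s = {s} causal markers:"
          f" need n >= {n_min:,} subjects (~{n_min // s}x s)")
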