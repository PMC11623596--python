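"""Dark-recovery kinetics of the photoreceptor chromophore.

After illumination the LOV2 flavin-cysteine adduct decays thermally and
absorbance at 447 nm recovers.  This simulates a recovery trace and fits
the one-phase association model A(t) = plateau + (A0 - plateau) e^(-k t).
"""

import numpy as np

from phototherm import fit_one_phase_association, simulate_relaxation_trace

trace = simulate_relaxation_trace(
    k_rel=0.018, a0=0.012, plateau=0.048, duration=400.0, noise_sd=5e-4, seed=9
)
fit = fit_one_phase_association(trace)

print(f"recovery rate k  = {fit.k_rel * 1e3:.2f} x10^-3 /s  (true 18.00)")
print(f"half-recovery    = {np.log(2) / fit.k_rel:.0f} s")
print(f"A(0) -> plateau  = {fit.a0:.4f} -> {fit.plateau:.4f} AU")
print(f"residual rms     = {fit.rms:.2e} AU")
print()
print("The half-recovery time sets how long a 'lit' sample stays lit after")
print("the light is switched off - the timescale on which dark-state")
print("measurements must outpace chromophore relaxation.")
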