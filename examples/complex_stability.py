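"""Fit the disassembly kinetics of a collided complex.

Simulates a gel time course decaying with two rate constants (a fast
minor phase and a slow major phase, as collided-complex gels show),
normalises it between the -NTP and proteinase K controls, and fits the
bi-exponential to extract the half-life with a bootstrap CI.
"""

import numpy as np

from rnapcollide import fit_biexponential, fraction_intact
from rnapcollide.synthetic import simulate_decay

timepoints = np.array([0, 2, 5, 10, 20, 40, 60, 90, 120, 180, 240, 300], float)
curve = simulate_decay(
    a1=0.35, k1=0.12, a2=0.65, k2=0.0035,
    timepoints=timepoints, noise_sd=0.02, seed=11,
)

fractions = fraction_intact(curve)
fit = fit_biexponential(timepoints, fractions, seed=0, n_boot=500)

print("time_min  fraction_intact")
for t, f in zip(timepoints, fractions):
    print(f"{t:8.0f}  {f:.3f}")
print()
print(f"fast phase : a1 = {fit.a1:.2f}, k1 = {fit.k1:.4f} /min")
print(f"slow phase : a2 = {fit.a2:.2f}, k2 = {fit.k2:.4f} /min")
print(f"half-life  : {fit.half_life:.0f} min "
      f"(95% CI {fit.ci95[0]:.0f}-{fit.ci95[1]:.0f} min)")
print()
print("The half-life is the time for the fitted curve to reach half its")
print("fitted t=0 value; a hairpin-stabilized collided complex persists for")
print("hours while an unstabilized one disassembles within minutes.")
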