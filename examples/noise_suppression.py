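"""Noise-induced extinction: stochastic path vs its deterministic skeleton.

With strong infection noise (sigma3 = 1.5) the stochastic reproduction
number drops below 1 while the deterministic one stays above it: the same
parameters are endemic without noise and extinct with it.
"""

from svirdelay import (NoisePlan, derived_constants, deterministic_simulate,
                       load_preset, ssstnsfd_simulate, time_average)

preset = load_preset("large_noise")
d = derived_constants(preset.params)
print(f"R0s = {d.R0s:.4f} < 1 < R0d = {d.R0d:.4f}")

grid, hist = preset.grid(), preset.history()
stoch = ssstnsfd_simulate(preset.params, grid, hist,
                          NoisePlan.gaussian(1, grid))
det = deterministic_simulate(preset.params, grid, hist, "ssstnsfd")
print(f"stochastic path:    I(T) = {stoch.I[-1]:.3e}, <I> = "
      f"{time_average(stoch, 'I'):.4f}")
print(f"  (recorded positivity violations with sigma3=1.5: "
      f"{len(stoch.positivity_violations)} steps -- large negative "
      f"increments can flip the sign of a near-zero I; they are recorded, "
      f"never clipped)")
print(f"deterministic path: I(T) = {det.I[-1]:.4f},   <I> = "
      f"{time_average(det, 'I'):.4f}")
print("The noise drives the infection to extinction even though the "
      "noise-free dynamics settle at an endemic level.")
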