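"""Closed-form threshold quantities for every experiment preset.

R0s is the stochastic reproduction number: below 1 the infection dies out
almost surely, above 1 (with a positive side condition) it persists in
mean.  R0d is its noise-free counterpart; a gap between them is the
infection noise suppressing transmission.
"""

from svirdelay import (PRESET_NAMES, derived_constants, load_preset,
                       reported_thresholds)

print(f"{'preset':<16} {'R0s':>8} {'R0d':>8} {'condition':>10}")
for name in PRESET_NAMES:
    p = load_preset(name).params
    d = derived_constants(p)
    print(f"{name:<16} {d.R0s:8.4f} {d.R0d:8.4f} {d.condition_value:10.4f}")

p = load_preset("persistence").params
t = reported_thresholds(p)
print(f"\npersistence thresholds (supercritical preset): "
      f"I* = {t.I_star}, S* = {t.S_star}, V* = {t.V_star}")
print("Long-run time averages should satisfy <I> >= I*, <S> <= S*, <V> -> V*.")
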