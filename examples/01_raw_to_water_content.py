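"""From raw sensor counts to stem water content.

Converts a handful of raw Teros-12 counts to dielectric permittivity via
the manufacturer polynomial, then to volumetric water content with the
tropical tree calibration (TTC): theta = 0.2227*sqrt(eps) - 0.396.
"""

import numpy as np

import stemwc as sw

registry = sw.default_registry()
transform = registry.transform("teros12")
ttc = registry.calibrations["TTC"]

raw_counts = np.array([2200.0, 2600.0, 3000.0, 3400.0])
sample = sw.raw_to_permittivity(raw_counts, transform)
vwc = sw.apply_calibration(sample.sqrt_epsilon, ttc)

print("raw counts -> permittivity -> stem water content (TTC)")
for r, eps, se, v in zip(raw_counts, sample.epsilon, sample.sqrt_epsilon, vwc):
    print(f"  raw {r:7.0f}  eps {eps:7.2f}  sqrt(eps) {se:5.2f}  VWC {v:6.3f} m3 m-3")
print()
print("Each VWC value is cubic metres of water per cubic metre of fresh wood;")
print("0.3-0.6 is the typical range for living tropical sapwood.")
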