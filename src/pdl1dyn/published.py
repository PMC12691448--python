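"""Published EMT6 comparison numbers, used as reference inputs.

The study's tumor-volume observations were digitized from figures and are
not printed anywhere, so they cannot be reproduced here; what is printed —
and therefore usable as input — is the per-therapy residual sum of squares
of each model variant, the corresponding AIC values, and the globally
fitted ε-equation constants. These let the AIC conventions and totals be
recomputed and checked from scratch.
"""

from __future__ import annotations

#: Arm order (a)–(f): isotype control; NHS-muIL12 2 μg; NHS-muIL12 10 μg;
#: Avelumab 200 μg; Avelumab + NHS 2 μg; Avelumab + NHS 10 μg.
ARM_ORDER = ("a", "b", "c", "d", "e", "f")

#: Per-therapy RSS of the unrefined base model (updated fixed parameters).
ORIGINAL_RSS = (5401.0, 26367.0, 12332.0, 27188.0, 249770.0, 9094.4)

#: Per-therapy RSS of the constant-ε model (one ε fitted per arm).
CONSTANT_RSS = (5367.9, 5664.4, 3240.4, 18396.0, 739.9, 1762.4)

#: Per-therapy AIC of the constant-ε model (n = 6, k = 1).
CONSTANT_AIC = (42.779, 43.101, 39.750, 50.169, 30.889, 36.096)

#: Per-therapy RSS decomposition of the global dynamic-ε fit.
DYNAMIC_RSS = (6555.9, 8251.0, 6474.1, 14853.0, 2330.5, 9161.8)

#: Per-therapy AIC of the dynamic-ε model (n = 6, k = 5).
DYNAMIC_AIC = (51.978, 53.358, 51.903, 56.885, 45.772, 53.986)

#: Published totals (summed-RSS convention, n = 36; k = 6 resp. 5).
TOTAL_CONSTANT_AIC = 259.84
TOTAL_DYNAMIC_AIC = 268.75
DELTA_AIC = 9

#: Observations per therapy and arm count of the EMT6 study.
N_PER_ARM = 6
N_ARMS = 6
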