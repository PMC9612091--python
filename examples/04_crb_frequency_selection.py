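"""Rank candidate spatial-frequency pairs by Cramér–Rao uncertainty.

Scans the four candidate pairs over 900-1000 nm on 10% intralipid
properties and prints the mean bounds plus penetration depths.
"""

import numpy as np

from sfdikit import (NoiseModel, effective_penetration_depth, rank_pairs,
                     reference_phantom_properties, scan_frequency_pairs)

wavelengths = np.arange(900.0, 1001.0, 5.0)
mu_a, mu_s = reference_phantom_properties(wavelengths)
pairs = [(0.0, 0.05), (0.0, 0.1), (0.0, 0.2), (0.0, 0.4)]

scan = scan_frequency_pairs(pairs, wavelengths, mu_a, mu_s, NoiseModel())
ranking = rank_pairs(scan)
ranking["depth_mm"] = [
    float(np.mean(effective_penetration_depth(mu_a, mu_s, f2)))
    for f2 in ranking.f2
]
print(ranking.to_string(index=False))
print("-> [0, 0.05] mm^-1 is the worst design (nearly parallel sensitivities);"
      " [0, 0.2] combines low uncertainty with usable penetration depth,"
      " while 0.4 mm^-1 probes shallower tissue.")
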