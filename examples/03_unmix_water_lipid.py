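"""Beer's-law unmixing: from an absorption spectrum to concentrations.

Synthesizes the 900-1000 nm absorption spectrum of an 85% water / 15% lipid
mixture, adds measurement-scale noise, and refits both concentrations.
"""

import numpy as np

from sfdikit import fit_concentrations, make_basis, synthesize_absorption

grid = np.arange(900.0, 1001.0, 5.0)
basis = make_basis(["water", "lipid"], grid)

truth = np.array([85.0, 15.0])  # percent volume fraction
mu_a = synthesize_absorption(basis, truth)
print(f"mu_a at 930 nm (lipid feature): {mu_a[grid == 930][0]:.5f} mm^-1")
print(f"mu_a at 970 nm (water feature): {mu_a[grid == 970][0]:.5f} mm^-1")

rng = np.random.default_rng(0)
noisy = mu_a + rng.normal(0, 1.5e-4, mu_a.shape)
conc, resid = fit_concentrations(noisy, basis, nonneg=True)
print(f"refit water = {conc[0]:.2f}%  lipid = {conc[1]:.2f}%  "
      f"(truth 85/15, residual RMS {resid:.2e} mm^-1)")
print("-> the 930-nm lipid and 970-nm water features make the two columns "
      "of the basis separable inside this silicon-detector window.")
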