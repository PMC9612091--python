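"""Wavelength-increment tradeoff: error statistics per sampling density.

Runs a reduced (20,000-sample) version of the increment study and prints
the percent-error statistics per increment and chromophore.
"""

from sfdikit import StudyConfig, run_increment_study

result = run_increment_study(StudyConfig(n_samples=20_000, seed=0))
print(result.table.to_string(index=False))
print("-> means stay near zero (the noise is zero-mean, the refit unbiased); "
      "the sd grows as the grid coarsens from 1 nm to 10 nm, roughly like "
      "1/sqrt(number of wavelengths). The 5-nm increment trades a modest sd "
      "inflation for 5x fewer acquisitions.")
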