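"""Generate the synthetic chromophore extinction and reference-phantom fixtures.

The packaged CSVs under ``src/sfdikit/data`` are smooth monotone-cubic (PCHIP)
constructions through anchor points placed at widely known absorption-feature
positions and magnitudes (water peak near 970 nm, lipid peak near 930 nm,
deoxyhemoglobin peak near 760 nm, the oxyhemoglobin NIR plateau). They are
synthetic stand-ins for tabulated literature spectra, adequate for exercising
the full processing chain: what matters downstream is that the Beer's-law
basis is full rank with realistic magnitudes (tissue-like mu_a in the
0.005-0.08 mm^-1 range over 900-1000 nm), not the exact literature values.

Run from the repository root:

    python scripts/make_fixture_spectra.py
"""

from __future__ import annotations

import pathlib

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "sfdikit" / "data"

GRID = np.arange(650, 1001)  # nm, 1-nm spacing

# Pure-water absorption, mm^-1 at volume fraction 1.0.  Anchors follow the
# familiar NIR water curve: weak 740/840 shoulders, steep rise past 900 nm to
# the ~970-nm peak (~0.0485 mm^-1), partial descent by 1000 nm.
WATER = [
    (650, 0.00032), (700, 0.00060), (720, 0.00105), (740, 0.00268),
    (760, 0.00256), (780, 0.00234), (800, 0.00215), (820, 0.00280),
    (840, 0.00395), (860, 0.00480), (880, 0.00555), (900, 0.00679),
    (920, 0.01100), (940, 0.02670), (950, 0.03900), (960, 0.04500),
    (970, 0.04850), (980, 0.04720), (990, 0.04200), (1000, 0.03630),
]

# Pure-lipid absorption, mm^-1 at volume fraction 1.0.  The 930-nm feature is
# the one this wavelength window exploits; a weak 760-nm overtone is included.
LIPID = [
    (650, 0.00040), (700, 0.00055), (740, 0.00085), (760, 0.00105),
    (780, 0.00080), (800, 0.00075), (830, 0.00110), (860, 0.00180),
    (880, 0.00240), (900, 0.00400), (915, 0.00700), (930, 0.01100),
    (945, 0.00650), (960, 0.00450), (975, 0.00420), (990, 0.00400),
    (1000, 0.00430),
]

# Hemoglobins: absorption mm^-1 at 1 uM concentration, i.e.
# ln(10) * epsilon[cm^-1/M] * 1e-6 [M] * 0.1 [cm/mm].  Anchor epsilons follow
# the standard NIR shapes: HHb high at 650 nm with a 760-nm peak then decline;
# HbO2 rising through the NIR to a broad plateau near 900-950 nm.
_EPS_TO_MM_PER_UM = np.log(10) * 1e-6 * 10.0  # mm^-1 per uM per (cm^-1/M)

HBO2_EPS = [
    (650, 368.0), (680, 290.0), (700, 290.0), (730, 390.0), (750, 518.0),
    (780, 710.0), (800, 816.0), (850, 1058.0), (900, 1198.0), (950, 1204.0),
    (975, 1150.0), (1000, 1080.0),
]
HHB_EPS = [
    (650, 3743.0), (680, 2407.0), (700, 1794.0), (730, 1244.0), (750, 1405.0),
    (760, 1670.0), (780, 1096.0), (800, 762.0), (850, 691.0), (900, 730.0),
    (950, 650.0), (975, 620.0), (1000, 600.0),
]

# 10% intralipid reference phantom: mu_a as 90/10 water/lipid mix, mu_s' as a
# Mie-like power law with amplitude typical of diluted intralipid emulsions.
SCAT_A_800 = 1.8  # mm^-1 at 800 nm
SCAT_B = 2.4


def _pchip(anchors: list[tuple[float, float]]) -> np.ndarray:
    x, y = map(np.asarray, zip(*anchors))
    return PchipInterpolator(x, y)(GRID)


def _write(name: str, values: np.ndarray, header_lines: list[str]) -> None:
    path = OUT / name
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(GRID, values):
            fh.write(f"{wl},{v:.6g}\n")
    print(f"wrote {path}")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    common = [
        "SYNTHETIC fixture: monotone-cubic construction through anchor points",
        "at standard NIR absorption-feature positions; not a literature table.",
        "Generated by scripts/make_fixture_spectra.py.",
    ]
    _write(
        "water_absorption_synthetic.csv", _pchip(WATER),
        ["Water absorption coefficient, mm^-1 at volume fraction 1.0."] + common,
    )
    _write(
        "lipid_absorption_synthetic.csv", _pchip(LIPID),
        ["Lipid absorption coefficient, mm^-1 at volume fraction 1.0."] + common,
    )
    _write(
        "oxyhemoglobin_absorption_synthetic.csv",
        _pchip(HBO2_EPS) * _EPS_TO_MM_PER_UM,
        ["Oxyhemoglobin absorption coefficient, mm^-1 at 1 uM.",
         "Converted from molar extinction as ln(10)*eps*1e-6*0.1."] + common,
    )
    _write(
        "deoxyhemoglobin_absorption_synthetic.csv",
        _pchip(HHB_EPS) * _EPS_TO_MM_PER_UM,
        ["Deoxyhemoglobin absorption coefficient, mm^-1 at 1 uM.",
         "Converted from molar extinction as ln(10)*eps*1e-6*0.1."] + common,
    )

    mu_a = 0.9 * _pchip(WATER) + 0.1 * _pchip(LIPID)
    mu_s = SCAT_A_800 * (GRID / 800.0) ** (-SCAT_B)
    path = OUT / "intralipid10_properties_synthetic.csv"
    with path.open("w") as fh:
        fh.write("# SYNTHETIC 10% intralipid reference-phantom optical properties.\n")
        fh.write("# mu_a: 0.9*water + 0.1*lipid from the synthetic fixtures above.\n")
        fh.write(f"# mu_s': {SCAT_A_800}*(lambda/800nm)^-{SCAT_B} mm^-1 power law.\n")
        fh.write("# Generated by scripts/make_fixture_spectra.py.\n")
        fh.write("wavelength_nm,mu_a_mm-1,mu_s_prime_mm-1\n")
        for wl, a, s in zip(GRID, mu_a, mu_s):
            fh.write(f"{wl},{a:.6g},{s:.6g}\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
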