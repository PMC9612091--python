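"""Chromophore extinction spectra and Beer's-law concentration unmixing.

Tissue absorption over the near-infrared is modelled as a concentration-
weighted sum of chromophore basis spectra,

    mu_a(lambda) = sum_i c_i * eps_i(lambda),

and concentrations are recovered per pixel by (non-negative) least squares.
Water and lipid are reported in percent volume fraction, hemoglobins in uM;
the packaged fixture spectra (see ``sfdikit/data``) are synthetic
constructions anchored at the standard NIR absorption features.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ChromophoreSpectrum",
    "ChromophoreBasis",
    "ChromophoreMap",
    "load_packaged_spectrum",
    "make_basis",
    "resample_spectrum",
    "synthesize_absorption",
    "fit_concentrations",
    "fit_concentrations_batch",
    "roi_average",
]

PACKAGED = {
    "water": ("water_absorption_synthetic.csv", "percent volume fraction"),
    "lipid": ("lipid_absorption_synthetic.csv", "percent volume fraction"),
    "oxyhemoglobin": ("oxyhemoglobin_absorption_synthetic.csv", "uM"),
    "deoxyhemoglobin": ("deoxyhemoglobin_absorption_synthetic.csv", "uM"),
}


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Absorption coefficient (mm^-1) of one chromophore at unit concentration.

    Unit concentration means volume fraction 1.0 for water/lipid and 1 uM for
    the hemoglobins; ``concentration_unit`` records the *reporting* unit used
    when this spectrum enters a basis (percent for the volume fractions).
    """

    name: str
    wavelengths: np.ndarray
    unit_absorption: np.ndarray
    concentration_unit: str = "percent volume fraction"
    source: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ua = np.asarray(self.unit_absorption, dtype=float)
        if wl.ndim != 1 or wl.shape != ua.shape:
            raise ValueError("wavelengths and unit_absorption must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly ascending")
        if np.any(ua < 0) or not np.all(np.isfinite(ua)):
            raise ValueError(f"{self.name}: unit absorption must be finite and >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "unit_absorption", ua)

    @property
    def reporting_scale(self) -> float:
        """Absorption per reporting unit (divides by 100 for percent fractions)."""
        return 0.01 if "percent" in self.concentration_unit else 1.0


def load_packaged_spectrum(name: str) -> ChromophoreSpectrum:
    """Load one of the packaged fixture spectra: water, lipid, oxy-/deoxyhemoglobin."""
    if name not in PACKAGED:
        raise KeyError(f"unknown chromophore {name!r}; packaged: {sorted(PACKAGED)}")
    fname, unit = PACKAGED[name]
    with resources.files("sfdikit.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, comment="#")
    return ChromophoreSpectrum(
        name, df["wavelength_nm"].to_numpy(), df["value"].to_numpy(),
        concentration_unit=unit, source=f"packaged synthetic fixture {fname}",
    )


def resample_spectrum(
    spectrum: ChromophoreSpectrum, target_grid: np.ndarray
) -> ChromophoreSpectrum:
    """Linear interpolation onto ``target_grid``; exact at shared grid points."""
    grid = np.asarray(target_grid, dtype=float)
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    out = grid[(grid < lo) | (grid > hi)]
    if out.size:
        raise ValueError(
            f"{spectrum.name}: wavelength {out[0]:g} nm outside tabulated "
            f"support [{lo:g}, {hi:g}] nm"
        )
    values = np.interp(grid, spectrum.wavelengths, spectrum.unit_absorption)
    return ChromophoreSpectrum(
        spectrum.name, grid, values, spectrum.concentration_unit, spectrum.source
    )


@dataclass(frozen=True)
class ChromophoreBasis:
    """Ordered chromophore spectra resampled onto one common wavelength grid.

    ``matrix`` (n_wavelengths x n_chromophores) is scaled to reporting units,
    so ``matrix @ concentrations`` with water/lipid in percent and hemoglobins
    in uM yields mu_a in mm^-1.
    """

    grid: np.ndarray
    spectra: tuple[ChromophoreSpectrum, ...]

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        for s in self.spectra:
            if s.wavelengths.shape != grid.shape or not np.allclose(s.wavelengths, grid):
                raise ValueError(f"{s.name}: spectrum not on the basis grid")
        m = self.matrix
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise np.linalg.LinAlgError("chromophore basis is rank deficient on this grid")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.spectra)

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(s.concentration_unit for s in self.spectra)

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack(
            [s.unit_absorption * s.reporting_scale for s in self.spectra]
        )

    @property
    def n_chromophores(self) -> int:
        return len(self.spectra)


def make_basis(names: list[str] | tuple[str, ...], grid: np.ndarray) -> ChromophoreBasis:
    """Build a basis from packaged spectra resampled onto ``grid`` (nm)."""
    spectra = tuple(
        resample_spectrum(load_packaged_spectrum(n), grid) for n in names
    )
    return ChromophoreBasis(np.asarray(grid, dtype=float), spectra)


def synthesize_absorption(basis: ChromophoreBasis, concentrations) -> np.ndarray:
    """mu_a(lambda) = sum_i c_i eps_i(lambda) on the basis grid, mm^-1."""
    c = np.asarray(concentrations, dtype=float)
    if c.shape != (basis.n_chromophores,):
        raise ValueError(
            f"expected {basis.n_chromophores} concentrations, got shape {c.shape}"
        )
    if not np.all(np.isfinite(c)):
        raise ValueError("concentrations must be finite")
    return basis.matrix @ c


def fit_concentrations(
    mu_a_spectrum: np.ndarray,
    basis: ChromophoreBasis,
    nonneg: bool = True,
    min_wavelengths: int | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares Beer's-law fit of one absorption spectrum.

    Returns (concentrations in reporting units, RMS residual in mm^-1).
    NaN wavelengths are masked out; fitting proceeds if at least
    ``min_wavelengths`` (default: number of chromophores) remain.
    """
    y = np.asarray(mu_a_spectrum, dtype=float)
    if y.shape != basis.grid.shape:
        raise ValueError("spectrum length does not match basis grid")
    k = basis.n_chromophores
    min_wavelengths = k if min_wavelengths is None else min_wavelengths
    mask = np.isfinite(y)
    if mask.sum() < min_wavelengths:
        raise ValueError(
            f"only {int(mask.sum())} finite wavelengths; need >= {min_wavelengths}"
        )
    E = basis.matrix[mask]
    yv = y[mask]
    if nonneg:
        c, _ = nnls(E, yv)
    else:
        c, *_ = np.linalg.lstsq(E, yv, rcond=None)
    resid = yv - E @ c
    return c, float(np.sqrt(np.mean(resid**2)))


def fit_concentrations_batch(
    spectra: np.ndarray, basis: ChromophoreBasis, nonneg: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized Beer's-law fit of many spectra (n_samples x n_wavelengths).

    The unconstrained normal-equation solution is computed for all rows at
    once; only rows with a negative component are re-solved with NNLS (the
    two coincide whenever the unconstrained optimum is already feasible).
    Returns (concentrations, rms residuals, number of NNLS fallbacks).
    """
    Y = np.asarray(spectra, dtype=float)
    E = basis.matrix
    if Y.ndim != 2 or Y.shape[1] != E.shape[0]:
        raise ValueError("spectra must be (n_samples, n_wavelengths) on the basis grid")
    gram_inv = np.linalg.inv(E.T @ E)
    C = Y @ E @ gram_inv
    n_clipped = 0
    if nonneg:
        neg = np.any(C < 0, axis=1)
        n_clipped = int(np.count_nonzero(neg))
        for i in np.flatnonzero(neg):
            C[i], _ = nnls(E, Y[i])
    resid = Y - C @ E.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return C, rms, n_clipped


@dataclass
class ChromophoreMap:
    """Per-pixel concentration maps, one image per basis chromophore."""

    names: tuple[str, ...]
    units: tuple[str, ...]
    maps: np.ndarray  # (n_chromophores, H, W)
    pixel_pitch: float  # mm / pixel
    residual_rms: np.ndarray | None = None  # (H, W), mm^-1


def roi_average(
    cmap: ChromophoreMap,
    center: tuple[float, float],
    diameter: float,
) -> pd.DataFrame:
    """Mean/sd of each chromophore over a circular region of interest.

    ``center`` is (row, col) in pixels, ``diameter`` in mm; a pixel belongs to
    the ROI when its center lies within the circle.  NaN pixels are excluded
    and counted.  A sub-pixel diameter degenerates to the single pixel
    containing the center.
    """
    if cmap.pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    h, w = cmap.maps.shape[1:]
    r_px = 0.5 * diameter / cmap.pixel_pitch
    cr, cc = center
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError(f"ROI center {center} outside image of shape {(h, w)}")
    if cr - r_px < -0.5 or cr + r_px > h - 0.5 or cc - r_px < -0.5 or cc + r_px > w - 0.5:
        raise ValueError("ROI circle extends outside the image")
    rows, cols = np.mgrid[0:h, 0:w]
    inside = (rows - cr) ** 2 + (cols - cc) ** 2 <= r_px**2
    if not inside.any():
        inside[int(round(cr)), int(round(cc))] = True
    records = []
    for name, unit, img in zip(cmap.names, cmap.units, cmap.maps):
        vals = img[inside]
        finite = vals[np.isfinite(vals)]
        records.append({
            "chromophore": name,
            "unit": unit,
            "mean": float(np.mean(finite)),
            "sd": float(np.std(finite)),
            "n_pixels": int(finite.size),
            "n_nan": int(vals.size - finite.size),
        })
    return pd.DataFrame.from_records(records)
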