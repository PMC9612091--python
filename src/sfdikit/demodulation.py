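"""Demodulation and calibration of structured-illumination frame stacks.

Three sinusoidal patterns shifted 120 deg in phase are reduced to a per-pixel
AC amplitude; a "white"/"black" pair provides the planar (fx = 0) component.
Calibration against a reference phantom of known optical properties converts
demodulated intensity to absolute diffuse reflectance:

    Rd(fx) = I(fx) / I_ref(fx) * Rd_ref_predicted(fx).

Any global gain common to sample and reference cancels in the ratio, as does
the demodulation prefactor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "demodulate_ac",
    "demodulate_dc",
    "calibrate",
    "drift_correct",
]

# sqrt(2)/3 makes the three-phase formula return exactly the sinusoidal
# amplitude; any constant here cancels in calibration.
AC_PREFACTOR = np.sqrt(2.0) / 3.0


def _check_shapes(*imgs: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(i, dtype=float) for i in imgs]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"frames must share shape, got {sorted(shapes)}")
    return arrs


def demodulate_ac(i1, i2, i3) -> np.ndarray:
    """AC amplitude from three frames at 0/120/240 deg pattern phase.

    For frames a + m*cos(theta + phase_k) this returns exactly m at every
    pixel, independent of the offset a and the spatial phase theta.
    """
    i1, i2, i3 = _check_shapes(i1, i2, i3)
    return AC_PREFACTOR * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )


def demodulate_dc(white, black) -> np.ndarray:
    """Planar-illumination component: white minus black (dark), floored at 0."""
    white, black = _check_shapes(white, black)
    return np.maximum(white - black, 0.0)


def calibrate(
    i_sample: np.ndarray,
    i_ref: np.ndarray,
    rd_ref_pred,
) -> np.ndarray:
    """Demodulated sample over demodulated reference, scaled by predicted Rd.

    ``rd_ref_pred`` is the reference phantom's forward-model reflectance at
    the same wavelength and spatial frequency (scalar or image, in (0,1)).
    Non-positive reference pixels yield NaN (flagged); an all-non-positive
    reference is an error.
    """
    i_sample, i_ref = _check_shapes(i_sample, i_ref)
    rd_ref_pred = np.asarray(rd_ref_pred, dtype=float)
    if np.any(rd_ref_pred <= 0) or np.any(rd_ref_pred >= 1):
        raise ValueError("predicted reference reflectance must lie in (0,1)")
    good = i_ref > 0
    if not good.any():
        raise ValueError("reference image has no positive pixels")
    out = np.full_like(i_sample, np.nan)
    np.divide(i_sample, i_ref, out=out, where=good)
    return out * rd_ref_pred


def drift_correct(
    rd_series: np.ndarray,
    tile_roi: tuple[slice, slice],
    baseline_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove source drift using an in-field reference tile.

    ``rd_series`` has time as the leading axis (T, H, W) — one series per
    (wavelength, fx).  Each time point is multiplied by
    mean(tile at baseline)/mean(tile at t), so the tile mean is exactly
    restored to its baseline value at every time point.  A drift that is
    multiplicative and global is removed exactly everywhere; drift confined
    outside the tile is (by construction) not corrected.

    Returns (corrected series, per-time correction factors).
    """
    series = np.asarray(rd_series, dtype=float)
    if series.ndim != 3:
        raise ValueError("rd_series must be (time, H, W)")
    if not (0 <= baseline_index < series.shape[0]):
        raise IndexError(f"baseline index {baseline_index} outside series")
    tile = series[(slice(None), *tile_roi)]
    if tile.shape[1] == 0 or tile.shape[2] == 0:
        raise ValueError("tile ROI selects no pixels")
    means = np.nanmean(tile, axis=(1, 2))
    if np.any(means <= 0) or not np.all(np.isfinite(means)):
        raise ValueError("tile mean must be positive and finite at every time point")
    factors = means[baseline_index] / means
    return series * factors[:, None, None], factors
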