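"""Synthetic scenes and an SFDI acquisition renderer for closed-loop testing.

The renderer inverts the processing chain: per pixel and wavelength it builds
absorption from the scene's chromophore concentrations, reduced scattering
from a power law, evaluates the forward reflectance at each spatial
frequency, and composes raw camera frames

    I_k   = gain * (Rd(0)*DC + Rd(fx)*AC*cos(2 pi fx x + phi_k)) + dark + noise
    white = gain * Rd(0)*(DC + AC) + dark + noise
    black = dark + noise

together with an identically rendered reference-phantom stack.  With zero
noise the demodulate -> calibrate chain recovers the scene's forward-model
reflectance to floating-point rounding, which is the module's defining
guarantee; scene templates mirror the validation experiments (homogeneous
water/lipid phantoms, a two-region lipid patch, an injection-blob time
series) without reproducing any measured dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .optics import rd_forward
from .spectra import load_packaged_spectrum, resample_spectrum
from .stack_io import AC_PATTERNS, RawFrameStack

__all__ = [
    "Scene",
    "AcquisitionSpec",
    "reference_phantom_properties",
    "make_scene",
    "render_stack",
    "render_time_series",
    "SCENE_TEMPLATES",
]

SCENE_TEMPLATES = ("homogeneous", "two_region", "injection")


@dataclass
class Scene:
    """Ground-truth per-pixel chromophore and scattering description.

    ``concentrations`` maps chromophore name to a (H, W) map in reporting
    units (percent for water/lipid, uM for hemoglobins).  Scattering follows
    mu_s'(lambda) = amplitude * (lambda/1000 nm)^(-power) per pixel.  An
    optional ``tile_region`` marks a correction tile rendered with the
    reference phantom's properties instead of the scene's.
    """

    concentrations: dict[str, np.ndarray]
    scatter_amplitude: np.ndarray  # mm^-1 at 1000 nm, (H, W)
    scatter_power: np.ndarray  # dimensionless, (H, W)
    pixel_pitch: float = 0.1  # mm / pixel
    tile_region: tuple[slice, slice] | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.concentrations.values()}
        shapes |= {self.scatter_amplitude.shape, self.scatter_power.shape}
        if len(shapes) != 1:
            raise ValueError("all scene maps must share one shape")
        for name, m in self.concentrations.items():
            if np.any(m < 0):
                raise ValueError(f"{name}: concentrations must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scatter_amplitude.shape

    def optical_properties(self, wavelength: float) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (mu_a, mu_s') maps at one wavelength, mm^-1."""
        mu_a = np.zeros(self.shape)
        for name, conc in self.concentrations.items():
            spec = load_packaged_spectrum(name)
            eps = resample_spectrum(spec, np.array([wavelength])).unit_absorption[0]
            mu_a = mu_a + conc * eps * spec.reporting_scale
        mu_s = self.scatter_amplitude * (wavelength / 1000.0) ** (-self.scatter_power)
        return mu_a, mu_s


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry, illumination levels and camera noise."""

    wavelengths: tuple[float, ...] = tuple(np.arange(900.0, 1001.0, 5.0))
    fx_pair: tuple[float, float] = (0.0, 0.2)  # mm^-1
    dc_level: float = 1000.0  # counts
    ac_level: float = 500.0  # counts
    gain: float = 1.0
    dark_level: float = 50.0  # counts
    noise_sd: float = 2.0  # counts, additive Gaussian; 0 disables
    exposure_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.fx_pair[0] == self.fx_pair[1]:
            raise ValueError("fx_pair must be distinct")
        if self.dc_level <= 0 or self.ac_level <= 0:
            raise ValueError("illumination levels must be positive")


def reference_phantom_properties(
    wavelengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(mu_a, mu_s') of the packaged 10% intralipid reference phantom, mm^-1."""
    with resources.files("sfdikit.data").joinpath(
        "intralipid10_properties_synthetic.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#")
    wl = np.asarray(wavelengths, dtype=float)
    tab = df["wavelength_nm"].to_numpy()
    if wl.min() < tab.min() or wl.max() > tab.max():
        raise ValueError("wavelength outside reference-phantom table support")
    mu_a = np.interp(wl, tab, df["mu_a_mm-1"].to_numpy())
    mu_s = np.interp(wl, tab, df["mu_s_prime_mm-1"].to_numpy())
    return mu_a, mu_s


def make_scene(template: str, seed: int = 0, shape: tuple[int, int] = (64, 64),
               pixel_pitch: float = 0.1, **params):
    """Build a named ground-truth scene (deterministic under ``seed``).

    Templates
    ---------
    homogeneous : uniform water/lipid phantom.
        params: water (percent, default 90), lipid (default 10),
        scatter_amplitude (default 0.18*lipid mm^-1 at 1000 nm — scattering
        scales with the lipid emulsion content), scatter_power (default 2.4),
        with_tile (default False).
    two_region : left/right halves with distinct (water, lipid).
        params: water_a/lipid_a (default 90/10), water_b/lipid_b (default 70/30).
    injection : time series of a Gaussian water blob growing over baseline.
        params: n_times (default 5), baseline_water (default 60), lipid
        (default 20), blob_amplitude (percent water added at final time,
        default 15), blob_sigma_mm (default 1.0).  Returns a list of Scenes.
    """
    if template not in SCENE_TEMPLATES:
        raise ValueError(f"unknown template {template!r}; available: {SCENE_TEMPLATES}")
    h, w = shape
    full = np.full((h, w), 1.0)

    def _uniform(water, lipid, scatter_amplitude=None, scatter_power=2.4):
        if scatter_amplitude is None:
            scatter_amplitude = 0.18 * lipid
        return Scene(
            {"water": full * water, "lipid": full * lipid},
            scatter_amplitude=full * scatter_amplitude,
            scatter_power=full * scatter_power,
            pixel_pitch=pixel_pitch,
        )

    if template == "homogeneous":
        scene = _uniform(
            params.get("water", 90.0), params.get("lipid", 10.0),
            params.get("scatter_amplitude"), params.get("scatter_power", 2.4),
        )
        if params.get("with_tile"):
            t = max(2, h // 8)
            scene.tile_region = (slice(0, t), slice(0, t))
        return scene

    if template == "two_region":
        water = np.where(np.arange(w) < w // 2,
                         params.get("water_a", 90.0), params.get("water_b", 70.0))
        lipid = np.where(np.arange(w) < w // 2,
                         params.get("lipid_a", 10.0), params.get("lipid_b", 30.0))
        return Scene(
            {"water": np.broadcast_to(water, (h, w)).copy(),
             "lipid": np.broadcast_to(lipid, (h, w)).copy()},
            scatter_amplitude=full * params.get("scatter_amplitude", 2.0),
            scatter_power=full * params.get("scatter_power", 2.4),
            pixel_pitch=pixel_pitch,
        )

    # injection: baseline scene plus a growing Gaussian water blob
    n_times = params.get("n_times", 5)
    base_water = params.get("baseline_water", 60.0)
    lipid = params.get("lipid", 20.0)
    amp = params.get("blob_amplitude", 15.0)
    sigma_px = params.get("blob_sigma_mm", 1.0) / pixel_pitch
    rows, cols = np.mgrid[0:h, 0:w]
    blob = np.exp(-((rows - h / 2) ** 2 + (cols - w / 2) ** 2) / (2 * sigma_px**2))
    scenes = []
    base = _uniform(base_water, lipid, params.get("scatter_amplitude", 2.0))
    for t in range(n_times):
        frac = t / max(n_times - 1, 1)
        conc = dict(base.concentrations)
        conc["water"] = base.concentrations["water"] + amp * frac * blob
        scenes.append(replace(base, concentrations=conc))
    return scenes


def _compose_frames(
    rd0: np.ndarray, rdf: np.ndarray, acq: AcquisitionSpec, x_mm: np.ndarray,
    gain: float, rng: np.random.Generator | None,
) -> dict[str, np.ndarray]:
    fx = acq.fx_pair[1] if acq.fx_pair[0] == 0 else acq.fx_pair[0]

    def _noise(shape):
        if rng is None or acq.noise_sd == 0:
            return 0.0
        return rng.normal(0.0, acq.noise_sd, shape)

    frames = {}
    for k, pat in enumerate(AC_PATTERNS):
        phi = 2.0 * np.pi * k / 3.0
        img = gain * (rd0 * acq.dc_level
                      + rdf * acq.ac_level * np.cos(2 * np.pi * fx * x_mm + phi))
        frames[pat] = np.maximum(img + acq.dark_level + _noise(img.shape), 0.0)
    white = gain * rd0 * (acq.dc_level + acq.ac_level) + acq.dark_level
    frames["white"] = np.maximum(white + _noise(white.shape), 0.0)
    frames["black"] = np.maximum(
        np.full_like(rd0, acq.dark_level) + _noise(rd0.shape), 0.0)
    return frames


def render_stack(
    scene: Scene,
    acq: AcquisitionSpec | None = None,
    seed: int | None = None,
    drift_factor: float = 1.0,
    timestamp: float = 0.0,
) -> tuple[RawFrameStack, RawFrameStack]:
    """Render (sample stack, reference-phantom stack) for one time point.

    ``drift_factor`` multiplies the illumination gain, emulating source
    drift; the reference stack is rendered drift-free (it is acquired once,
    at calibration time).  Deterministic under ``seed``; ``seed=None`` gives
    a noiseless render only if ``acq.noise_sd == 0``.
    """
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed) if acq.noise_sd > 0 else None
    f0, f1 = acq.fx_pair
    if f0 != 0:
        raise ValueError("renderer expects the planar frequency (0) in the pair")
    h, w = scene.shape
    x_mm = np.arange(w) * scene.pixel_pitch * np.ones((h, 1))
    wavelengths = np.asarray(acq.wavelengths, dtype=float)
    ref_mu_a, ref_mu_s = reference_phantom_properties(wavelengths)

    sample_frames: dict = {}
    ref_frames: dict = {}
    for i, wl in enumerate(wavelengths):
        mu_a, mu_s = scene.optical_properties(wl)
        if np.any(mu_a <= 0):
            raise ValueError(f"non-positive absorption at {wl} nm; scene invalid")
        if scene.tile_region is not None:
            mu_a = mu_a.copy()
            mu_s = mu_s.copy()
            mu_a[scene.tile_region] = ref_mu_a[i]
            mu_s[scene.tile_region] = ref_mu_s[i]
        rd0 = rd_forward(mu_a, mu_s, 0.0)
        rdf = rd_forward(mu_a, mu_s, f1)
        for pat, img in _compose_frames(
                rd0, rdf, acq, x_mm, acq.gain * drift_factor, rng).items():
            fx = 0.0 if pat in ("white", "black") else f1
            sample_frames[(wl, fx, pat)] = img

        r0 = np.full((h, w), rd_forward(ref_mu_a[i], ref_mu_s[i], 0.0))
        rf = np.full((h, w), rd_forward(ref_mu_a[i], ref_mu_s[i], f1))
        for pat, img in _compose_frames(r0, rf, acq, x_mm, acq.gain, rng).items():
            fx = 0.0 if pat in ("white", "black") else f1
            ref_frames[(wl, fx, pat)] = img

    mk = dict(pixel_pitch=scene.pixel_pitch, exposure_ms=acq.exposure_ms,
              timestamp=timestamp)
    return (RawFrameStack(sample_frames, **mk, meta={"kind": "sample"}),
            RawFrameStack(ref_frames, **mk, meta={"kind": "reference"}))


def render_time_series(
    scenes: list[Scene],
    acq: AcquisitionSpec | None = None,
    seed: int | None = None,
    drift: list[float] | None = None,
) -> tuple[list[RawFrameStack], RawFrameStack]:
    """Render a time series of sample stacks plus one shared reference stack."""
    acq = acq or AcquisitionSpec()
    drift = drift if drift is not None else [1.0] * len(scenes)
    if len(drift) != len(scenes):
        raise ValueError("drift must give one factor per time point")
    stacks = []
    ref_stack = None
    for t, (scene, g) in enumerate(zip(scenes, drift)):
        s_seed = None if seed is None else seed + t
        sample, ref = render_stack(scene, acq, seed=s_seed, drift_factor=g,
                                   timestamp=float(t))
        stacks.append(sample)
        if ref_stack is None:
            ref_stack = ref
    return stacks, ref_stack
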