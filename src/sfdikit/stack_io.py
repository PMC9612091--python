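"""Raw frame-stack container and TIFF + JSON-manifest serialization.

A raw acquisition is a set of camera frames indexed by (wavelength, spatial
frequency, pattern): three 120-deg-shifted sinusoidal patterns per nonzero
frequency and a white/black pair for planar illumination.  Stacks round-trip
losslessly through a multi-page TIFF plus a JSON manifest mapping page index
to its (wavelength, fx, pattern) key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["RawFrameStack", "write_stack", "read_stack", "AC_PATTERNS", "DC_PATTERNS"]

AC_PATTERNS = ("phase0", "phase120", "phase240")
DC_PATTERNS = ("white", "black")

FrameKey = tuple[float, float, str]  # (wavelength nm, fx mm^-1, pattern)


@dataclass
class RawFrameStack:
    """Camera frames keyed by (wavelength nm, fx mm^-1, pattern id)."""

    frames: dict[FrameKey, np.ndarray]
    pixel_pitch: float  # mm / pixel in the sample plane
    exposure_ms: float = 50.0
    timestamp: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        self.validate()

    def validate(self) -> None:
        shapes = {f.shape for f in self.frames.values()}
        if len(shapes) > 1:
            raise ValueError(f"all frames must share shape, got {sorted(shapes)}")
        for f in self.frames.values():
            if np.any(np.asarray(f) < 0):
                raise ValueError("pixel values must be >= 0")
        for wl in self.wavelengths:
            for fx in self.frequencies(wl):
                pats = {p for (w, f, p) in self.frames if w == wl and f == fx}
                want = set(DC_PATTERNS) if fx == 0 else set(AC_PATTERNS)
                if pats != want:
                    raise ValueError(
                        f"(wavelength {wl} nm, fx {fx} mm^-1): expected patterns "
                        f"{sorted(want)}, found {sorted(pats)}"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.frames.values())).shape

    @property
    def wavelengths(self) -> list[float]:
        return sorted({wl for (wl, _, _) in self.frames})

    def frequencies(self, wavelength: float) -> list[float]:
        return sorted({fx for (wl, fx, _) in self.frames if wl == wavelength})

    def frame(self, wavelength: float, fx: float, pattern: str) -> np.ndarray:
        return self.frames[(wavelength, fx, pattern)]


def write_stack(stack: RawFrameStack, path: str | Path) -> None:
    """Write frames as a multi-page 32-bit float TIFF with a JSON manifest."""
    path = Path(path)
    keys = sorted(stack.frames)
    with tifffile.TiffWriter(path) as tw:
        for k in keys:
            tw.write(stack.frames[k].astype(np.float32), contiguous=False)
    manifest = {
        "pixel_pitch_mm": stack.pixel_pitch,
        "exposure_ms": stack.exposure_ms,
        "timestamp": stack.timestamp,
        "meta": stack.meta,
        "pages": [
            {"page": i, "wavelength_nm": k[0], "fx_mm^-1": k[1], "pattern": k[2]}
            for i, k in enumerate(keys)
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def read_stack(path: str | Path) -> RawFrameStack:
    """Read a stack written by :func:`write_stack`; validates completeness."""
    path = Path(path)
    manifest_path = path.with_suffix(path.suffix + ".json")
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    frames: dict[FrameKey, np.ndarray] = {}
    for entry in manifest["pages"]:
        try:
            idx = entry["page"]
            key = (float(entry["wavelength_nm"]), float(entry["fx_mm^-1"]),
                   str(entry["pattern"]))
        except KeyError as exc:
            raise ValueError(f"malformed manifest entry {entry}: missing {exc}") from exc
        if idx >= len(pages):
            raise ValueError(f"manifest page {idx} beyond TIFF with {len(pages)} pages")
        frames[key] = np.asarray(pages[idx], dtype=np.float64)
    return RawFrameStack(
        frames,
        pixel_pitch=manifest["pixel_pitch_mm"],
        exposure_ms=manifest.get("exposure_ms", 50.0),
        timestamp=manifest.get("timestamp", 0.0),
        meta=manifest.get("meta", {}),
    )
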