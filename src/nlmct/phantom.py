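"""Synthetic low-dose-CT-like phantoms.

Clinical low-dose scans are degraded by mottled (grainy) noise plus
directional streak artifacts radiating through the image.  This module
builds clean ellipse phantoms on a 0–255 display scale — an abdomen-like
body outline with a few internal "organs" and a small bright lesion — and
degrades them with seeded Gaussian noise and additive oriented ridge
streaks through the image center.  The degradation is a stand-in with the
right statistical character (correlated, structured corruption), not a
projection-domain simulation: no Radon transform, photon statistics or
reconstruction physics are modelled.

Every function is a deterministic map of its spec (the noise uses the
spec's seed), so demos and tests reproduce bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

import numpy as np

from .core import validate_image

__all__ = ["Ellipse", "PhantomSpec", "default_ellipses", "make_phantom", "add_low_dose_noise"]

# (center_x, center_y, semi_axis_a, semi_axis_b, angle_degrees, intensity),
# centers and axes in pixels
Ellipse = Tuple[float, float, float, float, float, float]


def default_ellipses(size: int) -> Tuple[Ellipse, ...]:
    """Abdomen-like layout scaled to the grid: body, two organs, a lesion."""
    s = float(size)
    return (
        (0.50 * s, 0.50 * s, 0.42 * s, 0.34 * s, 0.0, 120.0),   # body outline
        (0.36 * s, 0.44 * s, 0.16 * s, 0.11 * s, 20.0, 160.0),  # bright organ
        (0.64 * s, 0.52 * s, 0.13 * s, 0.17 * s, -15.0, 90.0),  # darker organ
        (0.52 * s, 0.66 * s, 0.10 * s, 0.05 * s, 0.0, 60.0),    # low-density pocket
        (0.40 * s, 0.58 * s, 0.035 * s, 0.035 * s, 0.0, 200.0), # small lesion
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and degradation parameters of one synthetic study image.

    Intensities live on the 0–255 display scale so the default smoothing
    strength h = 10 keeps the same relative meaning as on windowed CT
    display values.  ``noise_sigma`` is the Gaussian noise SD in intensity
    units; streaks are 1–2 pixel wide additive ridges of peak amplitude
    ``streak_amplitude`` at seeded random angles through the center.
    """

    size: int = 128
    ellipses: Tuple[Ellipse, ...] | None = None  # None -> default_ellipses(size)
    background: float = 40.0
    noise_sigma: float = 15.0
    streak_count: int = 8
    streak_amplitude: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.size, int) and self.size >= 8):
            raise ValueError(f"phantom size must be an integer >= 8, got {self.size!r}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be non-negative, got {self.noise_sigma!r}")
        if not (isinstance(self.streak_count, int) and self.streak_count >= 0):
            raise ValueError(f"streak_count must be a non-negative integer, got {self.streak_count!r}")
        if not np.isfinite(self.streak_amplitude):
            raise ValueError("streak_amplitude must be finite")
        for e in self.resolved_ellipses():
            _, _, a, b, _, _ = e
            if not (a > 0 and b > 0 and np.all(np.isfinite(e))):
                raise ValueError(f"invalid ellipse geometry {e!r}: semi-axes must be positive")

    def resolved_ellipses(self) -> Tuple[Ellipse, ...]:
        return default_ellipses(self.size) if self.ellipses is None else tuple(self.ellipses)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["ellipses"] = [list(e) for e in self.resolved_ellipses()]
        return d


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the clean phantom: background, then ellipses in order.

    Later ellipses overwrite earlier ones where they overlap.  Purely
    deterministic — no randomness enters here.  Values clipped to [0, 255].
    """
    s = spec.size
    img = np.full((s, s), float(spec.background))
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for cx, cy, a, b, angle, intensity in spec.resolved_ellipses():
        th = math.radians(angle)
        dx, dy = xx - cx, yy - cy
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = float(intensity)
    return np.clip(img, 0.0, 255.0)


def add_low_dose_noise(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Degrade *img* with seeded mottle noise and streak artifacts.

    Adds i.i.d. Gaussian noise of SD ``noise_sigma`` plus ``streak_count``
    straight ridges through the image center at seeded uniform-random
    angles; each ridge has a Gaussian cross-profile of ~1.5 px FWHM and
    peak ``streak_amplitude``.  Output clipped to [0, 255]; the same spec
    (and thus seed) always produces the same output.
    """
    img = validate_image(img)
    rng = np.random.default_rng(spec.seed)
    out = img.copy()
    if spec.noise_sigma > 0:
        out += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    if spec.streak_count > 0:
        m, n = img.shape
        cy, cx = (m - 1) / 2.0, (n - 1) / 2.0
        yy, xx = np.mgrid[0:m, 0:n].astype(np.float64)
        width = 0.65  # Gaussian sigma in px -> ridge ~1.5 px FWHM
        for _ in range(spec.streak_count):
            theta = rng.uniform(0.0, math.pi)
            # signed distance from the line through the center at angle theta
            dist = (xx - cx) * math.sin(theta) - (yy - cy) * math.cos(theta)
            out += spec.streak_amplitude * np.exp(-(dist**2) / (2.0 * width**2))
    return np.clip(out, 0.0, 255.0)
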