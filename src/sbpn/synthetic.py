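"""Seeded grayscale phantoms emulating flat-background medical images.

Real radiological samples (X-ray, CT, MRI slices) are dominated by a large
near-constant background with a handful of piecewise-near-constant
anatomical regions -- exactly the run-length redundancy the cosimilar coder
exploits.  The generator composes a flat background, R elliptical or
polygonal regions drawn from a small intensity palette, an optional smooth
linear gradient, and optional additive Gaussian noise, then clips and
rounds to 8 bits.  Identical spec + seed always yields the identical image.

Noise is a documented stress case (it destroys runs), so the default sigma
is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.draw import polygon as _polygon

from .image_io import GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite",
           "generate_redundancy_sweep"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom.

    ``background_fraction`` is the approximate share of pixels left at the
    background intensity: region areas are scaled so the regions jointly
    target the remaining share (overlap can leave slightly more background).
    """

    dims: tuple[int, int] = (512, 512)
    regions: int = 4
    palette: int = 5
    background_fraction: float = 0.7
    shape: str = "ellipse"  # ellipse | polygon
    gradient_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        m, n = self.dims
        if m < 1 or n < 1:
            raise ValueError("dims must be positive")
        if self.regions < 0:
            raise ValueError("regions must be >= 0")
        if self.palette < 1:
            raise ValueError("palette must hold at least the background value")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.shape not in ("ellipse", "polygon"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render one phantom from its spec (deterministic given the seed)."""
    m, n = spec.dims
    rng = np.random.default_rng(spec.seed)
    # small, well-separated intensity palette; index 0 is the background
    levels = np.linspace(24, 232, spec.palette)
    palette = np.rint(levels + rng.uniform(-8, 8, spec.palette)).astype(np.int64)
    palette = np.clip(palette, 0, 255)
    canvas = np.full((m, n), float(palette[0]))

    if spec.regions > 0 and spec.background_fraction < 1.0:
        target_area = (1.0 - spec.background_fraction) * m * n
        # Regions sit on a jittered grid, one per cell, so they stay well
        # separated (like distinct anatomical structures) and so that every
        # random draw is independent of the background fraction: sweeping
        # the fraction only rescales radii around fixed centres.
        g = math.ceil(math.sqrt(spec.regions))
        weights = rng.uniform(0.5, 1.5, spec.regions)
        areas = target_area * weights / weights.sum()
        params = [_sample_region(rng, spec.shape, i, g, m, n)
                  for i in range(spec.regions)]
        for i, p in enumerate(params):
            intensity = float(palette[1 + i % max(spec.palette - 1, 1)])
            if spec.shape == "ellipse":
                _draw_ellipse(canvas, areas[i], intensity, **p)
            else:
                _draw_polygon(canvas, areas[i], intensity, **p)

    if spec.gradient_amplitude:
        yy = np.linspace(0.0, 1.0, m)[:, None]
        xx = np.linspace(0.0, 1.0, n)[None, :]
        canvas = canvas + spec.gradient_amplitude * (xx + yy) / 2.0

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=(m, n))

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return GrayImage(pixels)


def _sample_region(rng, shape: str, index: int, grid: int, m: int, n: int) -> dict:
    """All random parameters of one region, drawn before any area is known."""
    gi, gj = divmod(index, grid)
    cell_h, cell_w = m / grid, n / grid
    cy = (gi + 0.5) * cell_h + rng.uniform(-1.0, 1.0) * cell_h / 8.0
    cx = (gj + 0.5) * cell_w + rng.uniform(-1.0, 1.0) * cell_w / 8.0
    if shape == "ellipse":
        return {"cy": cy, "cx": cx,
                "ratio": rng.uniform(0.7, 1.4),
                "rot": rng.uniform(0.0, math.pi)}
    n_vert = int(rng.integers(5, 9))
    return {"cy": cy, "cx": cx,
            "angles": np.sort(rng.uniform(0.0, 2.0 * math.pi, n_vert)),
            "radii_rel": rng.uniform(0.6, 1.0, n_vert)}


def _draw_ellipse(canvas: np.ndarray, area: float, intensity: float, *,
                  cy: float, cx: float, ratio: float, rot: float) -> None:
    m, n = canvas.shape
    r_minor = math.sqrt(area / (math.pi * ratio))
    r_major = ratio * r_minor
    if 2 * r_major > min(m, n):
        raise ValueError(
            f"region (major axis {2 * r_major:.0f}) larger than image {m}x{n}"
        )
    rr, cc = _ellipse(cy, cx, r_major, r_minor, shape=canvas.shape, rotation=rot)
    canvas[rr, cc] = intensity


def _draw_polygon(canvas: np.ndarray, area: float, intensity: float, *,
                  cy: float, cx: float, angles: np.ndarray,
                  radii_rel: np.ndarray) -> None:
    m, n = canvas.shape
    # star-convex polygon around the centre; base radius set to hit the area
    unit_area = 0.5 * np.sum(
        radii_rel * np.roll(radii_rel, -1) * np.abs(np.sin(np.diff(
            np.concatenate((angles, [angles[0] + 2 * math.pi])))))
    )
    base_r = math.sqrt(area / unit_area)
    if 2 * base_r > min(m, n):
        raise ValueError(f"region (span {2 * base_r:.0f}) larger than image {m}x{n}")
    rr, cc = _polygon(cy + base_r * radii_rel * np.sin(angles),
                      cx + base_r * radii_rel * np.cos(angles),
                      shape=canvas.shape)
    canvas[rr, cc] = intensity


def generate_suite(n_images: int, base_spec: PhantomSpec | None = None,
                   seed: int = 0) -> list[GrayImage]:
    """A deterministic suite of distinct phantoms (the test-sample stand-in).

    Per-image seeds are derived from ``seed`` so two calls with the same
    arguments return identical suites.
    """
    base_spec = base_spec or PhantomSpec()
    children = np.random.SeedSequence(seed).generate_state(n_images) % (2 ** 31)
    return [
        generate_phantom(replace(base_spec, seed=int(s))) for s in children
    ]


def generate_redundancy_sweep(fractions, base_spec: PhantomSpec | None = None,
                              seed: int = 0) -> list[GrayImage]:
    """Phantoms sharing one region layout, sweeping the background fraction.

    All randomness (region placement, palette, shapes) is held fixed by the
    single seed; only the background fraction varies, so run-length
    redundancy increases monotonically along the sweep.
    """
    base_spec = base_spec or PhantomSpec()
    return [
        generate_phantom(replace(base_spec, background_fraction=float(f), seed=seed))
        for f in fractions
    ]
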