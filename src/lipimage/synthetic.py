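"""Synthetic fixtures: every test input the package needs, generated in code.

Four kinds of fixture cover the enhancement workflows end to end without
any external data:

* ``ramp_chart`` — a horizontal linear grey ramp spanning the full scale,
  the classic chart on which tone profiles and their LIP opposites are
  inspected.
* ``low_light`` — a well-exposed base image darkened *in the tone domain*
  with a LIP operation, emulating a shorter exposure time: either
  ``λ ⊗ f`` with λ > 1 (thicker obstacle) or ``f ⊕ C`` (an extra uniform
  filter).  The ground-truth darkening parameter is returned with the
  image so enhancement tests can do parameter recovery.
* ``colour_scene`` — a smooth random RGB scene of limited dynamic range
  (sums of Gaussian blobs per channel), seeded and reproducible.
* ``slice_stack`` — a short stack of dim slices of a drifting Gaussian
  blob, shaped like anisotropic tomographic data (in-plane resolution
  finer than the slice spacing).

All fixtures are deterministic functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import (
    GreyScale,
    IntensityImage,
    LIPError,
    ToneImage,
    from_tone,
    lip_add,
    lip_negate,
    lip_scalar_mul,
    to_tone,
)
from .interp import SliceStack

__all__ = [
    "FixtureSpec",
    "LowLightFixture",
    "generate_ramp_chart",
    "ramp_profile",
    "generate_low_light",
    "generate_colour_scene",
    "generate_slice_stack",
    "generate_fixture",
]

KINDS = ("ramp_chart", "low_light", "colour_scene", "slice_stack")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a reproducible fixture.

    ``darkening`` is the exposure-simulation parameter: a thickness
    factor λ > 1 for ``mode="scalar"`` or a uniform tone C ∈ [0, M[ for
    ``mode="additive"``.
    """

    kind: str = "ramp_chart"
    shape: tuple = (32, 256)
    scale: GreyScale = GreyScale(256.0)
    seed: int = 0
    darkening: float = 2.0
    darkening_mode: str = "scalar"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")


class LowLightFixture(NamedTuple):
    image: IntensityImage
    mode: str
    parameter: float


def generate_ramp_chart(
    width: int = 256, height: int = 32, scale: GreyScale = GreyScale(256.0)
) -> IntensityImage:
    """Horizontal linear ramp covering the full scale.

    Tones run 0 (left, white) to M-1 (right, black); intensities are the
    inverted values actually stored.  Width must allow at least 2 steps.
    """
    if width < 2:
        raise ValueError("ramp needs width >= 2")
    tones = np.rint(np.linspace(0.0, scale.max_intensity, width))
    field = np.tile(tones, (height, 1))
    return from_tone(ToneImage(field, scale))


def ramp_profile(img: IntensityImage, row: int | None = None):
    """Tone profile along one row of a chart, with its LIP opposites.

    Returns ``(tones, opposites)``, the raw material of a chart-profile
    plot: grey levels along a horizontal line and the negative grey
    levels that would cancel them.
    """
    f = to_tone(img)
    if f.values.ndim != 2:
        raise LIPError("profile extraction expects a single-channel chart")
    row = f.values.shape[0] // 2 if row is None else row
    line = ToneImage(f.values[row : row + 1, :], f.scale)
    return line.values[0].copy(), lip_negate(line).values[0].copy()


def generate_low_light(
    base: IntensityImage, darkening: float, mode: str = "scalar"
) -> LowLightFixture:
    """Darken a well-exposed image in the tone domain (exposure simulation).

    ``mode="scalar"``: tones become ``λ ⊗ f`` with ``λ = darkening > 1``.
    ``mode="additive"``: tones become ``f ⊕ C`` with ``C = darkening``
    in ``[0, M[`` — superposing a uniform semi-transparent filter.
    """
    f = to_tone(base)
    if mode == "scalar":
        if darkening <= 1:
            raise ValueError(f"scalar darkening needs λ > 1, got {darkening}")
        dark = lip_scalar_mul(darkening, f)
    elif mode == "additive":
        if not 0 <= darkening < f.scale.M:
            raise ValueError(
                f"additive darkening needs C in [0, M[, got {darkening}"
            )
        dark = lip_add(f, darkening)
    else:
        raise ValueError(f"unknown darkening mode {mode!r}")
    return LowLightFixture(from_tone(dark), mode, float(darkening))


def _blob_field(rng: np.random.Generator, shape: tuple, n_blobs: int) -> np.ndarray:
    """Sum of random Gaussian blobs, normalized to [0, 1]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    acc = np.zeros(shape, dtype=float)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        s = rng.uniform(0.08, 0.3) * max(h, w)
        acc += rng.uniform(0.3, 1.0) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)
        )
    acc -= acc.min()
    peak = acc.max()
    return acc / peak if peak > 0 else acc


def generate_colour_scene(
    shape: tuple = (64, 64),
    seed: int = 0,
    scale: GreyScale = GreyScale(256.0),
    tone_range: tuple = (40.0, 220.0),
) -> IntensityImage:
    """Smooth random RGB scene with tones confined to ``tone_range``.

    The limited range makes it a natural input for dynamic-range
    expansion; the scene is a deterministic function of ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = tone_range
    channels = [
        lo + (hi - lo) * _blob_field(rng, shape, n_blobs=4) for _ in range(3)
    ]
    tones = np.stack(channels, axis=-1)
    return from_tone(ToneImage(tones, scale))


def generate_slice_stack(
    n_slices: int = 12,
    shape: tuple = (16, 16),
    seed: int = 0,
    spacing: float = 1.0,
    pixel_size: float = 0.2,
    scale: GreyScale = GreyScale(256.0),
    tone_range: tuple = (120.0, 240.0),
) -> SliceStack:
    """Stack of dim slices of a Gaussian blob drifting through the volume.

    Defaults mimic anisotropic tomographic acquisitions: 12 slices,
    in-plane resolution (0.2) five times finer than the slice spacing
    (1.0), and a compressed dark tone range awaiting enhancement.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y0, x0 = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
    y1, x1 = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
    lo, hi = tone_range
    slices = []
    for i in range(n_slices):
        t = i / max(n_slices - 1, 1)
        cy, cx = y0 + t * (y1 - y0), x0 + t * (x1 - x0)
        s = 0.18 * max(h, w)
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
        tones = hi - (hi - lo) * blob  # blob is brighter (lower tone)
        slices.append(ToneImage(tones, scale))
    return SliceStack(slices, spacing=spacing, pixel_size=pixel_size)


def generate_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    if spec.kind == "ramp_chart":
        h, w = spec.shape
        return generate_ramp_chart(width=w, height=h, scale=spec.scale)
    if spec.kind == "low_light":
        h, w = spec.shape
        base = generate_colour_scene(
            (h, w), seed=spec.seed, scale=spec.scale
        )
        grey = IntensityImage(base.values[..., 1], base.scale)
        return generate_low_light(grey, spec.darkening, spec.darkening_mode).image
    if spec.kind == "colour_scene":
        return generate_colour_scene(spec.shape, seed=spec.seed, scale=spec.scale)
    if spec.kind == "slice_stack":
        return generate_slice_stack(shape=spec.shape, seed=spec.seed, scale=spec.scale)
    raise ValueError(spec.kind)
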