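"""Core algebra of the Logarithmic Image Processing (LIP) model.

The LIP model describes images acquired in transmission.  A pixel carries a
*tone* (LIP grey level) ``f`` in the half-open scale ``[0, M[``: tone 0 is
perfect transparency (the sensor sees the source directly, i.e. display
white) and tones approaching ``M`` correspond to total opacity (black).
Each tone is equivalent to a transmittance ``T = 1 - f/M``, the fraction of
source flux that passes the obstacle.

Superposing two semi-transparent obstacles multiplies their transmittances,
which induces the LIP addition

    f ⊕ g = f + g - f·g/M

and, for a real thickness factor ``λ``, the LIP scalar multiplication

    λ ⊗ f = M - M·(1 - f/M)**λ

Together these give the tone space a real vector-space structure once it is
extended to the *over-space* of tones in ``]-∞, M[``: the additive opposite
``⊖f = -f / (1 - f/M)`` is negative for positive tones, and a negative tone
is interpreted physically as a light intensifier (brighter than the
reference source; transmittance greater than 1).

All arithmetic here operates on real-valued tone arrays.  Display
intensities, as stored in files, live on the inverted scale
``I = (M-1) - f`` and are converted only at the I/O boundary
(:func:`to_tone` / :func:`from_tone`).
"""

from __future__ import annotations

import logging
import numbers
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("lipimage")

__all__ = [
    "GreyScale",
    "ToneImage",
    "IntensityImage",
    "Transmittance",
    "LIPError",
    "ScaleMismatchError",
    "DegenerateImageError",
    "to_tone",
    "from_tone",
    "lip_add",
    "lip_negate",
    "lip_subtract",
    "lip_scalar_mul",
    "transmittance",
    "tone_from_transmittance",
]


class LIPError(ValueError):
    """Base class for violations of the LIP model's contracts."""


class ScaleMismatchError(LIPError):
    """Operands do not share a grey scale, or data exceed the scale bound."""


class DegenerateImageError(LIPError):
    """An operation requiring a non-trivial dynamic range met a constant image."""


@dataclass(frozen=True)
class GreyScale:
    """The grey-scale bound ``M``.

    ``M`` is an open upper limit (total opacity, never attained); the
    largest storable display intensity is ``M - 1``.  Default 256 for 8-bit
    data, 65536 for 16-bit.
    """

    M: float = 256.0

    def __post_init__(self) -> None:
        if not self.M > 1:
            raise ValueError(f"grey-scale bound M must exceed 1, got {self.M}")

    @classmethod
    def for_bit_depth(cls, bits: int) -> "GreyScale":
        if bits not in (8, 16):
            raise ValueError(f"unsupported bit depth {bits}; expected 8 or 16")
        return cls(float(2**bits))

    @classmethod
    def for_dtype(cls, dtype: np.dtype) -> "GreyScale":
        dtype = np.dtype(dtype)
        if dtype == np.uint8:
            return cls(256.0)
        if dtype == np.uint16:
            return cls(65536.0)
        raise ValueError(f"unsupported intensity dtype {dtype}; expected uint8 or uint16")

    @property
    def max_intensity(self) -> float:
        """Largest storable display intensity, ``M - 1``."""
        return self.M - 1.0


@dataclass
class ToneImage:
    """A real-valued tone array on the extended scale ``]-∞, M[``.

    ``values`` is float64, 2-D for single-channel images or 3-D
    ``(H, W, C)`` for multi-channel; every channel shares one
    :class:`GreyScale`.  Negative tones (light intensifiers) are legal and
    unbounded below; values must stay strictly below ``M``.

    The vector-space operators are available as Python operators:
    ``f + g`` (LIP addition), ``-f`` (LIP opposite), ``f - g`` (LIP
    subtraction) and ``lam * f`` (LIP scalar multiplication).
    """

    values: np.ndarray
    scale: GreyScale = field(default_factory=GreyScale)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise LIPError("empty tone image")
        if np.any(self.values >= self.scale.M):
            raise LIPError(
                f"tone values must be strictly below M={self.scale.M}; "
                f"max found {self.values.max()}"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[-1]

    def with_values(self, values: np.ndarray) -> "ToneImage":
        return ToneImage(values, self.scale)

    # -- vector-space operator sugar -------------------------------------
    def __add__(self, other):
        return lip_add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return lip_negate(self)

    def __sub__(self, other):
        return lip_subtract(self, other)

    def __rmul__(self, lam):
        if not isinstance(lam, numbers.Real):
            return NotImplemented
        return lip_scalar_mul(lam, self)


@dataclass
class IntensityImage:
    """An integer display image on ``[0, M-1]`` as stored in files.

    ``clipped`` counts pixels clipped during quantization (see
    :func:`from_tone`); it is 0 for images read from files.
    """

    values: np.ndarray
    scale: GreyScale | None = None
    clipped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"intensity images are uint8 or uint16, got {self.values.dtype}"
            )
        if self.scale is None:
            self.scale = GreyScale.for_dtype(self.values.dtype)
        if self.values.size and self.values.max() > self.scale.max_intensity:
            raise ScaleMismatchError(
                f"intensity {self.values.max()} exceeds M-1={self.scale.max_intensity}"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class Transmittance:
    """Per-pixel fraction of source flux passing the obstacle.

    Values in ``]0, 1]`` for ordinary tones; values above 1 arise from
    negative tones and are interpreted as light amplification.
    """

    values: np.ndarray
    scale: GreyScale = field(default_factory=GreyScale)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values <= 0):
            raise LIPError("transmittance must be strictly positive")


# ---------------------------------------------------------------------------
# intensity <-> tone


def to_tone(img: IntensityImage, scale: GreyScale | None = None) -> ToneImage:
    """Convert a stored display image to tones: ``f = (M-1) - I``.

    Stored white (``I = M-1``) maps to tone 0 (transparent); stored black
    maps to tone ``M-1``.  An explicit ``scale`` overrides the image's own,
    but must still accommodate its intensities.
    """
    scale = scale or img.scale
    if img.values.size and img.values.max() > scale.max_intensity:
        raise ScaleMismatchError(
            f"intensity {img.values.max()} does not fit scale M={scale.M}"
        )
    return ToneImage(scale.max_intensity - img.values.astype(np.float64), scale)


def from_tone(f: ToneImage) -> IntensityImage:
    """Quantize a tone image for display: ``I = round((M-1) - f)``, clipped.

    Rounding is half-to-even; out-of-range results are clipped to
    ``[0, M-1]`` silently, but the number of clipped pixels is recorded on
    the result and logged.
    """
    M = f.scale.M
    raw = np.rint(f.scale.max_intensity - f.values)
    clipped = int(np.count_nonzero((raw < 0) | (raw > f.scale.max_intensity)))
    if clipped:
        logger.info("from_tone: clipped %d of %d pixels", clipped, raw.size)
    out = np.clip(raw, 0, f.scale.max_intensity)
    dtype = np.uint8 if M <= 256 else np.uint16
    return IntensityImage(out.astype(dtype), f.scale, clipped=clipped)


# ---------------------------------------------------------------------------
# the LIP laws


def _coerce(g, scale: GreyScale, shape) -> np.ndarray:
    """Accept a ToneImage or a real constant as the second operand."""
    if isinstance(g, ToneImage):
        if g.scale != scale:
            raise ScaleMismatchError(f"grey scales differ: {scale} vs {g.scale}")
        if g.values.shape != shape:
            raise LIPError(f"shape mismatch: {shape} vs {g.values.shape}")
        return g.values
    g = float(g)
    if g >= scale.M:
        raise LIPError(f"constant {g} must be strictly below M={scale.M}")
    return np.full((), g)


def lip_add(f: ToneImage, g) -> ToneImage:
    """LIP addition ``f ⊕ g = f + g - f·g/M`` (superposition of obstacles).

    Equivalent to multiplying transmittances; closed on ``]-∞, M[``.
    ``g`` may be a tone image of the same shape and scale or a real
    constant below ``M`` (a uniform filter).
    """
    gv = _coerce(g, f.scale, f.values.shape)
    return f.with_values(f.values + gv - f.values * gv / f.scale.M)


def lip_negate(f: ToneImage) -> ToneImage:
    """LIP opposite ``⊖f = -f / (1 - f/M)``: the unique g with f ⊕ g = 0.

    Positive tones map to negative ones (light intensifiers) and
    vice versa; ``⊖⊖f = f``.
    """
    return f.with_values(-f.values / (1.0 - f.values / f.scale.M))


def lip_subtract(f: ToneImage, g) -> ToneImage:
    """LIP subtraction ``f ⊖ g = (f - g) / (1 - g/M)`` = ``f ⊕ (⊖g)``."""
    gv = _coerce(g, f.scale, f.values.shape)
    return f.with_values((f.values - gv) / (1.0 - gv / f.scale.M))


def lip_scalar_mul(lam: float, f: ToneImage) -> ToneImage:
    """LIP scalar multiplication ``λ ⊗ f = M - M·(1 - f/M)**λ``.

    Physically, scales the thickness of the semi-transparent obstacle:
    ``λ ∈ ]0,1[`` brightens (thinner), ``λ > 1`` darkens (thicker), and
    negative ``λ`` yields negative tones — a virtual light intensifier.
    """
    lam = float(lam)
    M = f.scale.M
    return f.with_values(M - M * np.power(1.0 - f.values / M, lam))


def transmittance(f: ToneImage) -> Transmittance:
    """Transmittance ``T = 1 - f/M``; values above 1 flag amplification."""
    return Transmittance(1.0 - f.values / f.scale.M, f.scale)


def tone_from_transmittance(t: Transmittance) -> ToneImage:
    """Inverse map ``f = M·(1 - T)``; rejects non-positive transmittance."""
    return ToneImage(t.scale.M * (1.0 - t.values), t.scale)
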