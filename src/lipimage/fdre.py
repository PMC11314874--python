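"""Full Dynamic Range Expansion (FDRE) of low-light images.

FDRE maps an image's observed tone range ``[f(b), f(a)]`` exactly onto the
full grey scale ``[0, M-1]`` using only LIP operations, so the transform
is bijective (no information loss) and has a physical reading.

Two routes:

* **subtractive** — LIP-subtract a uniform constant ``C0``.  Since
  ``DR(f ⊖ C) = (f(a) - f(b)) / (1 - C/M)`` grows with ``C``, the value
  achieving ``DR = M-1`` has the closed form
  ``C0 = M·(1 - DR(f)/(M-1))``.  Because ``f ⊖ C`` is affine in ``f``,
  this route coincides with the classical linear stretch of
  ``[f(b), f(a)]`` onto ``[0, M-1]``.

* **multiplicative** — LIP-multiply by a negative scalar ``λ0`` (a virtual
  negative thickness, i.e. a light intensifier).  ``DR(λ ⊗ f)`` grows
  from 0 to ∞ as ``λ`` decreases below 0, so the defining equation

      (1 - f(a)/M)**λ0 - (1 - f(b)/M)**λ0 = 1 - 1/M

  has a unique negative root, found by an integer bracket descent
  ``λ = -1, -2, -3, …`` followed by dichotomy (bisection).  The enhanced
  image is ``λ0 ⊗ f`` translated (ordinary subtraction) by ``λ0 ⊗ f(a)``
  so it spans ``[0, M-1]``.  This route is nonlinear: it expands dark
  tones less than bright ones.

The colour extension solves one shared ``λ0`` on the Global Dynamic Range
(max minus min over all three channels jointly) and applies the same map
and the same translation constant to R, G and B, which preserves hue
ordering between channels.

Note on orientation: because ``λ0 < 0``, the literal map
``λ0 ⊗ f - λ0 ⊗ f(a)`` is strictly *decreasing* in tone, i.e. it inverts
bright and dark.  The default ``orientation="order_preserving"`` reflects
the result as ``(M-1) - g``, which spans the same range while keeping
``f(b) ↦ 0`` and ``f(a) ↦ M-1``; ``orientation="literal"`` returns the
unreflected map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DegenerateImageError, GreyScale, LIPError, ToneImage

__all__ = [
    "DynamicRange",
    "GlobalDynamicRange",
    "FDREResult",
    "dynamic_range",
    "global_dynamic_range",
    "fdre_subtractive",
    "solve_lambda0",
    "fdre_multiplicative",
    "fdre_colour",
]

ORIENTATIONS = ("order_preserving", "literal")


@dataclass(frozen=True)
class DynamicRange:
    """Sup tone ``f(a)``, inf tone ``f(b)`` and their difference ``DR``."""

    sup_tone: float
    inf_tone: float

    @property
    def dr(self) -> float:
        return self.sup_tone - self.inf_tone


@dataclass(frozen=True)
class GlobalDynamicRange:
    """Joint max/min tone over all three channels of a colour image."""

    max_channel_tone: float
    min_channel_tone: float

    @property
    def gdr(self) -> float:
        return self.max_channel_tone - self.min_channel_tone


@dataclass
class FDREResult:
    """Enhanced image plus the solved parameter and solver diagnostics.

    ``parameter`` is ``C0`` for the subtractive route or ``λ0`` for the
    multiplicative/colour routes; ``bracket`` is the integer dichotomy
    bracket (multiplicative only).
    """

    enhanced: ToneImage
    parameter: float
    achieved_dr: float
    mode: str
    iterations: int = 0
    bracket: tuple | None = None
    orientation: str | None = None


def dynamic_range(f: ToneImage) -> DynamicRange:
    """``DR(f) = Sup f - Inf f`` over every pixel (and channel)."""
    return DynamicRange(float(f.values.max()), float(f.values.min()))


def global_dynamic_range(f: ToneImage) -> GlobalDynamicRange:
    """Joint tone extrema over the R, G, B channels of a colour image."""
    if f.values.ndim != 3 or f.values.shape[-1] != 3:
        raise LIPError(
            f"global dynamic range needs a 3-channel image, got shape {f.shape}"
        )
    return GlobalDynamicRange(float(f.values.max()), float(f.values.min()))


def fdre_subtractive(f: ToneImage) -> FDREResult:
    """Full expansion by LIP subtraction of the closed-form constant ``C0``.

    The result is ``(f ⊖ C0)`` translated so its minimum tone is 0; it
    spans exactly ``[0, M-1]`` and is identical to the linear stretch
    ``(f - f(b))·(M-1)/DR(f)`` up to floating error.
    """
    M = f.scale.M
    rng = dynamic_range(f)
    if rng.dr <= 0:
        raise DegenerateImageError("constant image: full expansion undefined")
    c0 = M * (1.0 - rng.dr / (M - 1.0))
    stretched = (f.values - c0) / (1.0 - c0 / M)
    stretched -= stretched.min()
    enhanced = f.with_values(stretched)
    return FDREResult(
        enhanced=enhanced,
        parameter=c0,
        achieved_dr=dynamic_range(enhanced).dr,
        mode="subtractive",
    )


def _dr_gap(lam: float, ta: float, tb: float) -> float:
    """LHS of the defining equation: (Ta)**λ - (Tb)**λ for transmittances."""
    with np.errstate(over="ignore"):
        return float(ta**lam - tb**lam)


def solve_lambda0(
    dr_stats: DynamicRange,
    scale: GreyScale,
    tol: float = 1e-6,
    max_bracket: int = 1000,
    max_iter: int = 200,
) -> tuple[float, int, tuple]:
    """Solve for the unique ``λ0 < 0`` giving ``DR(λ0 ⊗ f) = M - 1``.

    Follows the integer bracket descent ``λ = -1, -2, -3, …`` until the
    dynamic-range gap first exceeds ``1 - 1/M`` (so ``λ0 ∈ ]λ, λ+1]``),
    then bisects that unit interval until its width is below ``tol``
    (default 1e-6) or ``max_iter`` halvings.  Uniqueness follows from the
    strict monotonicity of ``DR(λ ⊗ f)`` in ``λ``.

    Returns ``(λ0, bisection_iterations, (λ, λ+1))``.
    """
    M = scale.M
    fa, fb = dr_stats.sup_tone, dr_stats.inf_tone
    if fa - fb <= 0:
        raise DegenerateImageError("constant image: λ0 undefined")
    if fa >= M:
        raise LIPError(f"sup tone {fa} must be strictly below M={M}")
    ta, tb = 1.0 - fa / M, 1.0 - fb / M
    target = 1.0 - 1.0 / M

    lo = None
    for k in range(1, max_bracket + 1):
        if _dr_gap(-float(k), ta, tb) > target:
            lo = -float(k)
            break
    if lo is None:
        raise LIPError(
            f"no bracket found down to λ={-max_bracket}: dynamic range "
            f"[{fb}, {fa}] cannot be expanded to M-1 in this family"
        )
    bracket = (lo, lo + 1.0)

    a, b = bracket
    iterations = 0
    while (b - a) > tol and iterations < max_iter:
        mid = 0.5 * (a + b)
        if _dr_gap(mid, ta, tb) > target:
            a = mid
        else:
            b = mid
        iterations += 1
    return 0.5 * (a + b), iterations, bracket


def _display_multiplicative(
    f: ToneImage, lam0: float, sup_tone: float, orientation: str
) -> ToneImage:
    """λ0 ⊗ f translated by λ0 ⊗ f(a); optionally reflected to preserve order."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    M = f.scale.M
    mul = M - M * np.power(1.0 - f.values / M, lam0)
    shift = M - M * (1.0 - sup_tone / M) ** lam0
    g = mul - shift
    if orientation == "order_preserving":
        g = (M - 1.0) - g
    return f.with_values(g)


def fdre_multiplicative(
    f: ToneImage, orientation: str = "order_preserving", tol: float = 1e-6
) -> FDREResult:
    """Full expansion by LIP multiplication with the solved ``λ0 < 0``.

    Spans ``[0, M-1]`` by construction: the endpoint tones map to
    ``{0, M-1}`` (assignment depending on ``orientation``; see module
    docstring).
    """
    rng = dynamic_range(f)
    lam0, iters, bracket = solve_lambda0(rng, f.scale, tol=tol)
    enhanced = _display_multiplicative(f, lam0, rng.sup_tone, orientation)
    return FDREResult(
        enhanced=enhanced,
        parameter=lam0,
        achieved_dr=dynamic_range(enhanced).dr,
        mode="multiplicative",
        iterations=iters,
        bracket=bracket,
        orientation=orientation,
    )


def fdre_colour(
    f: ToneImage, orientation: str = "order_preserving", tol: float = 1e-6
) -> FDREResult:
    """Colour FDRE: one shared ``λ0`` solved on the Global Dynamic Range.

    All three channels are LIP-multiplied by the same ``λ0`` and translated
    by the single constant ``λ0 ⊗ (joint max tone)``, so the output's joint
    range is ``[0, M-1]`` and the per-pixel ordering between channels is
    preserved (``order_preserving``) or uniformly reversed (``literal``).
    """
    gdr = global_dynamic_range(f)
    if gdr.gdr <= 0:
        raise DegenerateImageError("constant colour image: GDR expansion undefined")
    stats = DynamicRange(gdr.max_channel_tone, gdr.min_channel_tone)
    lam0, iters, bracket = solve_lambda0(stats, f.scale, tol=tol)
    enhanced = _display_multiplicative(f, lam0, gdr.max_channel_tone, orientation)
    return FDREResult(
        enhanced=enhanced,
        parameter=lam0,
        achieved_dr=global_dynamic_range(enhanced).gdr,
        mode="colour",
        iterations=iters,
        bracket=bracket,
        orientation=orientation,
    )
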