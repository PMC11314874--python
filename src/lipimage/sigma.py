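"""Enhancement by maximizing the grey-level standard deviation.

An alternative to full-range expansion: pick the enhancement parameter
that maximizes the spread σ of the enhanced image's grey-level
distribution, under the constraint that every enhanced tone stays inside
the grey scale ``[0, M[``.  Two one-parameter families are searched:

* ``f ⊖ C`` (uniform LIP subtraction).  This map is affine in ``f`` with
  slope ``1/(1 - C/M)``, strictly increasing in ``C``, so σ increases
  monotonically with ``C`` and the in-scale constraint binds: the optimum
  is ``C0 = f(b)`` (the infimum tone), in closed form.  A grid search is
  kept only as a verification oracle in the test suite.

* ``λ ⊗ f`` for ``λ > 0``.  Closure of the LIP laws keeps all tones in
  ``[0, M[`` automatically, so the search is unconstrained on a bounded
  interval: a coarse grid locates the basin, golden-section refines it.

σ here is the population standard deviation of the pixel tone values —
equivalently the standard deviation of the grey-level distribution given
by a 1-grey-level-bin histogram (not the spread of the bin *counts*,
which a constant image would maximize).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DegenerateImageError, ToneImage, lip_scalar_mul, lip_subtract

__all__ = [
    "SigmaSearchResult",
    "tone_sigma",
    "optimize_subtractive",
    "optimize_scalar",
]


@dataclass
class SigmaSearchResult:
    """Optimal parameter (``C0`` or ``λ0``), attained σ, and diagnostics."""

    parameter: float
    sigma: float
    evaluations: int
    constraint_active: bool
    enhanced: ToneImage


def tone_sigma(f: ToneImage) -> float:
    """Population standard deviation of the tone values (grey levels)."""
    return float(f.values.std())


def optimize_subtractive(f: ToneImage) -> SigmaSearchResult:
    """σ-maximal uniform LIP subtraction: closed form ``C0 = f(b)``.

    σ[f ⊖ C] grows strictly with C while the minimum enhanced tone
    ``(f(b) - C)/(1 - C/M)`` must stay ≥ 0, i.e. ``C ≤ f(b)``; the
    constraint is always active.
    """
    fb = float(f.values.min())
    if f.values.max() - fb <= 0:
        raise DegenerateImageError("constant image: σ search degenerate")
    if fb < 0:
        raise DegenerateImageError(
            "subtractive σ search requires non-negative tones (C ∈ [0, M[)"
        )
    enhanced = lip_subtract(f, fb)
    return SigmaSearchResult(
        parameter=fb,
        sigma=tone_sigma(enhanced),
        evaluations=1,
        constraint_active=True,
        enhanced=enhanced,
    )


def sigma_profile(f: ToneImage, lams: np.ndarray) -> np.ndarray:
    """σ[λ ⊗ f] evaluated for every λ in ``lams`` (vectorized)."""
    M = f.scale.M
    u = 1.0 - f.values.reshape(-1) / M
    tones = M - M * np.power(u[None, :], np.asarray(lams, dtype=float)[:, None])
    return tones.std(axis=1)


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(fun, a: float, b: float, tol: float) -> tuple[float, float, int]:
    """Golden-section maximization of a unimodal function on [a, b]."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = fun(c), fun(d)
    n = 2
    while (b - a) > tol:
        if fc < fd:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = fun(d)
        else:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = fun(c)
        n += 1
    x = 0.5 * (a + b)
    return x, fun(x), n + 1


def optimize_scalar(
    f: ToneImage,
    lam_max: float = 5.0,
    coarse_step: float = 0.01,
    tol: float = 1e-3,
) -> SigmaSearchResult:
    """σ-maximal LIP scalar multiple over ``λ ∈ (0, lam_max]``.

    Coarse grid (step ``coarse_step``) followed by golden-section
    refinement of the bracketing interval; ties break to the smallest λ.
    ``constraint_active`` records a hit at the ``lam_max`` boundary.
    """
    if float(f.values.max()) - float(f.values.min()) <= 0:
        raise DegenerateImageError("constant image: σ search degenerate")
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")

    grid = np.arange(coarse_step, lam_max + 0.5 * coarse_step, coarse_step)
    grid = grid[grid <= lam_max]
    sigmas = sigma_profile(f, grid)
    best = int(np.argmax(sigmas))  # first max -> smallest λ on ties
    lo = max(grid[best] - coarse_step, coarse_step * 1e-3)
    hi = min(grid[best] + coarse_step, lam_max)

    def objective(lam: float) -> float:
        return float(sigma_profile(f, np.array([lam]))[0])

    lam0, sig, n_refine = _golden_max(objective, lo, hi, tol)
    enhanced = lip_scalar_mul(lam0, f)
    return SigmaSearchResult(
        parameter=lam0,
        sigma=sig,
        evaluations=len(grid) + n_refine,
        constraint_active=bool(lam_max - lam0 <= tol),
        enhanced=enhanced,
    )
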