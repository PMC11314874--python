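"""Tests for full dynamic range expansion (subtractive, multiplicative, colour)."""

import numpy as np
import pytest

import lipimage as lp
from lipimage import GreyScale, ToneImage
from lipimage.fdre import DynamicRange

from conftest import M8, tone


def lambda0_grid_oracle(fa, fb, M, step=1e-4, cap=50.0):
    """Independent dense-grid bisection for the defining equation.

    Scans λ = -step, -2·step, … for the first grid point whose
    dynamic-range gap exceeds 1 - 1/M, then bisects the two neighbouring
    grid points down to 1e-12.  Shares no code with the production solver.
    """
    ta, tb = 1.0 - fa / M, 1.0 - fb / M
    target = 1.0 - 1.0 / M
    lams = -np.arange(step, cap, step)
    gaps = ta**lams - tb**lams
    idx = np.flatnonzero(gaps > target)
    assert idx.size, "oracle: no root within scan range"
    hi = lams[idx[0]] + step  # gap below target here
    lo = lams[idx[0]]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if ta**mid - tb**mid > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# dynamic range


@pytest.mark.parametrize(
    "values, expected",
    [
        (np.full((3, 3), 42.0), 0.0),
        (np.linspace(100.0, 200.0, 9).reshape(3, 3), 100.0),
        (np.arange(256.0).reshape(16, 16), 255.0),
    ],
)
def test_dynamic_range_definition(values, expected):
    assert lp.dynamic_range(ToneImage(values, M8)).dr == pytest.approx(expected)


def test_global_dynamic_range_joint_over_channels():
    f = ToneImage(np.stack([np.full((4, 4), v) for v in (50.0, 100.0, 150.0)], axis=-1), M8)
    gdr = lp.global_dynamic_range(f)
    assert gdr.gdr == pytest.approx(100.0)
    # joint extrema dominate every per-channel range
    for c in range(3):
        ch = ToneImage(f.values[..., c], M8)
        assert gdr.gdr >= lp.dynamic_range(ch).dr
    with pytest.raises(lp.LIPError):
        lp.global_dynamic_range(ToneImage(np.zeros((4, 4)), M8))


# ---------------------------------------------------------------------------
# subtractive FDRE


def test_subtractive_closed_form_constant():
    f = tone([[100.0, 150.0, 200.0]])
    res = lp.fdre_subtractive(f)
    assert res.parameter == pytest.approx(256.0 * (1.0 - 100.0 / 255.0))
    assert res.achieved_dr == pytest.approx(255.0, abs=1e-9)


def test_subtractive_equals_linear_stretch(random_tone_image):
    res = lp.fdre_subtractive(random_tone_image)
    v = random_tone_image.values
    stretch = (v - v.min()) * (M8.M - 1.0) / (v.max() - v.min())
    np.testing.assert_allclose(res.enhanced.values, stretch, atol=1e-9)
    assert np.all(np.diff(np.sort(res.enhanced.values.ravel())) >= 0)


def test_subtractive_two_pixel_endpoints():
    res = lp.fdre_subtractive(tone([[100.0, 200.0]]))
    np.testing.assert_allclose(res.enhanced.values, [[0.0, 255.0]], atol=1e-9)


def test_subtractive_full_range_input_is_pure_translation():
    f = tone([[0.0, 255.0]])
    res = lp.fdre_subtractive(f)
    assert res.parameter == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(res.enhanced.values, f.values, atol=1e-9)


def test_subtractive_rejects_constant_image():
    with pytest.raises(lp.DegenerateImageError):
        lp.fdre_subtractive(tone([[5.0, 5.0]]))


# ---------------------------------------------------------------------------
# the λ0 dichotomy


def test_lambda0_reference_case():
    lam0, iters, bracket = lp.solve_lambda0(DynamicRange(200.0, 100.0), M8)
    assert lam0 == pytest.approx(-0.5508195902, abs=1e-5)
    assert bracket == (-1.0, 0.0)
    assert iters > 0
    # defining equation: the expanded range hits M-1
    gap = (1 - 200 / 256.0) ** lam0 - (1 - 100 / 256.0) ** lam0
    assert 256.0 * gap == pytest.approx(255.0, abs=0.5)


def test_lambda0_matches_independent_grid_oracle(rng):
    for _ in range(20):
        fa = rng.uniform(30.0, 255.0)
        fb = rng.uniform(0.0, fa - 5.0)
        lam0, _, _ = lp.solve_lambda0(DynamicRange(fa, fb), M8)
        assert lam0 == pytest.approx(lambda0_grid_oracle(fa, fb, M8.M), abs=1e-3)


def test_dr_grows_monotonically_as_lambda_decreases():
    ta, tb = 1 - 200 / 256.0, 1 - 100 / 256.0
    lams = -np.linspace(0.0, 5.0, 400)
    dr = 256.0 * (ta**lams - tb**lams)
    assert dr[0] == pytest.approx(0.0)
    assert np.all(np.diff(dr) > 0)  # uniqueness of the root follows


def test_lambda0_error_paths():
    with pytest.raises(lp.DegenerateImageError):
        lp.solve_lambda0(DynamicRange(50.0, 50.0), M8)
    # an all-negative-tone image keeps DR(λ (x) f) bounded: no bracket
    with pytest.raises(lp.LIPError, match="bracket"):
        lp.solve_lambda0(DynamicRange(-100.0, -200.0), M8, max_bracket=50)


# ---------------------------------------------------------------------------
# multiplicative FDRE


def test_multiplicative_two_pixel_orientations():
    f = tone([[100.0, 200.0]])
    keep = lp.fdre_multiplicative(f, "order_preserving")
    np.testing.assert_allclose(keep.enhanced.values, [[0.0, 255.0]], atol=1e-3)
    lit = lp.fdre_multiplicative(f, "literal")
    np.testing.assert_allclose(lit.enhanced.values, [[255.0, 0.0]], atol=1e-3)
    assert keep.parameter == lit.parameter < 0


def test_multiplicative_full_span_on_random_images(rng):
    for _ in range(10):
        f = ToneImage(rng.uniform(0.0, 250.0, size=(12, 12)), M8)
        res = lp.fdre_multiplicative(f)
        assert res.enhanced.values.min() == pytest.approx(0.0, abs=0.5)
        assert res.enhanced.values.max() == pytest.approx(255.0, abs=0.5)
        assert res.achieved_dr == pytest.approx(255.0, abs=0.5)
        assert res.parameter < 0


def test_multiplicative_literal_map_reverses_order(rng):
    v = np.sort(rng.uniform(10.0, 240.0, size=(1, 32)))
    res = lp.fdre_multiplicative(ToneImage(v, M8), "literal")
    assert np.all(np.diff(res.enhanced.values[0]) < 0)
    res2 = lp.fdre_multiplicative(ToneImage(v, M8), "order_preserving")
    assert np.all(np.diff(res2.enhanced.values[0]) > 0)


def test_multiplicative_rejects_constant_and_bad_orientation():
    with pytest.raises(lp.DegenerateImageError):
        lp.fdre_multiplicative(tone([[9.0, 9.0]]))
    with pytest.raises(ValueError):
        lp.fdre_multiplicative(tone([[1.0, 2.0]]), "sideways")


def test_range_idempotence():
    """Re-enhancing an already full-range image changes little."""
    base = lp.fdre_subtractive(tone([[100.0, 150.0, 200.0]])).enhanced
    again = lp.fdre_subtractive(base)
    assert again.parameter == pytest.approx(0.0, abs=1e-9)
    assert again.achieved_dr == pytest.approx(255.0, abs=1e-9)
    mult = lp.fdre_multiplicative(base)
    assert mult.achieved_dr == pytest.approx(255.0, abs=0.5)


# ---------------------------------------------------------------------------
# colour FDRE


def test_colour_reduces_to_grey_case():
    grey = tone([[100.0, 200.0]])
    colour = ToneImage(np.repeat(grey.values[:, :, None], 3, axis=2), M8)
    cres = lp.fdre_colour(colour)
    gres = lp.fdre_multiplicative(grey)
    assert cres.parameter == pytest.approx(gres.parameter, abs=1e-9)
    for c in range(3):
        np.testing.assert_allclose(
            cres.enhanced.values[..., c], gres.enhanced.values, atol=1e-9
        )


def test_colour_full_joint_range_and_channel_order(random_colour_image):
    res = lp.fdre_colour(random_colour_image)
    assert res.achieved_dr == pytest.approx(255.0, abs=0.5)
    assert res.enhanced.values.min() == pytest.approx(0.0, abs=0.5)
    # one shared monotone map: per-pixel channel ordering is preserved
    order_in = np.argsort(random_colour_image.values, axis=-1)
    order_out = np.argsort(res.enhanced.values, axis=-1)
    np.testing.assert_array_equal(order_in, order_out)


def test_colour_rejects_constant_image():
    with pytest.raises(lp.DegenerateImageError):
        lp.fdre_colour(ToneImage(np.full((4, 4, 3), 77.0), M8))
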