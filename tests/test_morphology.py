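"""Exactness and algebra of the flat morphological operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calmorph.morphology import (
    StructuringElement,
    closing,
    closing_by_reconstruction,
    dilate,
    erode,
    geodesic_dilate,
    geodesic_erode,
    opening,
    opening_by_reconstruction,
    reconstruct_by_dilation,
    reconstruct_by_erosion,
)

from _oracles import (
    brute_dilate,
    brute_erode,
    naive_closing_by_reconstruction,
    naive_opening_by_reconstruction,
    naive_reconstruct_by_dilation,
    naive_reconstruct_by_erosion,
)


def random_image(rng, shape=(16, 16), high=255):
    return rng.integers(0, high, shape).astype(np.int64)


# ---------------------------------------------------------------- elementary

def test_constant_inputs_are_fixed_points(rng):
    c = np.full((9, 9), 7, dtype=np.int64)
    for op in (erode, dilate, opening, closing,
               opening_by_reconstruction, closing_by_reconstruction):
        assert np.array_equal(op(c, 2), c)


def test_line_window_extrema():
    assert np.array_equal(erode(np.array([5, 1, 5]), StructuringElement("line", 1)),
                          [1, 1, 1])
    assert np.array_equal(dilate(np.array([0, 3, 0]), StructuringElement("line", 1)),
                          [3, 3, 3])


def test_isolated_spike_removed_by_opening_kept_by_closing():
    f = np.zeros((11, 11), dtype=np.int64)
    f[5, 5] = 10
    assert opening(f, 1).max() == 0
    assert np.array_equal(closing(f, 1), f)


@pytest.mark.parametrize("mu", [1, 2, 3])
def test_erode_dilate_match_window_scan_oracle(mu):
    rng = np.random.default_rng(mu)
    for _ in range(25):
        f = random_image(rng)
        assert np.array_equal(erode(f, mu), brute_erode(f, mu))
        assert np.array_equal(dilate(f, mu), brute_dilate(f, mu))
    s = rng.integers(0, 255, 40)
    se = StructuringElement("line", mu)
    assert np.array_equal(erode(s, se), brute_erode(s, mu))
    assert np.array_equal(dilate(s, se), brute_dilate(s, mu))


def test_size_zero_element_is_identity(rng):
    f = random_image(rng)
    for op in (erode, dilate, opening_by_reconstruction,
               closing_by_reconstruction):
        assert np.array_equal(op(f, 0), f)


def test_disc_element_differs_from_square(rng):
    f = random_image(rng)
    sq = erode(f, StructuringElement("square", 2))
    dc = erode(f, StructuringElement("disc", 2))
    assert (dc >= sq).all() and not np.array_equal(dc, sq)


def test_empty_and_invalid_inputs_error():
    with pytest.raises(ValueError, match="empty-domain"):
        erode(np.array([]), 1)
    with pytest.raises(ValueError):
        StructuringElement("hexagon", 1)
    with pytest.raises(ValueError):
        StructuringElement("square", -1)


# ------------------------------------------------------------------ geodesic

def test_geodesic_step_fixed_point_and_formula(rng):
    f = random_image(rng).astype(np.float64)
    assert np.array_equal(geodesic_dilate(f, f), f)
    assert np.array_equal(geodesic_erode(f, f), f)
    g = f - 3.0
    assert np.array_equal(geodesic_dilate(g, f), np.minimum(f, brute_dilate(g, 1)))
    assert np.array_equal(geodesic_erode(f, g), np.maximum(g, brute_erode(f, 1)))


def test_geodesic_marker_mask_order_enforced(rng):
    f = random_image(rng)
    with pytest.raises(ValueError, match="marker-mask-order"):
        geodesic_dilate(f + 1, f)
    with pytest.raises(ValueError, match="marker-mask-order"):
        geodesic_erode(f - 1, f)


def test_single_seed_geodesic_dilation_grows_one_neighborhood():
    f = np.full((7, 7), 9, dtype=np.int64)
    g = np.zeros_like(f)
    g[3, 3] = 9
    step = geodesic_dilate(g, f)
    expected = np.zeros_like(f)
    expected[2:5, 2:5] = 9
    assert np.array_equal(step, expected)


# ------------------------------------------------------------- reconstruction

def test_reconstruction_matches_fixpoint_oracle(rng):
    for _ in range(10):
        f = random_image(rng)
        g = brute_erode(f, 2)
        assert np.array_equal(reconstruct_by_dilation(f, g),
                              naive_reconstruct_by_dilation(f, g))
        h = brute_dilate(f, 2)
        assert np.array_equal(reconstruct_by_erosion(f, h),
                              naive_reconstruct_by_erosion(f, h))


def test_binary_reconstruction_extracts_marked_component():
    f = np.zeros((9, 14), dtype=np.uint8)
    f[2:5, 2:5] = 1       # blob A
    f[5:8, 9:13] = 1      # blob B
    g = np.zeros_like(f)
    g[3, 3] = 1           # dot inside A
    rec = reconstruct_by_dilation(f, g)
    expected = np.zeros_like(f)
    expected[2:5, 2:5] = 1
    assert np.array_equal(rec, expected)


def test_ridge_removed_plateau_restored_by_reconstruction_opening():
    f = np.zeros((9, 30), dtype=np.int64)
    f[3:6, 4:7] = 50      # 3-px-wide ridge
    f[0:9, 12:21] = 50    # 9-px-wide plateau
    out = opening_by_reconstruction(f, 2)
    assert out[4, 5] == 0
    assert np.array_equal(out[:, 12:21], f[:, 12:21])
    assert np.array_equal(out, naive_opening_by_reconstruction(f, 2))


def test_by_reconstruction_filters_match_fixpoint_oracle(rng):
    for mu in (1, 2):
        for _ in range(5):
            f = random_image(rng)
            assert np.array_equal(opening_by_reconstruction(f, mu),
                                  naive_opening_by_reconstruction(f, mu))
            assert np.array_equal(closing_by_reconstruction(f, mu),
                                  naive_closing_by_reconstruction(f, mu))


def test_reconstruction_opening_dominates_plain_opening(rng):
    f = random_image(rng)
    assert (opening_by_reconstruction(f, 2) >= opening(f, 2)).all()


def test_monotone_signals_are_fixed_points_of_reconstruction_filters(rng):
    w = np.sort(rng.normal(0, 10, 60))[::-1].copy()
    for mu in (1, 4, 9):
        se = StructuringElement("line", mu)
        assert np.array_equal(opening_by_reconstruction(w, se), w)
        assert np.array_equal(closing_by_reconstruction(w, se), w)


# ------------------------------------------------------------------- algebra

@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
def test_algebraic_laws(seed, mu):
    """Idempotence, order preservation, extensivity, sandwich, duality."""
    rng = np.random.default_rng(seed)
    f = random_image(rng, (12, 12))
    g = f + rng.integers(0, 20, f.shape)     # f <= g

    for op in (opening, closing, opening_by_reconstruction,
               closing_by_reconstruction):
        assert np.array_equal(op(op(f, mu), mu), op(f, mu))

    for op in (erode, dilate, opening, closing,
               opening_by_reconstruction, closing_by_reconstruction):
        assert (op(f, mu) <= op(g, mu)).all()

    assert (opening(f, mu) <= f).all() and (f <= closing(f, mu)).all()
    assert (opening_by_reconstruction(f, mu) <= f).all()
    assert (f <= closing_by_reconstruction(f, mu)).all()

    m = int(f.max())
    assert np.array_equal(closing_by_reconstruction(f, mu),
                          m - opening_by_reconstruction(m - f, mu))
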