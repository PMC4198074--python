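"""Marker detection: top-hat, regional minima, accumulation, filtering."""

import numpy as np
import pytest

from calmorph.markers import (
    ImageSequence,
    MarkerConfig,
    OccurrenceMap,
    accumulate_minima,
    detect_frame_minima,
    detect_markers,
    extract_markers,
    regional_minima,
    white_tophat,
)

from conftest import component_centroids, match_counts
from _oracles import flood_regional_minima


def make_frame(nuclei, shape=(64, 64), background=100, cyto=60, depth=30,
               r_nuc=4, r_cyt=10):
    """Flat background with bright cytoplasm discs holding darker cores."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    f = np.full(shape, background, dtype=np.int64)
    for (r, c) in nuclei:
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        f[d2 <= r_cyt ** 2] = background + cyto
        f[d2 <= r_nuc ** 2] = background + cyto - depth
    return f


# ------------------------------------------------------------------ top-hat

def test_tophat_of_flat_image_is_zero():
    assert white_tophat(np.full((20, 20), 77, dtype=np.int64), 3).max() == 0


def test_tophat_isolates_small_bump_on_offset_background():
    f = np.full((21, 21), 100, dtype=np.int64)
    f[10, 9:12] += 50      # 3-px bump, window of scale 3 is 7 px wide
    th = white_tophat(f, 3)
    assert th[10, 10] == 50
    assert th[0, 0] == 0
    assert (th >= 0).all()


def test_tophat_removes_wide_illumination_ramp():
    yy, xx = np.mgrid[0:64, 0:64]
    cells = make_frame([(20, 20), (44, 44)])
    ramp = (0.5 * xx + 0.3 * yy).astype(np.int64)
    mu = 12            # window wider than a cell, much narrower than the frame
    th = white_tophat(cells + ramp, mu)
    # away from the border the linear ramp is removed almost exactly
    interior = np.zeros((64, 64), dtype=bool)
    interior[mu:-mu, mu:-mu] = True
    bg = th[(cells == 100) & interior]
    assert bg.max() - bg.min() <= 2   # vs the ramp's ~50-count span


def test_tophat_requires_positive_scale():
    with pytest.raises(ValueError):
        white_tophat(np.zeros((4, 4)), 0)


# ----------------------------------------------------------- regional minima

def test_regional_minima_of_ramp_and_constant():
    ramp = np.tile(np.arange(10, dtype=np.int64), (5, 1))
    m = regional_minima(ramp)
    assert m[:, 0].all() and not m[:, 1:].any()
    assert regional_minima(np.full((6, 6), 3, dtype=np.int64)).all()


def test_regional_minima_match_flood_oracle(rng):
    for _ in range(20):
        f = rng.integers(0, 8, (16, 16)).astype(np.int64)  # few levels: flat zones
        assert np.array_equal(regional_minima(f), flood_regional_minima(f))


# ------------------------------------------------------- per-frame detection

def test_frame_minima_find_each_nucleus_and_ignore_salt_noise():
    nuclei = [(16, 16), (16, 48), (48, 16), (48, 48)]
    cfg = MarkerConfig()
    clean = make_frame(nuclei)
    m = detect_frame_minima(clean, cfg)
    cents = component_centroids(m)
    _, n_rec = match_counts(cents, np.array(nuclei), cfg.cell_radius)
    assert n_rec == len(nuclei)

    noisy = clean.copy()
    noisy[30, 30] -= 40    # isolated single-pixel dark speck
    m2 = detect_frame_minima(noisy, cfg)
    # the unitary closing by reconstruction fills the pit exactly, so the
    # speck never becomes a separate minimum component
    assert np.array_equal(m2, m)


def test_frame_minima_of_constant_frame_cover_it():
    cfg = MarkerConfig(tophat_scale=3)
    assert detect_frame_minima(np.full((16, 16), 9, dtype=np.int64), cfg).all()


# -------------------------------------------------------------- accumulation

def test_accumulation_counts_frames(rng):
    frame = make_frame([(16, 16)], shape=(32, 32))
    cfg = MarkerConfig()
    single = ImageSequence(frames=frame[None])
    occ1 = accumulate_minima(single, cfg)
    mask = detect_frame_minima(frame, cfg)
    assert np.array_equal(occ1.counts, mask.astype(np.int64))

    ten = ImageSequence(frames=np.repeat(frame[None], 10, axis=0))
    occ10 = accumulate_minima(ten, cfg)
    assert np.array_equal(occ10.counts, 10 * mask.astype(np.int64))
    assert occ10.n_frames == 10


def test_accumulation_is_monotone_in_frames():
    frame = make_frame([(16, 16)], shape=(32, 32))
    other = make_frame([(16, 20)], shape=(32, 32))
    cfg = MarkerConfig()
    seq_small = ImageSequence(frames=np.stack([frame, other]))
    seq_big = ImageSequence(frames=np.stack([frame, other, frame]))
    a = accumulate_minima(seq_small, cfg).counts
    b = accumulate_minima(seq_big, cfg).counts
    assert (b >= a).all()


def test_frame_range_restricts_accumulation():
    frame = make_frame([(16, 16)], shape=(32, 32))
    seq = ImageSequence(frames=np.repeat(frame[None], 6, axis=0))
    occ = accumulate_minima(seq, MarkerConfig(frame_range=(0, 3)))
    assert occ.n_frames == 3


def test_occurrence_map_bounds_validated():
    with pytest.raises(ValueError):
        OccurrenceMap(counts=np.array([[5]]), n_frames=3)


# ------------------------------------------------------------ marker filter

def test_extract_markers_recovers_separated_nuclei():
    nuclei = [(16, 16), (16, 48), (48, 16), (48, 48)]
    cfg = MarkerConfig()
    frame = make_frame(nuclei)
    mask = detect_frame_minima(frame, cfg)
    # nucleus minima recur every frame; background minima wander, so their
    # per-pixel occurrence stays low
    inside_cells = frame != 100
    counts = np.where(inside_cells, 10, 1) * mask.astype(np.int64)
    occ = OccurrenceMap(counts=counts, n_frames=10)
    out = extract_markers(occ, cfg)
    cents = component_centroids(out)
    n_prec, n_rec = match_counts(cents, np.array(nuclei), cfg.cell_radius)
    assert n_rec == len(nuclei) and n_prec == len(cents)


def test_low_count_smear_is_filtered_out():
    counts = np.zeros((40, 40), dtype=np.int64)
    counts[5:35, 5:35] = 3          # huge smear seen in 3 of 10 frames
    occ = OccurrenceMap(counts=counts, n_frames=10)
    with pytest.warns(UserWarning, match="no-markers"):
        out = extract_markers(occ, MarkerConfig())
    assert not out.any()


def test_large_persistent_blob_removed_by_reconstruction_difference():
    counts = np.zeros((60, 60), dtype=np.int64)
    counts[10:40, 10:40] = 10       # persistent but far too large
    counts[48:52, 48:52] = 10       # nucleus-sized
    occ = OccurrenceMap(counts=counts, n_frames=10)
    out = extract_markers(occ, MarkerConfig())
    cents = component_centroids(out)
    assert len(cents) == 1
    assert abs(cents[0][0] - 49.5) < 2 and abs(cents[0][1] - 49.5) < 2


def test_nearby_fragments_are_merged_by_closing():
    counts = np.zeros((40, 40), dtype=np.int64)
    counts[18:22, 10:14] = 10
    counts[18:22, 16:20] = 10       # 2 px gap
    occ = OccurrenceMap(counts=counts, n_frames=10)
    out = extract_markers(occ, MarkerConfig())
    assert len(component_centroids(out)) == 1


def test_detection_recall_precision_on_default_scene(default_scene):
    seq, truth, _ = default_scene
    cfg = MarkerConfig()
    cents = component_centroids(detect_markers(seq, cfg))
    n_prec, n_rec = match_counts(cents, truth.centers.astype(float),
                                 cfg.cell_radius)
    assert n_rec / len(truth.centers) >= 0.95
    assert n_prec / max(len(cents), 1) >= 0.95
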