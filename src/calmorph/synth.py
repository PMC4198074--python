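"""Synthetic fluorescence sequences with known ground truth.

Every processing stage is testable without real data through this
generator.  It emulates the salient features of a calcium-imaging
acquisition of stained follicular cells: dark nuclei of a few pixels
radius inside brighter cytoplasm discs, a smooth spatially varying
background illumination, per-cell fluorescence that rises linearly to a
stimulus peak and then decays exponentially toward a resting level, and
additive zero-mean Gaussian readout noise, quantized to integer counts.

The generator is fully deterministic given its seed, and returns the
ground truth (cell centers, masks, noiseless volume traces, peak frames,
decay constants) alongside the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import ImageSequence

__all__ = ["SceneSpec", "GroundTruth", "generate_sequence", "generate_trace",
           "temporal_profile"]


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    Intensities are in arbitrary fluorescence counts on an 8-bit-like
    scale.  ``peak_frames`` and ``decay_taus`` may be given explicitly
    (one per cell); by default they are drawn per cell from mid-sequence
    stimulus windows: peaks in [15%, 30%] of the sequence, decay constants
    in [15%, 35%] of the sequence length.
    """

    n_cells: int = 8
    cell_radius: int = 4
    cytoplasm_radius: int | None = None
    frame_size: tuple[int, int] = (128, 128)
    n_frames: int = 200
    frame_interval: float = 1.0 / 30.0
    background_base: float = 30.0
    background_ramp: float = 8.0
    cytoplasm_gain: float = 120.0
    nucleus_depth: float = 60.0
    rest_level: float = 0.15
    rise_frames: int = 10
    noise_sigma: float = 0.5
    decay_taus: list[float] | None = None
    peak_frames: list[int] | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.cytoplasm_radius is None:
            self.cytoplasm_radius = int(round(2.5 * self.cell_radius))
        if self.nucleus_depth > self.cytoplasm_gain:
            raise ValueError("nucleus_depth cannot exceed cytoplasm_gain")
        if not (0.0 <= self.rest_level < 1.0):
            raise ValueError("rest_level must be in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    centers: np.ndarray            # (n_cells, 2) row, col
    nucleus_masks: np.ndarray      # (n_cells, H, W) bool
    region_masks: np.ndarray       # (n_cells, H, W) bool, full cell disc
    volumes: np.ndarray            # (n_cells, n_frames) noiseless volume traces
    peak_frames: np.ndarray        # (n_cells,) int
    decay_taus: np.ndarray         # (n_cells,) float, frames
    profiles: np.ndarray = field(default=None)  # (n_cells, n_frames) g_n(t)


def temporal_profile(n_frames: int, peak: int, tau: float,
                     rest_level: float = 0.15, rise_frames: int = 10) -> np.ndarray:
    """Normalized per-cell fluorescence dynamic g(t) in [rest_level, 1].

    Resting level before the stimulus, linear rise over ``rise_frames`` to
    1.0 at ``peak``, then exponential decay exp(-(t-peak)/tau) back toward
    the resting level.
    """
    t = np.arange(n_frames, dtype=np.float64)
    h = np.zeros(n_frames)
    rise_start = max(0, peak - rise_frames)
    if peak > rise_start:
        ramp = (t - rise_start) / (peak - rise_start)
        h = np.where((t >= rise_start) & (t <= peak), ramp, h)
    else:
        h[t == peak] = 1.0
    h = np.where(t > peak, np.exp(-(t - peak) / tau), h)
    return rest_level + (1.0 - rest_level) * h


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.frame_size
    margin = spec.cytoplasm_radius + 2
    min_sep = max(4 * spec.cell_radius, 2 * spec.cytoplasm_radius + 3)
    centers: list[tuple[int, int]] = []
    for _ in range(20000):
        if len(centers) == spec.n_cells:
            break
        r = int(rng.integers(margin, H - margin))
        c = int(rng.integers(margin, W - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep ** 2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < spec.n_cells:
        raise ValueError("placement-failure")
    return np.array(centers, dtype=np.int64)


def generate_sequence(spec: SceneSpec,
                      return_noiseless: bool = False):
    """Render a synthetic sequence and its ground truth.

    Returns ``(ImageSequence, GroundTruth)``, or with
    ``return_noiseless=True`` a third element: the noiseless float frame
    stack before quantization.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.frame_size
    n, T = spec.n_cells, spec.n_frames

    centers = _place_centers(spec, rng) if n > 0 else np.zeros((0, 2), np.int64)

    if spec.peak_frames is not None:
        peaks = np.asarray(spec.peak_frames, dtype=np.int64)
    else:
        peaks = rng.integers(int(0.15 * T), max(int(0.30 * T), int(0.15 * T) + 1),
                             size=n)
    if spec.decay_taus is not None:
        taus = np.asarray(spec.decay_taus, dtype=np.float64)
    else:
        taus = rng.uniform(0.15 * T, 0.35 * T, size=n)
    if len(peaks) != n or len(taus) != n:
        raise ValueError("peak_frames and decay_taus must have one entry per cell")

    yy, xx = np.mgrid[0:H, 0:W]
    background = spec.background_base + spec.background_ramp * (
        0.6 * xx / max(W - 1, 1) + 0.4 * yy / max(H - 1, 1))

    nucleus_masks = np.zeros((n, H, W), dtype=bool)
    region_masks = np.zeros((n, H, W), dtype=bool)
    for i, (r, c) in enumerate(centers):
        d2 = (yy - r) ** 2 + (xx - c) ** 2
        nucleus_masks[i] = d2 <= spec.cell_radius ** 2
        region_masks[i] = d2 <= spec.cytoplasm_radius ** 2

    profiles = np.array([
        temporal_profile(T, int(peaks[i]), float(taus[i]),
                         spec.rest_level, spec.rise_frames)
        for i in range(n)
    ]) if n > 0 else np.zeros((0, T))

    # per-cell static intensity shape: flat cytoplasm disc with flat darker core
    shapes = np.where(nucleus_masks, spec.cytoplasm_gain - spec.nucleus_depth,
                      np.where(region_masks, spec.cytoplasm_gain, 0.0))

    frames = np.empty((T, H, W), dtype=np.uint16)
    noiseless = np.empty((T, H, W), dtype=np.float64) if return_noiseless else None
    volumes = np.zeros((n, T), dtype=np.float64)
    flat_regions = region_masks.reshape(n, H * W)
    for t in range(T):
        clean = background.copy()
        for i in range(n):
            clean += profiles[i, t] * shapes[i]
        if n > 0:
            volumes[:, t] = flat_regions @ clean.ravel()
        if return_noiseless:
            noiseless[t] = clean
        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=(H, W))
        frames[t] = np.clip(np.rint(noisy), 0, np.iinfo(np.uint16).max
                            ).astype(np.uint16)

    seq = ImageSequence(frames=frames, frame_interval=spec.frame_interval)
    truth = GroundTruth(centers=centers, nucleus_masks=nucleus_masks,
                        region_masks=region_masks, volumes=volumes,
                        peak_frames=peaks, decay_taus=taus, profiles=profiles)
    if return_noiseless:
        return seq, truth, noiseless
    return seq, truth


def generate_trace(amplitude: float, tau: float, peak: int, n: int,
                   noise_sigma: float, seed: int,
                   rest_level: float = 0.15,
                   rise_frames: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Standalone (noisy, noiseless) decay-trace pair for 1-D module tests.

    The noiseless trace is ``amplitude * g(t)`` with the same rise/decay
    dynamic as the image generator; noise is additive zero-mean Gaussian.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    noiseless = amplitude * temporal_profile(n, peak, tau, rest_level, rise_frames)
    noisy = noiseless + rng.normal(0.0, noise_sigma, size=n)
    return noisy, noiseless
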