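"""Nucleus-marker detection from a fluorescence image sequence.

Cell nuclei appear as small dark regions surrounded by brighter cytoplasm.
Each frame is first flattened with a white top-hat (image minus its opening
by a large element, which tracks the illumination field rather than the
cells), enhanced with a unitary closing by reconstruction to suppress
single-pixel noise minima, and its regional minima are extracted.  Minima
occurrences are accumulated across the sequence — a nucleus is a minimum in
most frames while noise minima wander — and the accumulated map is
thresholded, closed to fill holes and connect fragments, stripped of large
structures via an opening-by-reconstruction difference, and finally
filtered by component area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima

from .morphology import (
    closing,
    closing_by_reconstruction,
    opening,
    opening_by_reconstruction,
)

__all__ = [
    "ImageSequence",
    "OccurrenceMap",
    "MarkerConfig",
    "white_tophat",
    "regional_minima",
    "detect_frame_minima",
    "accumulate_minima",
    "extract_markers",
    "detect_markers",
]

#: 8-connectivity structure used for component labeling throughout
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class ImageSequence:
    """Time-ordered stack of same-sized grayscale frames.

    ``frames`` has shape ``(n_frames, height, width)``; ``frame_interval``
    is the time between frames in seconds (the reciprocal of the
    acquisition rate).
    """

    frames: np.ndarray
    frame_interval: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) stack with >= 1 frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(len(self)) * self.frame_interval


@dataclass
class OccurrenceMap:
    """Per-pixel count of frames in which the pixel was a regional minimum."""

    counts: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_frames:
            raise ValueError("counts must lie in [0, n_frames]")


@dataclass
class MarkerConfig:
    """Tuning knobs of the marker-detection chain.

    All scales are homothetic structuring-element sizes (a size-``mu``
    element spans ``2*mu+1`` pixels).  Derived defaults follow the expected
    nucleus radius ``cell_radius`` (about 4 px at the acquisition scale the
    pipeline was designed for):

    * ``tophat_scale`` defaults to ``10 * cell_radius`` so the opening tracks
      the illumination field, not the cells;
    * ``min_area``/``max_area`` default to the areas of discs of radius
      ``cell_radius / 2`` and ``3 * cell_radius``.
    """

    cell_radius: int = 4
    tophat_scale: int | None = None
    recon_scale: int = 1
    hole_close_scale: int = 3
    area_open_scale: int = 6
    occurrence_threshold: float = 0.5
    min_area: int | None = None
    max_area: int | None = None
    frame_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.tophat_scale is None:
            self.tophat_scale = 10 * self.cell_radius
        if self.min_area is None:
            self.min_area = max(1, math.ceil(math.pi * (self.cell_radius / 2) ** 2))
        if self.max_area is None:
            self.max_area = math.ceil(math.pi * (3 * self.cell_radius) ** 2)
        if not (0 < self.occurrence_threshold <= 1):
            raise ValueError("occurrence_threshold must be in (0, 1]")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")
        for name in ("tophat_scale", "recon_scale", "hole_close_scale",
                     "area_open_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def white_tophat(frame: np.ndarray, tophat_scale: int) -> np.ndarray:
    """Local contrast correction: ``frame - opening(frame, tophat_scale)``.

    With an element much wider than the cells, the opening approximates the
    illumination field, so the residual is the cell signal on a flat
    background.  Nonnegative everywhere by anti-extensivity of the opening.
    """
    if tophat_scale < 1:
        raise ValueError("tophat_scale must be >= 1")
    return frame - opening(frame, tophat_scale)


def regional_minima(frame: np.ndarray) -> np.ndarray:
    """Boolean mask of the regional minima of ``frame``.

    A regional minimum is a connected (8-connected) flat zone with no
    strictly lower neighbor.
    """
    frame = np.asarray(frame)
    if frame.min() == frame.max():
        # one flat zone spanning the frame: a single regional minimum
        return np.ones(frame.shape, dtype=bool)
    connectivity = frame.ndim  # full connectivity: 8 in 2-D, 2 neighbors in 1-D
    return local_minima(frame, connectivity=connectivity)


def detect_frame_minima(frame: np.ndarray, cfg: MarkerConfig) -> np.ndarray:
    """Candidate nucleus minima of a single frame.

    Top-hat correction, then a closing by reconstruction at the (unitary by
    default) ``recon_scale`` to fill dark noise pits narrower than the
    element, then regional minima.
    """
    corrected = white_tophat(frame, cfg.tophat_scale)
    enhanced = closing_by_reconstruction(corrected, cfg.recon_scale)
    return regional_minima(enhanced)


def accumulate_minima(seq: ImageSequence, cfg: MarkerConfig) -> OccurrenceMap:
    """Sum the per-frame minima masks over the (optionally restricted)
    sequence: ``counts(x)`` = number of frames where ``x`` is a minimum."""
    lo, hi = cfg.frame_range if cfg.frame_range is not None else (0, len(seq))
    frames = seq.frames[lo:hi]
    if frames.shape[0] < 1:
        raise ValueError("frame range selects no frames")
    counts = np.zeros(seq.frame_shape, dtype=np.int64)
    for frame in frames:
        counts += detect_frame_minima(frame, cfg)
    return OccurrenceMap(counts=counts, n_frames=frames.shape[0])


def extract_markers(occ: OccurrenceMap, cfg: MarkerConfig) -> np.ndarray:
    """Reduce an occurrence map to the final binary nucleus-marker mask.

    Steps, in order: threshold the counts at ``occurrence_threshold`` of the
    frame count; morphological closing at ``hole_close_scale`` to fill small
    holes and connect close fragments; subtract the binary opening by
    reconstruction at ``area_open_scale`` (removes every component wide
    enough to contain that element, i.e. structures much larger than a
    nucleus); drop components whose pixel area falls outside
    ``[min_area, max_area]``.
    """
    thresh = cfg.occurrence_threshold * occ.n_frames
    mask = (occ.counts >= thresh).astype(np.uint8)
    if cfg.hole_close_scale > 0:
        mask = closing(mask, cfg.hole_close_scale)
    if cfg.area_open_scale > 0:
        # binary morphology as grayscale on {0,1}: single code path
        mask = mask - opening_by_reconstruction(mask, cfg.area_open_scale)
    labels, n = ndi.label(mask, structure=EIGHT_CONNECTED)
    if n:
        areas = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero((areas >= cfg.min_area) & (areas <= cfg.max_area)) + 1
        mask = np.isin(labels, keep).astype(bool)
    else:
        mask = mask.astype(bool)
    if not mask.any():
        warnings.warn("no-markers: marker extraction produced an empty mask",
                      stacklevel=2)
    return mask


def detect_markers(seq: ImageSequence, cfg: MarkerConfig | None = None) -> np.ndarray:
    """Full marker chain: per-frame minima, accumulation, filtering."""
    cfg = cfg if cfg is not None else MarkerConfig()
    return extract_markers(accumulate_minima(seq, cfg), cfg)
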