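"""Reading and writing sequences, masks and label images.

Sequences are accepted either as a multi-page TIFF stack or as a directory
of single-frame TIFF/PNG images in lexicographic order; all frames must
share one size.  Outputs are written as plain TIFF (8/16-bit) and PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .markers import ImageSequence

__all__ = ["load_sequence", "save_sequence", "save_mask", "save_labels",
           "save_overlay"]

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


def load_sequence(path: str | Path, frame_interval: float = 1.0 / 30.0) -> ImageSequence:
    """Load a sequence from a multi-page TIFF or an image directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames under {path}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("expected single-channel grayscale frames")
    return ImageSequence(frames=frames, frame_interval=frame_interval)


def save_sequence(path: str | Path, seq: ImageSequence) -> None:
    """Write the sequence as a multi-page TIFF."""
    tifffile.imwrite(path, seq.frames)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit TIFF (0/255 for visibility)."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def save_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def save_overlay(path: str | Path, image: np.ndarray, labels: np.ndarray) -> None:
    """Write an RGB PNG of the labels overlaid on the grayscale image."""
    from skimage.color import label2rgb

    image = np.asarray(image, dtype=np.float64)
    span = image.max() - image.min()
    norm = (image - image.min()) / (span if span else 1.0)
    rgb = label2rgb(np.asarray(labels), image=norm, bg_label=0, alpha=0.3)
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
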