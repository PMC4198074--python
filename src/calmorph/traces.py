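"""Per-cell fluorescence "volume" traces.

The calcium proxy for a cell is the discrete volume under its intensity
surface: the sum of pixel intensities over the cell's region (unit pixel
spacing), taken frame by frame.  Quantification defaults to the ORIGINAL
uncorrected frames — the top-hat changes absolute intensities, and it is
the raw luminance that tracks calcium concentration — over regions found
on the corrected images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .markers import EIGHT_CONNECTED, ImageSequence

__all__ = ["CellTrace", "cell_volume", "extract_traces", "traces_to_frame",
           "frame_to_traces"]


@dataclass
class CellTrace:
    """Fluorescence volume of one cell over time."""

    cell_id: int
    values: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval


def cell_volume(frame: np.ndarray, region: np.ndarray) -> float:
    """Sum of ``frame`` intensities over the boolean ``region`` mask."""
    frame = np.asarray(frame)
    region = np.asarray(region, dtype=bool)
    if region.shape != frame.shape:
        raise ValueError("region and frame shapes differ")
    if not region.any():
        raise ValueError("empty-region")
    return float(frame[region].sum(dtype=np.float64))


def extract_traces(seq: ImageSequence, labels: np.ndarray,
                   dilate_px: int = 0) -> list[CellTrace]:
    """One volume trace per positive label of ``labels``.

    Regions are fixed over time (the cells are assumed static).  An
    optional ``dilate_px`` grows each region by that many pixels to include
    the immediate neighborhood; overlaps arising from the dilation stay
    with the lower label.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    traces: list[CellTrace] = []
    flat = seq.frames.reshape(len(seq), -1)
    claimed = np.zeros(labels.shape, dtype=bool)
    for k in ids:
        region = labels == k
        if dilate_px > 0:
            region = ndi.binary_dilation(region, structure=EIGHT_CONNECTED,
                                         iterations=dilate_px)
            region &= ~claimed
            claimed |= region
        values = flat[:, region.ravel()].sum(axis=1, dtype=np.float64)
        traces.append(CellTrace(cell_id=int(k), values=values,
                                frame_interval=seq.frame_interval))
    return traces


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Tidy table (cell_id, frame, time_s, volume) from a list of traces."""
    parts = []
    for tr in traces:
        parts.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "frame": np.arange(len(tr)),
            "time_s": tr.times,
            "volume": tr.values,
        }))
    if not parts:
        return pd.DataFrame(columns=["cell_id", "frame", "time_s", "volume"])
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    """Inverse of :func:`traces_to_frame`."""
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy()
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        traces.append(CellTrace(cell_id=int(cid),
                                values=grp["volume"].to_numpy(),
                                frame_interval=dt))
    return traces
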