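"""Independent brute-force oracles for the morphology operators.

These restate the operator *definitions* directly — window scans over
shifted copies for erosion/dilation, iterate-until-idempotence for the
reconstructions, flat-zone flooding for regional minima — without going
through scipy.ndimage's filters or skimage's propagation algorithms, so
they are an independent route to the same mathematical objects.
"""

from __future__ import annotations

import numpy as np


def _shifted(f: np.ndarray, offsets) -> list[np.ndarray]:
    """Edge-replicated shifts of ``f`` for every offset in the window."""
    out = []
    if f.ndim == 1:
        n = f.size
        idx = np.arange(n)
        for d in offsets:
            out.append(f[np.clip(idx + d, 0, n - 1)])
    else:
        H, W = f.shape
        ii = np.arange(H)[:, None]
        jj = np.arange(W)[None, :]
        for di, dj in offsets:
            out.append(f[np.clip(ii + di, 0, H - 1), np.clip(jj + dj, 0, W - 1)])
    return out


def _window(mu: int, ndim: int):
    r = range(-mu, mu + 1)
    if ndim == 1:
        return list(r)
    return [(di, dj) for di in r for dj in r]


def brute_erode(f: np.ndarray, mu: int) -> np.ndarray:
    """Window minimum with replicated borders (definition of flat erosion)."""
    if mu == 0:
        return f.copy()
    return np.minimum.reduce(_shifted(f, _window(mu, f.ndim)))


def brute_dilate(f: np.ndarray, mu: int) -> np.ndarray:
    """Window maximum with replicated borders."""
    if mu == 0:
        return f.copy()
    return np.maximum.reduce(_shifted(f, _window(mu, f.ndim)))


def naive_reconstruct_by_dilation(mask: np.ndarray, marker: np.ndarray) -> np.ndarray:
    """Unit geodesic dilations iterated until nothing changes."""
    cur = marker.copy()
    for _ in range(10_000_000):
        nxt = np.minimum(mask, brute_dilate(cur, 1))
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt
    raise AssertionError("no-idempotence")


def naive_reconstruct_by_erosion(mask: np.ndarray, marker: np.ndarray) -> np.ndarray:
    cur = marker.copy()
    for _ in range(10_000_000):
        nxt = np.maximum(mask, brute_erode(cur, 1))
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt
    raise AssertionError("no-idempotence")


def _pad_edge(f: np.ndarray, mu: int) -> np.ndarray:
    return np.pad(f, mu, mode="edge")


def _crop(f: np.ndarray, mu: int) -> np.ndarray:
    return f[tuple(slice(mu, n - mu) for n in f.shape)]


def naive_opening_by_reconstruction(f: np.ndarray, mu: int) -> np.ndarray:
    """Fixpoint definition on the edge-replicated extension of ``f``."""
    if mu == 0:
        return f.copy()
    fe = _pad_edge(f, mu)
    return _crop(naive_reconstruct_by_dilation(fe, brute_erode(fe, mu)), mu)


def naive_closing_by_reconstruction(f: np.ndarray, mu: int) -> np.ndarray:
    if mu == 0:
        return f.copy()
    fe = _pad_edge(f, mu)
    return _crop(naive_reconstruct_by_erosion(fe, brute_dilate(fe, mu)), mu)


def flood_regional_minima(f: np.ndarray) -> np.ndarray:
    """Regional minima by explicit flat-zone flooding.

    Floods each 8-connected (2-connected in 1-D) flat zone and marks it iff
    no boundary neighbor is strictly lower.
    """
    f = np.asarray(f)
    if f.ndim == 1:
        f2 = f[None, :]
    else:
        f2 = f
    H, W = f2.shape
    visited = np.zeros((H, W), dtype=bool)
    out = np.zeros((H, W), dtype=bool)
    nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
            if (di, dj) != (0, 0)]
    for si in range(H):
        for sj in range(W):
            if visited[si, sj]:
                continue
            level = f2[si, sj]
            stack = [(si, sj)]
            zone = []
            visited[si, sj] = True
            is_min = True
            while stack:
                i, j = stack.pop()
                zone.append((i, j))
                for di, dj in nbrs:
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < H and 0 <= nj < W):
                        continue
                    if f2[ni, nj] == level:
                        if not visited[ni, nj]:
                            visited[ni, nj] = True
                            stack.append((ni, nj))
                    elif f2[ni, nj] < level:
                        is_min = False
            if is_min:
                for i, j in zone:
                    out[i, j] = True
    return out[0] if f.ndim == 1 else out
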