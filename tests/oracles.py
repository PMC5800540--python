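"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and fast scipy
primitives where they are the thing under test): thresholds by exhaustive
fixed-point scan, morphology by explicit disk sweeps, labeling by BFS
flood fill.
"""

from __future__ import annotations

import math
from collections import deque
from typing import List, Set, Tuple

import numpy as np


def intermeans_fixpoints(values: np.ndarray) -> Set[int]:
    """All t in [0, 254] satisfying t == round((mean<=t + mean>t) / 2)."""
    values = np.asarray(values).ravel()
    out = set()
    for t in range(255):
        low = values[values <= t]
        high = values[values > t]
        if low.size == 0 or high.size == 0:
            continue
        nt = int(math.floor((low.mean() + high.mean()) / 2.0 + 0.5))
        if nt == t:
            out.add(t)
    return out


def disk_offsets(radius: int) -> List[Tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def brute_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Disk closing by explicit dilation + erosion on a padded frame."""
    if radius == 0:
        return mask.copy()
    offs = disk_offsets(radius)
    pad = radius + 1
    m = np.pad(np.asarray(mask, dtype=bool), pad)
    H, W = m.shape
    dil = np.zeros_like(m)
    for dr, dc in offs:
        shifted = np.zeros_like(m)
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        shifted[r0:r1, c0:c1] = m[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        dil |= shifted
    ero = np.ones_like(m)
    for dr, dc in offs:
        shifted = np.zeros_like(m)
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        shifted[r0:r1, c0:c1] = dil[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        ero &= shifted
    return ero[pad:-pad, pad:-pad]


def flood_fill_label(mask: np.ndarray) -> Tuple[np.ndarray, int]:
    """8-connected labeling by BFS, labels assigned in raster order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if not mask[r, c] or labels[r, c]:
                continue
            current += 1
            queue = deque([(r, c)])
            labels[r, c] = current
            while queue:
                y, x = queue.popleft()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < H
                            and 0 <= nx < W
                            and mask[ny, nx]
                            and not labels[ny, nx]
                        ):
                            labels[ny, nx] = current
                            queue.append((ny, nx))
    return labels, current


def best_dice_threshold(channel: np.ndarray, reference: np.ndarray) -> int:
    """Exhaustive scan of t in [0,255] maximizing Dice(channel > t, ref)."""
    channel = np.asarray(channel)
    reference = np.asarray(reference, dtype=bool)
    best_t, best_d = 0, -1.0
    nref = int(reference.sum())
    for t in range(256):
        fg = channel > t
        denom = int(fg.sum()) + nref
        d = 1.0 if denom == 0 else 2.0 * int((fg & reference).sum()) / denom
        if d > best_d:
            best_d, best_t = d, t
    return best_t
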