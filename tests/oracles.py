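"""Independent brute-force reference implementations.

Deliberately written as plain per-pixel Python loops (or exhaustive scans)
so they share no code path with the package; tests compare the two exactly.
"""

from __future__ import annotations

import numpy as np


def brute_mask(pixels: np.ndarray, threshold: float) -> np.ndarray:
    out = np.zeros(pixels.shape, dtype=float)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            v = float(pixels[r, c])
            if v > threshold:
                out[r, c] = v
    return out


def brute_arosa(masked: np.ndarray) -> float:
    total = 0.0
    n = 0
    for r in range(masked.shape[0]):
        for c in range(masked.shape[1]):
            total += float(masked[r, c])
            n += 1
    return total / n


def brute_mpd(masked: np.ndarray, surface_rows: np.ndarray, scale: float) -> float:
    depths = []
    for r in range(masked.shape[0]):
        for c in range(masked.shape[1]):
            if masked[r, c] > 0:
                s = surface_rows[c]
                if s < 0:  # column without surface
                    continue
                if r >= s:
                    depths.append((r - s) * scale)
    return float(np.mean(depths)) if depths else 0.0


def brute_otsu(values: np.ndarray) -> int:
    """Exhaustive between-class-variance scan over integer thresholds."""
    values = np.asarray(values).astype(np.int64).ravel()
    best_t, best_var = None, -1.0
    for t in range(int(values.min()), int(values.max())):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var = var
            best_t = t
    return best_t
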