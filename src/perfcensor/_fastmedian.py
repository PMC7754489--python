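"""Exact 2-D median filtering with reflect padding.

Both detrending stages of the pipeline subtract a large-window (31-71 px)
median-filtered copy of a 256-square image, which dominates runtime. The
kernel here maintains a sorted sliding window along each row (batch remove /
merge-insert of one column per step), giving the exact same result as a
naive per-pixel median at a fraction of the cost. Padding is mirror
("reflect"): pixel -1 maps to 0, -2 to 1, and so on.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _medfilt2d_reflect(img: np.ndarray, w: int) -> np.ndarray:  # pragma: no cover - jitted
    half = w // 2
    rows, cols = img.shape
    out = np.empty_like(img)
    n = w * w
    sortwin = np.empty(n, img.dtype)
    colbuf = np.empty(w, img.dtype)

    def refl(i, m):
        if i < 0:
            return -i - 1
        if i >= m:
            return 2 * m - i - 1
        return i

    for r in range(rows):
        k = 0
        for dr in range(-half, half + 1):
            rr = refl(r + dr, rows)
            for dc in range(-half, half + 1):
                sortwin[k] = img[rr, refl(dc, cols)]
                k += 1
        sortwin.sort()
        out[r, 0] = sortwin[n // 2]
        for c in range(1, cols):
            rem_c = refl(c - 1 - half, cols)
            add_c = refl(c + half, cols)
            for i in range(w):
                colbuf[i] = img[refl(r - half + i, rows), rem_c]
            colbuf.sort()
            # batch-remove the departing column (multiset removal by value)
            j = 0
            dst = 0
            for src in range(n):
                v = sortwin[src]
                if j < w and v == colbuf[j]:
                    j += 1
                else:
                    sortwin[dst] = v
                    dst += 1
            for i in range(w):
                colbuf[i] = img[refl(r - half + i, rows), add_c]
            colbuf.sort()
            # merge-insert the arriving column from the high end
            src = n - w - 1
            j = w - 1
            dst = n - 1
            while j >= 0:
                if src >= 0 and sortwin[src] > colbuf[j]:
                    sortwin[dst] = sortwin[src]
                    src -= 1
                else:
                    sortwin[dst] = colbuf[j]
                    j -= 1
                dst -= 1
            out[r, c] = sortwin[n // 2]
    return out


def median_filter_reflect(img: np.ndarray, window: int) -> np.ndarray:
    """Median filter with a ``window x window`` square footprint and mirror
    padding; ``window`` must be odd. Exact (no quantization)."""
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    arr = np.ascontiguousarray(img, dtype=np.float64)
    return _medfilt2d_reflect(arr, window)
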