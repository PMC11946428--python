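"""JIT-compiled memory-movement kernels (with pure-numpy fallbacks).

The im2col gather is the bandwidth bottleneck of CPU convolution; a compiled
loop moves the short z-runs at several times the speed of strided numpy
assignment.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _im2col3_jit(xp, k, cols):
        B, C, Xp, Yp, Zp = xp.shape
        X = Xp - (k - 1)
        Y = Yp - (k - 1)
        Z = Zp - (k - 1)
        for b in range(B):
            t = 0
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        for c in range(C):
                            for x in range(X):
                                for y in range(Y):
                                    cols[b, t, c, x, y, :] = \
                                        xp[b, c, x + i, y + j, l:l + Z]
                        t += 1

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


# Free-list of released im2col buffers keyed by shape.  Re-using buffers
# avoids repeated page-fault cost on the ~100 MB gathers at full resolution.
_POOL: dict = {}


def take_buffer(shape) -> np.ndarray:
    free = _POOL.get(shape)
    if free:
        return free.pop()
    return np.empty(shape, dtype=np.float32)


def release_buffer(arr: np.ndarray) -> None:
    base = arr if arr.base is None else arr.base
    free = _POOL.setdefault(base.shape, [])
    if len(free) < 2:
        free.append(base)


def im2col3(xp: np.ndarray, k: int) -> np.ndarray:
    """Tap-major im2col for a cubic kernel, stride 1.

    xp is the padded input (B, C, Xp, Yp, Zp); returns (B, k^3, C, X, Y, Z)
    where spatial dims are the valid-convolution output sizes.  Buffers come
    from a free-list; callers hand them back via :func:`release_buffer`.
    """
    B, C, Xp, Yp, Zp = xp.shape
    X, Y, Z = Xp - (k - 1), Yp - (k - 1), Zp - (k - 1)
    cols = take_buffer((B, k ** 3, C, X, Y, Z))
    if HAVE_NUMBA:
        _im2col3_jit(xp, k, cols)
    else:
        t = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    cols[:, t] = xp[:, :, i:i + X, j:j + Y, l:l + Z]
                    t += 1
    return cols
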