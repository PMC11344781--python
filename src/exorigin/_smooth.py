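"""Sliding-window smoothing with fractional half-widths.

A window of width ``w`` is a symmetric moving average whose offsets ``|k| < floor(w)``
carry weight 1 and, when ``w`` is fractional, the two edge offsets ``|k| = floor(w)``
carry the remaining fraction split evenly.  Width 2.5 therefore gives the kernel
(0.25, 1, 1, 1, 0.25)/3.5 over offsets -2..+2, and an integer width ``w`` gives a
plain (2w-1)-point box.  The kernel is symmetric with its maximum at the centre, so
smoothing never moves the location of a peak.
"""

from __future__ import annotations

import numpy as np

__all__ = ["window_kernel", "smooth"]


def window_kernel(width: float) -> np.ndarray:
    """Normalised symmetric kernel for a sliding window of the given width."""
    if width <= 0:
        raise ValueError("width must be > 0")
    m = int(np.floor(width))
    frac = width - m
    if m == 0:
        return np.array([1.0])
    inner = np.ones(2 * m - 1)
    if frac > 0:
        k = np.concatenate(([frac / 2], inner, [frac / 2]))
    else:
        k = inner
    return k / k.sum()


def smooth(values: np.ndarray, width: float = 2.5) -> np.ndarray:
    """Smooth a 1-D array, renormalising the kernel at the edges.

    NaNs are propagated: positions whose window contains only NaN stay NaN;
    otherwise the average is over the finite values in the window.
    """
    v = np.asarray(values, dtype=float)
    k = window_kernel(width)
    if k.size == 1 or v.size == 0:
        return v.copy()
    half = k.size // 2
    finite = np.isfinite(v)
    vf = np.where(finite, v, 0.0)
    num = np.convolve(vf, k, mode="full")[half : half + v.size]
    den = np.convolve(finite.astype(float), k, mode="full")[half : half + v.size]
    out = np.full(v.size, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out
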