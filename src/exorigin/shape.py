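"""Sequence-based DNA shape profiles from a pentamer table, element-aligned
median +/- 95% CI signatures, and profile-shift comparison.

Per-bp features (minor groove width, propeller twist, electrostatic potential)
are looked up for the pentamer centred on each position; step features (roll,
helical twist) are assigned to the step's left bp.  The two bp at each end of a
sequence have no centred pentamer and are undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._smooth import smooth as smooth_profile_values

__all__ = [
    "ShapeProfile",
    "AlignedProfile",
    "read_shape_table",
    "write_shape_table",
    "shape_profile",
    "aligned_median_profile",
    "profile_shift",
    "smooth_profile",
]

PER_BP_FEATURES = ("MGW", "ProT", "EP")
STEP_FEATURES = ("Roll", "HelT")


@dataclass
class ShapeProfile:
    """Per-position feature arrays aligned to one sequence (NaN at margins)."""

    sequence: str
    features: dict[str, np.ndarray]

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.features[feature]


@dataclass
class AlignedProfile:
    """Median +/- bootstrap 95% CI of one feature across aligned windows."""

    feature: str
    offsets: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_sequences: int


def read_shape_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("pentamer")
    if len(df) != 4**5:
        raise ValueError(f"shape table must cover all 1024 pentamers, has {len(df)}")
    return df


def write_shape_table(table: pd.DataFrame, path: str | Path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)


def shape_profile(seq: str, table: pd.DataFrame) -> ShapeProfile:
    """Look up per-position shape features for one sequence (length >= 5)."""
    s = seq.upper()
    if len(s) < 5:
        raise ValueError("sequence must be at least 5 bp")
    n = len(s)
    feats = {f: np.full(n, np.nan) for f in table.columns}
    lookup = table.to_dict("index")
    for i in range(2, n - 2):
        penta = s[i - 2 : i + 3]
        row = lookup.get(penta)
        if row is None:  # contains N
            continue
        for f, v in row.items():
            feats[f][i] = v
    return ShapeProfile(s, feats)


def aligned_median_profile(
    seqs: Sequence[str],
    table: pd.DataFrame,
    feature: str,
    ci_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> AlignedProfile:
    """Per-offset median of a feature across element-centred windows.

    Windows must share one length; offsets run -(L//2)..+(L//2) around the
    window centre.  The 95% CI is a seeded percentile bootstrap over sequences;
    with fewer than 3 sequences the CI is undefined (NaN).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("all windows must share one length")
    mat = np.vstack([shape_profile(s, table)[feature] for s in seqs])
    ok = np.isfinite(mat).any(axis=0)  # margins (and all-N columns) stay NaN
    med = np.full(L, np.nan)
    med[ok] = np.nanmedian(mat[:, ok], axis=0)
    offsets = np.arange(L) - L // 2
    n = len(seqs)
    lo = np.full(L, np.nan)
    hi = np.full(L, np.nan)
    if n >= 3 and ci_boot >= 1:
        rng = np.random.default_rng(seed)
        boots = np.empty((ci_boot, int(ok.sum())))
        for b in range(ci_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = np.nanmedian(mat[idx][:, ok], axis=0)
        q = (1 - ci_level) / 2
        lo[ok] = np.minimum(np.nanquantile(boots, q, axis=0), med[ok])
        hi[ok] = np.maximum(np.nanquantile(boots, 1 - q, axis=0), med[ok])
    return AlignedProfile(feature, offsets, med, lo, hi, n)


def profile_shift(
    profile_a: np.ndarray | AlignedProfile,
    profile_b: np.ndarray | AlignedProfile,
    max_shift: int = 20,
) -> tuple[int, np.ndarray]:
    """Best integer alignment offset of profile a onto profile b.

    Returns the shift s minimising the mean squared difference between
    ``a[x + s]`` and ``b[x]`` over their overlap, and the per-offset difference
    track at that shift.  A profile translated downstream by +k therefore
    reports shift -k against the original.
    """
    a = profile_a.median if isinstance(profile_a, AlignedProfile) else np.asarray(profile_a, float)
    b = profile_b.median if isinstance(profile_b, AlignedProfile) else np.asarray(profile_b, float)
    best_s, best_mse = 0, np.inf
    for s in range(-max_shift, max_shift + 1):
        lo = max(0, -s)
        hi = min(len(b), len(a) - s)
        if hi - lo < 5:
            continue
        diff = a[lo + s : hi + s] - b[lo:hi]
        ok = np.isfinite(diff)
        if ok.sum() < 5:
            continue
        mse = float(np.mean(diff[ok] ** 2))
        if mse < best_mse - 1e-12:
            best_mse, best_s = mse, s
    lo = max(0, -best_s)
    hi = min(len(b), len(a) - best_s)
    return best_s, a[lo + best_s : hi + best_s] - b[lo:hi]


def smooth_profile(values: np.ndarray, width: float = 2.5) -> np.ndarray:
    """Sliding-window smoothing that never moves the location of per-bp values."""
    return smooth_profile_values(values, width)
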