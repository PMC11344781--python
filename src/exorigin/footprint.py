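"""Composite profiles, footprint boundary/width estimation, peak classes, occupancy.

A ChIP-Exo footprint is the protected interval between the modal forward-strand
5'-end position (the left exonuclease stop) and the modal reverse-strand 5'-end
position (the right stop).  Width is inclusive: ``right - left + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._smooth import smooth
from .io import GenomicInterval, TagTrack

__all__ = [
    "CompositeProfile",
    "FootprintCall",
    "NoCall",
    "PeakClass",
    "composite_profile",
    "estimate_footprint_width",
    "call_site_footprint",
    "localization_ratio",
    "classify_origin_peaks",
    "occupancy",
]


@dataclass
class CompositeProfile:
    """Stranded tag counts on an offset axis -W..+W relative to aligned anchors."""

    halfwidth: int
    forward: np.ndarray
    reverse: np.ndarray
    n_anchors: int
    n_tags: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)


@dataclass(frozen=True)
class FootprintCall:
    """A called protected interval with boundary modes in genomic coordinates."""

    interval: GenomicInterval
    left: int   # forward-strand boundary mode
    right: int  # reverse-strand boundary mode
    n_tags: int

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError("footprint needs left < right")

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    @property
    def centre(self) -> int:
        return (self.left + self.right) // 2


@dataclass(frozen=True)
class NoCall:
    """A site where no footprint could be called (a value, not an error)."""

    reason: str


@dataclass
class PeakClass:
    label: str  # "single" | "dominant" | "multi" | "no call"
    peak_positions: list[int]
    peak_heights: list[float]


def composite_profile(
    tags: TagTrack,
    anchors: Sequence[tuple[str, int, str]],
    halfwidth: int,
) -> CompositeProfile:
    """Aggregate stranded tags around anchors into one oriented offset axis.

    Anchors are (chrom, position, strand).  For '-' strand anchors offsets are
    negated and strands swapped, so every origin contributes in a common local
    orientation.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    if not anchors:
        raise ValueError("anchors must be non-empty")
    W = halfwidth
    fwd = np.zeros(2 * W + 1, dtype=float)
    rev = np.zeros(2 * W + 1, dtype=float)
    n_tags = 0
    for chrom, pos, strand in anchors:
        flip = strand == "-"
        for tag_strand, vec in (("+", fwd), ("-", rev)):
            src = ("-" if tag_strand == "+" else "+") if flip else tag_strand
            p, c = tags.positions_in(chrom, src, pos - W, pos + W + 1)
            if len(p) == 0:
                continue
            off = (pos - p) if flip else (p - pos)
            np.add.at(vec, off + W, c)
            n_tags += int(c.sum())
    return CompositeProfile(W, fwd, rev, len(anchors), n_tags)


def _mode(
    values: np.ndarray,
    raw: np.ndarray | None = None,
    prefer_near: int | None = None,
) -> int:
    """Index of the maximum of ``values``.

    Ties (the fractional kernel has a flat top, so lone spikes smooth into
    plateaus) are broken by the raw unsmoothed height, then by proximity to
    ``prefer_near``, then by lowest index."""
    idx = np.flatnonzero(values == values.max())
    if raw is not None and len(idx) > 1:
        idx = idx[raw[idx] == raw[idx].max()]
    if prefer_near is None or len(idx) == 1:
        return int(idx[0])
    return int(idx[np.argmin(np.abs(idx - prefer_near))])


def estimate_footprint_width(
    profile: CompositeProfile, smooth_width: float = 2.5
) -> tuple[int, int, int]:
    """(width, left offset, right offset) from composite boundary modes.

    Left = argmax of the smoothed forward vector, right = argmax of the smoothed
    reverse vector (inclusive).  Equal-height ties resolve towards the anchor.
    """
    if profile.forward.sum() == 0 or profile.reverse.sum() == 0:
        raise ValueError("profile must be non-zero on both strands")
    W = profile.halfwidth
    f = smooth(profile.forward, smooth_width)
    r = smooth(profile.reverse, smooth_width)
    left = _mode(f, profile.forward, prefer_near=W) - W
    right = _mode(r, profile.reverse, prefer_near=W) - W
    if left >= right:
        raise ValueError(
            f"no protected region: forward mode {left} not left of reverse mode {right}"
        )
    return right - left + 1, left, right


def call_site_footprint(
    tags: TagTrack,
    region: GenomicInterval,
    smooth_width: float = 2.5,
    min_tags_per_strand: int = 10,
) -> FootprintCall | NoCall:
    """Call one footprint inside a region from per-site boundary modes."""
    chrom = region.chrom
    n_f = tags.count_in(chrom, "+", region.start, region.end)
    n_r = tags.count_in(chrom, "-", region.start, region.end)
    if n_f < min_tags_per_strand or n_r < min_tags_per_strand:
        return NoCall(f"insufficient tags (fwd {n_f}, rev {n_r})")
    span = len(region)
    fwd = np.zeros(span)
    rev = np.zeros(span)
    for strand, vec in (("+", fwd), ("-", rev)):
        p, c = tags.positions_in(chrom, strand, region.start, region.end)
        np.add.at(vec, p - region.start, c)
    centre_idx = span // 2
    left = _mode(smooth(fwd, smooth_width), fwd, prefer_near=centre_idx) + region.start
    right = _mode(smooth(rev, smooth_width), rev, prefer_near=centre_idx) + region.start
    if left >= right:
        return NoCall("anti-oriented boundary modes")
    return FootprintCall(region, left, right, n_f + n_r)


def localization_ratio(
    tags: TagTrack,
    chrom: str,
    centre: int,
    inner: int = 60,
    outer: int = 800,
) -> float:
    """Fraction of tags in the inner window among those in the outer window.

    Windows are centred: centre +/- inner/2 vs centre +/- outer/2.  Returns NaN
    when the outer window is empty (0/0 undefined).
    """
    if inner >= outer:
        raise ValueError("need inner < outer")
    n_in = tags.count_window(chrom, centre - inner // 2, centre + (inner + 1) // 2)
    n_out = tags.count_window(chrom, centre - outer // 2, centre + (outer + 1) // 2)
    if n_out == 0:
        return float("nan")
    return n_in / n_out


def classify_origin_peaks(
    tags: TagTrack,
    region: GenomicInterval,
    footprint_width: int = 64,
    smooth_width: float = 15.0,
    r_multi: float = 0.5,
    noise_floor_frac: float = 0.1,
    min_separation: int = 40,
    min_tags: int = 20,
) -> PeakClass:
    """Classify an origin as single / dominant / multi by its DH peak structure.

    A midpoint-density score pairs forward signal half a footprint upstream with
    reverse signal half a footprint downstream (geometric mean), is smoothed,
    and local maxima above a noise floor (max of 3x the regional median and
    ``noise_floor_frac`` of the primary peak) are called peaks.  Label: single
    with exactly one peak; multi when a secondary peak reaches ``r_multi`` of
    the primary; dominant otherwise.
    """
    span = len(region)
    k = int(np.ceil(smooth_width))
    if span < 2 * k + 1:
        raise ValueError("region too small for the smoothing kernel")
    chrom = region.chrom
    if tags.count_window(chrom, region.start, region.end) < min_tags:
        return PeakClass("no call", [], [])
    fwd = np.zeros(span)
    rev = np.zeros(span)
    for strand, vec in (("+", fwd), ("-", rev)):
        p, c = tags.positions_in(chrom, strand, region.start, region.end)
        np.add.at(vec, p - region.start, c)
    f = smooth(fwd, smooth_width)
    r = smooth(rev, smooth_width)
    half = footprint_width // 2
    mid = np.zeros(span)
    lo, hi = half, span - half
    if hi <= lo:
        return PeakClass("no call", [], [])
    mid[lo:hi] = np.sqrt(f[lo - half : hi - half] * r[lo + half - 1 : hi + half - 1])
    if mid.max() <= 0:
        return PeakClass("no call", [], [])
    floor = max(3.0 * float(np.median(mid)), noise_floor_frac * float(mid.max()))
    is_max = np.zeros(span, dtype=bool)
    is_max[1:-1] = (mid[1:-1] >= mid[:-2]) & (mid[1:-1] > mid[2:]) & (mid[1:-1] > floor)
    idx = np.flatnonzero(is_max)
    # merge maxima closer than min_separation, keeping the higher
    peaks: list[int] = []
    for i in sorted(idx, key=lambda j: -mid[j]):
        if all(abs(i - j) >= min_separation for j in peaks):
            peaks.append(int(i))
    peaks.sort()
    if not peaks:
        return PeakClass("no call", [], [])
    heights = [float(mid[i]) for i in peaks]
    positions = [region.start + i for i in peaks]
    if len(peaks) == 1:
        label = "single"
    else:
        ordered = sorted(heights, reverse=True)
        label = "multi" if ordered[1] >= r_multi * ordered[0] else "dominant"
    return PeakClass(label, positions, heights)


def occupancy(
    tags: TagTrack,
    chrom: str,
    centre: int,
    window: int = 100,
    library_size: int | None = None,
) -> float:
    """Tag count in centre +/- window/2, scaled per million library tags."""
    if window <= 0:
        raise ValueError("window must be > 0")
    n = tags.count_window(chrom, centre - window // 2, centre + (window + 1) // 2)
    lib = library_size if library_size is not None else tags.total()
    if lib <= 0:
        return 0.0
    return n * 1e6 / lib
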