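"""Origin-geometry statistics: element distances, DH-ORC overlap, B2 multiplicity,
downstream-window localisation, spacing periodicity, and peak/valley enrichment.

Distance conventions: all element distances are anchor-to-anchor (conserved A of
the A-element to conserved T of B2) in origin-local orientation (downstream
positive along the A-element strand).  The DH downstream edge is
``centre + floor(width / 2)``, which makes a 64 bp DH with a 51 bp centre-to-B2
distance sit 19 bp from the B2 anchor when measured from the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._smooth import smooth
from .footprint import FootprintCall, NoCall
from .motif import B2Assignment

__all__ = [
    "OriginAnnotation",
    "SpacingSpectrum",
    "element_distance",
    "dh_overlap_fraction",
    "b2_multiplicity",
    "downstream_window_fraction",
    "mcm_to_b2_distance",
    "spacing_spectrum",
    "peak_valley_enrichment",
    "at_skew",
]


@dataclass
class OriginAnnotation:
    """Per-origin geometry aggregated across pipeline stages."""

    origin_id: str
    chrom: str
    a_anchor: int
    a_strand: str
    b2: B2Assignment | None = None
    orc_calls: dict[str, FootprintCall | NoCall] = field(default_factory=dict)
    dh_call: FootprintCall | NoCall | None = None
    mcm_occupancy: float = float("nan")
    orc_occupancy: dict[str, float] = field(default_factory=dict)
    cluster: str = ""   # C1..C4
    quintile: str = ""  # M1..M5

    def local(self, genomic: int) -> int:
        """Origin-local coordinate: downstream-positive along the A strand."""
        return genomic - self.a_anchor if self.a_strand == "+" else self.a_anchor - genomic


def element_distance(a_anchor: int, b2_anchor: int, a_strand: str) -> int:
    """Anchor-to-anchor distance in origin-local orientation.

    Positive when the B2 anchor is downstream of the A anchor; negative
    (upstream) values are returned signed so callers can flag them.
    """
    return b2_anchor - a_anchor if a_strand == "+" else a_anchor - b2_anchor


def dh_overlap_fraction(
    annotations: Sequence[OriginAnnotation], phase: str = "G1"
) -> tuple[float, int, int]:
    """Fraction of DH footprint centres inside the phase ORC footprint.

    Returns (fraction, n_evaluated, n_excluded); origins lacking either call
    are excluded and counted.
    """
    n_in = n_eval = n_excl = 0
    for ann in annotations:
        orc = ann.orc_calls.get(phase)
        if not isinstance(ann.dh_call, FootprintCall) or not isinstance(orc, FootprintCall):
            n_excl += 1
            continue
        n_eval += 1
        if orc.left <= ann.dh_call.centre <= orc.right:
            n_in += 1
    frac = n_in / n_eval if n_eval else float("nan")
    return frac, n_eval, n_excl


def b2_multiplicity(
    assignments: Sequence[B2Assignment | None],
) -> tuple[dict[str, int], dict[str, int], list[int]]:
    """Tally B2 multiplicity {0, 1, 2-5, >5}, orientations, and inter-B2 intervals."""
    tally = {"0": 0, "1": 0, "2-5": 0, ">5": 0}
    orient = {"correct": 0, "incorrect": 0}
    intervals: list[int] = []
    for a in assignments:
        m = a.multiplicity if a is not None else 0
        if m == 0:
            tally["0"] += 1
        elif m == 1:
            tally["1"] += 1
        elif m <= 5:
            tally["2-5"] += 1
        else:
            tally[">5"] += 1
        if a is None:
            continue
        if a.orientations:
            orient[a.orientations[0]] += 1
        if m >= 2:
            d = sorted(a.distances)
            intervals.extend(int(d[i + 1] - d[i]) for i in range(len(d) - 1))
    return tally, orient, intervals


def _dh_edge_local(ann: OriginAnnotation) -> int | None:
    """Origin-local coordinate of the DH downstream edge (centre + width//2)."""
    if not isinstance(ann.dh_call, FootprintCall):
        return None
    return ann.local(ann.dh_call.centre) + ann.dh_call.width // 2


def downstream_window_fraction(
    annotations: Sequence[OriginAnnotation], window: int = 66
) -> tuple[float, int]:
    """Fraction of first correctly-orientated B2 anchors within ``window`` bp
    immediately downstream of the DH footprint edge.

    Counted over origins that have both a DH call and a correct-orientation B2;
    "within" is 1..window bp past the edge, inclusive.
    """
    n_in = n_eval = 0
    for ann in annotations:
        edge = _dh_edge_local(ann)
        if edge is None or ann.b2 is None:
            continue
        fc = ann.b2.first_correct
        if fc is None:
            continue
        _, dist = fc
        n_eval += 1
        if 1 <= dist - edge <= window:
            n_in += 1
    return (n_in / n_eval if n_eval else float("nan")), n_eval


def mcm_to_b2_distance(
    annotations: Sequence[OriginAnnotation],
) -> tuple[list[int], list[int], float, float]:
    """Centre-to-anchor and edge-to-anchor DH -> first-correct-B2 distances.

    Returns (centre distances, edge distances, median centre, median edge); for
    every origin, centre - edge distance equals width // 2 by construction.
    """
    centre_d: list[int] = []
    edge_d: list[int] = []
    for ann in annotations:
        if not isinstance(ann.dh_call, FootprintCall) or ann.b2 is None:
            continue
        fc = ann.b2.first_correct
        if fc is None:
            continue
        _, dist = fc
        c_local = ann.local(ann.dh_call.centre)
        centre_d.append(abs(dist - c_local))
        edge_d.append(abs(dist - c_local) - ann.dh_call.width // 2)
    med_c = float(np.median(centre_d)) if centre_d else float("nan")
    med_e = float(np.median(edge_d)) if edge_d else float("nan")
    return centre_d, edge_d, med_c, med_e


@dataclass
class SpacingSpectrum:
    """Histogram of A-B2 anchor distances with extrema and dominant period."""

    distances: np.ndarray       # bp axis, 1 bp resolution
    counts: np.ndarray
    smoothed: np.ndarray
    peaks: list[int]            # bp values of local maxima
    valleys: list[int]
    period: int | None          # dominant period, bp; None = no periodicity
    period_pvalue: float

    @property
    def has_periodicity(self) -> bool:
        return self.period is not None


def _alternating_extrema(sm: np.ndarray, axis: np.ndarray) -> tuple[list[int], list[int]]:
    """Plateau-aware local extrema; a flat run reports its centre position.

    The smoothing kernel's flat top turns isolated histogram spikes into short
    plateaus, so extrema are classified per run of equal values.  A run is a
    peak when both flanking values are lower (a missing flank counts as lower),
    a valley when both are higher."""
    peaks, valleys = [], []
    n = len(sm)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[j + 1] if j + 1 < n else -np.inf
        centre = int(axis[(i + j) // 2])
        if left < sm[i] and right < sm[i]:
            peaks.append(centre)
        elif left > sm[i] and right > sm[i]:
            valleys.append(centre)
        i = j + 1
    return peaks, valleys


def spacing_spectrum(
    distances: Sequence[int],
    bp_range: tuple[int, int] = (41, 141),
    smooth_width: float = 2.5,
    lag_range: tuple[int, int] = (8, 20),
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> SpacingSpectrum:
    """Distance histogram at 1 bp resolution with periodicity detection.

    The dominant period is the lag of the autocorrelation maximum of the
    mean-subtracted smoothed histogram within ``lag_range``; significance comes
    from a permutation null (histogram bins shuffled), and a non-significant
    maximum yields period None ("no periodicity").
    """
    d = np.asarray(distances, dtype=int)
    d = d[(d >= bp_range[0]) & (d <= bp_range[1])]
    if len(d) < 30:
        raise ValueError("need >= 30 distances in range")
    axis = np.arange(bp_range[0], bp_range[1] + 1)
    counts = np.bincount(d - bp_range[0], minlength=len(axis)).astype(float)
    sm = smooth(counts, smooth_width)
    peaks, valleys = _alternating_extrema(sm, axis)

    centred = sm - sm.mean()

    def max_lag_ac(v: np.ndarray) -> tuple[int, float]:
        best_lag, best = lag_range[0], -np.inf
        denom = float(v @ v) or 1.0
        for lag in range(lag_range[0], lag_range[1] + 1):
            ac = float(v[:-lag] @ v[lag:]) / denom
            if ac > best:
                best, best_lag = ac, lag
        return best_lag, best

    lag, observed = max_lag_ac(centred)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(counts)
        pc = smooth(perm, smooth_width)
        null[i] = max_lag_ac(pc - pc.mean())[1]
    pval = float((1 + (null >= observed).sum()) / (1 + n_permutations))
    period = int(lag) if pval < alpha else None
    return SpacingSpectrum(axis, counts, sm, peaks, valleys, period, pval)


def peak_valley_enrichment(
    annotations: Sequence[OriginAnnotation],
    spectrum: SpacingSpectrum,
) -> tuple[dict[str, dict[str, int]], float]:
    """Label each origin peak/valley by its A-B2 distance; MCM abundance share.

    Every origin with a finite A-B2 distance gets the label of its nearest
    spectrum extremum (ties go to peak).  Returns a per-quintile contingency
    table and the share of summed MCM occupancy carried by peak-labelled
    origins.
    """
    if not spectrum.peaks:
        raise ValueError("spectrum has no peaks")
    table: dict[str, dict[str, int]] = {}
    occ_peak = occ_total = 0.0
    for ann in annotations:
        if ann.b2 is None or ann.b2.first_correct is None:
            continue
        _, dist = ann.b2.first_correct
        d_peak = min(abs(dist - p) for p in spectrum.peaks)
        d_valley = min((abs(dist - v) for v in spectrum.valleys), default=np.inf)
        label = "peak" if d_peak <= d_valley else "valley"
        cls = ann.quintile or "all"
        table.setdefault(cls, {"peak": 0, "valley": 0})[label] += 1
        if np.isfinite(ann.mcm_occupancy):
            occ_total += ann.mcm_occupancy
            if label == "peak":
                occ_peak += ann.mcm_occupancy
    share = occ_peak / occ_total if occ_total > 0 else float("nan")
    return table, share


def at_skew(seq: str, window: int = 21) -> np.ndarray:
    """Per-position AT skew (nA - nT)/(nA + nT) over a centred window.

    ``window`` must be odd.  Positions whose window holds no A or T are NaN."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = seq.upper()
    a = np.array([c == "A" for c in s], dtype=float)
    t = np.array([c == "T" for c in s], dtype=float)
    k = np.ones(window)
    half = window // 2
    na = np.convolve(a, k, mode="full")[half : half + len(s)]
    nt = np.convolve(t, k, mode="full")[half : half + len(s)]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (na - nt) / (na + nt)
    return out
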