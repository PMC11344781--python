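"""Occupancy clustering (C1-C4 / M1-M5), phase changes, paired tests, and
discovery of G1-only non-origin ORC sites with TSS annotation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .footprint import FootprintCall, NoCall, call_site_footprint, occupancy
from .io import GenomicInterval, TagTrack, TssSet

__all__ = [
    "NonOriginSite",
    "assign_quartile_clusters",
    "assign_quintiles",
    "phase_change",
    "paired_signed_rank",
    "paired_t_test",
    "discover_nonorigin_sites",
    "annotate_tss_proximity",
]


def _rank_blocks(
    occ: Sequence[float],
    ids: Sequence[str] | None,
    n_blocks: int,
    prefix: str,
) -> list[str]:
    n = len(occ)
    if n < n_blocks:
        raise ValueError(f"need at least {n_blocks} values, got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (-occ[i], ids[i]))
    base, extra = divmod(n, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    labels = [""] * n
    pos = 0
    for b, size in enumerate(sizes):
        for i in order[pos : pos + size]:
            labels[i] = f"{prefix}{b + 1}"
        pos += size
    return labels


def assign_quartile_clusters(
    occ: Sequence[float], ids: Sequence[str] | None = None
) -> list[str]:
    """C1..C4 by descending occupancy; near-equal contiguous blocks.

    Sizes differ by at most 1 with extra members in earlier clusters (323
    origins -> 81, 81, 81, 80).  Ties are broken by id for determinism.
    """
    return _rank_blocks(occ, ids, 4, "C")


def assign_quintiles(occ: Sequence[float], ids: Sequence[str] | None = None) -> list[str]:
    """M1..M5 quintiles by descending occupancy, M1 highest."""
    return _rank_blocks(occ, ids, 5, "M")


def phase_change(
    occ_a: Sequence[float],
    occ_b: Sequence[float],
    groups: Sequence[str],
    statistic: str = "mean",
) -> dict[str, float]:
    """Per-group percent change 100 * (stat_b - stat_a) / stat_a.

    Groups with zero phase-a statistic yield NaN (undefined, flagged)."""
    if len(occ_a) != len(occ_b) or len(occ_a) != len(groups):
        raise ValueError("occ_a, occ_b, groups must be the same length")
    agg = np.mean if statistic == "mean" else np.median
    out: dict[str, float] = {}
    for g in sorted(set(groups)):
        idx = [i for i, lab in enumerate(groups) if lab == g]
        a = float(agg([occ_a[i] for i in idx]))
        b = float(agg([occ_b[i] for i in idx]))
        out[g] = float("nan") if a == 0 else 100.0 * (b - a) / a
    return out


def paired_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are removed; the exact null distribution is used for
    n <= ``exact_max_n`` and a normal approximation with continuity correction
    above.  All-zero differences return (0, 1) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if len(d) < 5:
        raise ValueError("need >= 5 nonzero differences")
    method = "exact" if len(d) <= exact_max_n else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(
    x: Sequence[float], y: Sequence[float], paired: bool = True
) -> tuple[float, float]:
    """Two-sided Student's t-test companion (paired by default)."""
    if paired:
        res = stats.ttest_rel(x, y)
    else:
        res = stats.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class NonOriginSite:
    """A G1-specific ORC site outside the origin mask."""

    interval: GenomicInterval
    centre: int
    occupancy_g1: float
    occupancy_g2: float
    footprint: FootprintCall | NoCall
    tss_distance: float = float("nan")  # signed, upstream negative
    gene_id: str = ""
    promoter: bool = False

    @property
    def footprint_width(self) -> float:
        return self.footprint.width if isinstance(self.footprint, FootprintCall) else float("nan")


def _origin_mask(
    origins: Sequence[GenomicInterval], buffer: int
) -> dict[str, list[tuple[int, int]]]:
    mask: dict[str, list[tuple[int, int]]] = {}
    for iv in origins:
        mask.setdefault(iv.chrom, []).append((iv.start - buffer, iv.end + buffer))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in mask.items():
        spans.sort()
        out = [spans[0]]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _in_mask(mask: dict[str, list[tuple[int, int]]], chrom: str, start: int, end: int) -> bool:
    for s, e in mask.get(chrom, []):
        if start < e and end > s:
            return True
    return False


def discover_nonorigin_sites(
    tags_g1: TagTrack,
    tags_g2: TagTrack,
    origins: Sequence[GenomicInterval],
    chrom_lengths: dict[str, int],
    window: int = 200,
    step: int = 50,
    buffer: int = 1000,
    k_enrich: float = 5.0,
    k_g2: float = 0.5,
    footprint_halfwidth: int = 150,
    min_tags_per_strand: int = 10,
) -> list[NonOriginSite]:
    """Sliding-window scan for sites enriched in G1 but quiet in G2.

    A window outside every origin +/- ``buffer`` is a candidate when its G1
    count is at least ``k_enrich`` times the genomic background (the mean
    masked-genome window count) and its G2 count is at most ``k_g2`` times its
    G1 count.  Overlapping candidate windows are merged; each merged site gets
    a tag-centroid centre, occupancies, and a per-site footprint call.
    Discovered sites never intersect the origin mask.
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    mask = _origin_mask(origins, buffer)
    lib_g1 = tags_g1.total()
    lib_g2 = tags_g2.total()

    # genomic background: mean G1 window count over the unmasked genome
    unmasked_bp = 0
    for chrom, L in chrom_lengths.items():
        masked = sum(min(e, L) - max(s, 0) for s, e in mask.get(chrom, []))
        unmasked_bp += max(L - masked, 0)
    masked_tags = sum(
        tags_g1.count_window(chrom, max(s, 0), min(e, chrom_lengths.get(chrom, e)))
        for chrom, spans in mask.items()
        for s, e in spans
        if chrom in chrom_lengths
    )
    bg_per_bp = max(lib_g1 - masked_tags, 0) / max(unmasked_bp, 1)
    threshold = k_enrich * max(bg_per_bp * window, 1.0)

    candidates: dict[str, list[tuple[int, int]]] = {}
    for chrom, L in chrom_lengths.items():
        for start in range(0, max(L - window, 0) + 1, step):
            end = start + window
            if _in_mask(mask, chrom, start, end):
                continue
            n1 = tags_g1.count_window(chrom, start, end)
            if n1 < threshold:
                continue
            n2 = tags_g2.count_window(chrom, start, end) * (
                lib_g1 / lib_g2 if lib_g2 else 1.0
            )
            if n2 > k_g2 * n1:
                continue
            candidates.setdefault(chrom, []).append((start, end))

    sites: list[NonOriginSite] = []
    for chrom in sorted(candidates):
        spans = sorted(candidates[chrom])
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            pos_f, cnt_f = tags_g1.positions_in(chrom, "+", s, e)
            pos_r, cnt_r = tags_g1.positions_in(chrom, "-", s, e)
            total = cnt_f.sum() + cnt_r.sum()
            centre = int(
                round((pos_f @ cnt_f + pos_r @ cnt_r) / total)
            ) if total else (s + e) // 2
            occ1 = occupancy(tags_g1, chrom, centre, library_size=lib_g1)
            occ2 = occupancy(tags_g2, chrom, centre, library_size=lib_g2)
            L = chrom_lengths[chrom]
            region = GenomicInterval(
                chrom, max(0, centre - footprint_halfwidth),
                min(L, centre + footprint_halfwidth),
            )
            fp = call_site_footprint(
                tags_g1, region, min_tags_per_strand=min_tags_per_strand
            )
            assert not _in_mask(mask, chrom, s, e), "site intersects the origin mask"
            sites.append(NonOriginSite(GenomicInterval(chrom, s, e), centre, occ1, occ2, fp))
    return sites


def annotate_tss_proximity(
    sites: Sequence[NonOriginSite],
    tss: TssSet,
    cutoffs: Sequence[int] = (380,),
    promoter_window: int = 1000,
) -> pd.DataFrame:
    """Annotate sites with the signed distance to the nearest TSS.

    Distance is gene-local: negative upstream of the TSS, positive downstream.
    Returns a one-row summary with, per cutoff, the fraction of sites within
    |distance| <= cutoff, plus the fraction in the 1 kbp upstream (promoter)
    window.  Sites are annotated in place.
    """
    if len(tss) == 0:
        raise ValueError("TSS set is empty")
    by_chrom = tss.by_chrom()
    dists: list[float] = []
    for site in sites:
        entries = by_chrom.get(site.interval.chrom)
        if not entries:
            site.tss_distance = float("nan")
            continue
        best = None
        for pos, strand, gid in entries:
            d = site.centre - pos if strand == "+" else pos - site.centre
            if best is None or abs(d) < abs(best[0]):
                best = (d, gid)
        site.tss_distance = float(best[0])
        site.gene_id = best[1]
        site.promoter = -promoter_window <= best[0] < 0
        dists.append(float(best[0]))
    arr = np.array(dists) if dists else np.empty(0)
    row = {"n_sites": len(sites), "n_annotated": len(arr)}
    for c in cutoffs:
        row[f"frac_within_{c}bp"] = float((np.abs(arr) <= c).mean()) if len(arr) else float("nan")
    row["frac_upstream_1kbp"] = (
        float(((arr < 0) & (arr >= -promoter_window)).mean()) if len(arr) else float("nan")
    )
    return pd.DataFrame([row])
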