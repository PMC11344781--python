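"""Position weight matrices: scoring, exact score p-values, scanning, and ZOOPS EM.

The A-element (ARS consensus sequence, ACS) and the B2-element are represented as
:class:`MotifModel` objects with an *anchor column* — the conserved central adenine
of the ACS and the conserved thymidine of B2 — because all origin distance
conventions are measured anchor-to-anchor.

Score p-values are computed from the full distribution of the log-odds score of a
background word, obtained by dynamic programming over per-column score atoms.  For
ordinary motif widths the distribution is exact; very wide motifs fall back to an
integerised grid of configurable resolution.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import GenomicInterval, GenomeSequence

__all__ = [
    "MotifModel",
    "MotifHit",
    "B2Assignment",
    "EMResult",
    "log_odds_score",
    "score_distribution",
    "score_pvalue",
    "scan",
    "scan_window",
    "refine_motif_em",
    "assign_b2",
    "read_meme_motif",
    "write_meme_motif",
    "packaged_motif",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class MotifModel:
    """A PWM over A,C,G,T with background, pseudocount and an anchor column."""

    name: str
    matrix: np.ndarray  # shape (4, w); columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01
    anchor: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("matrix columns must sum to 1")
        if self.anchor is not None and not (0 <= self.anchor < self.width):
            raise ValueError("anchor column out of range")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """4 x w log2 odds with pseudocount-regularised probabilities."""
        p = (self.matrix + self.pseudocount * self.background[:, None]) / (
            1.0 + self.pseudocount
        )
        return np.log2(p / self.background[:, None])

    def information_content(self) -> float:
        """Total relative entropy vs background, in bits."""
        p = (self.matrix + self.pseudocount * self.background[:, None]) / (
            1.0 + self.pseudocount
        )
        return float(np.sum(p * np.log2(p / self.background[:, None])))

    def reverse_complement(self) -> "MotifModel":
        anchor = None if self.anchor is None else self.width - 1 - self.anchor
        return MotifModel(
            name=self.name + "_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            anchor=anchor,
        )

    def default_anchor(self, base: str) -> int:
        """Column where ``base`` is most informative (highest probability)."""
        return int(self.matrix[_CODE[base]].argmax())

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=self.matrix[:, j]) for j in range(self.width)]
        return "".join(BASES[i] for i in cols)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence."""

    interval: GenomicInterval
    strand: str
    score: float  # bits
    pvalue: float
    anchor_pos: int  # strand-aware genomic position of the anchor column

    @property
    def start(self) -> int:
        return self.interval.start


@dataclass
class B2Assignment:
    """B2 hits for one origin, ordered by distance from the A-element anchor."""

    origin_id: str
    hits: list[MotifHit]
    orientations: list[str]  # "correct" / "incorrect", parallel to hits
    distances: list[int]  # anchor-to-anchor bp, origin-local orientation

    @property
    def multiplicity(self) -> int:
        return len(self.hits)

    @property
    def first_correct(self) -> tuple[MotifHit, int] | None:
        for hit, orient, dist in zip(self.hits, self.orientations, self.distances):
            if orient == "correct":
                return hit, dist
        return None


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def log_odds_score(motif: MotifModel, word: str) -> float:
    """Log2-odds score of one word of the motif's width, in bits."""
    if len(word) != motif.width:
        raise ValueError(f"word length {len(word)} != motif width {motif.width}")
    codes = _encode(word.upper())
    if (codes < 0).any():
        raise ValueError("word contains non-ACGT letters")
    lod = motif.log_odds()
    return float(lod[codes, np.arange(motif.width)].sum())


# -- score distribution -------------------------------------------------------

_EXACT_ATOM_CAP = 300_000
_ROUND = 10  # decimals for merging exactly-equal score atoms


def score_distribution(
    motif: MotifModel, resolution: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the score of a random background word.

    Returns (scores, survival) with scores ascending and
    ``survival[i] = P(score >= scores[i])``.  Exact while the number of distinct
    score atoms stays below a cap; wider motifs are rebinned onto an integer grid
    with ``resolution`` bins per column.  Cached per motif instance.
    """
    if resolution < 100:
        raise ValueError("resolution must be >= 100 score bins")
    cache = getattr(motif, "_dist_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(motif, "_dist_cache", cache)
    if resolution in cache:
        return cache[resolution]
    lod = motif.log_odds()
    bg = motif.background
    scores = np.zeros(1)
    probs = np.ones(1)
    span = float(np.ptp(lod, axis=0).mean()) or 1.0
    quantum = span / resolution
    for j in range(motif.width):
        cand = np.round(scores[:, None] + lod[None, :, j], _ROUND).ravel()
        p = (probs[:, None] * bg[None, :]).ravel()
        scores, inv = np.unique(cand, return_inverse=True)
        probs = np.bincount(inv, weights=p)
        if len(scores) > _EXACT_ATOM_CAP:
            binned = np.round(np.round(scores / quantum) * quantum, _ROUND)
            scores, inv = np.unique(binned, return_inverse=True)
            probs = np.bincount(inv, weights=probs)
    survival = probs[::-1].cumsum()[::-1]
    cache[resolution] = (scores, survival)
    return cache[resolution]


def score_pvalue(motif: MotifModel, score: float, resolution: int = 1000) -> float:
    """P(background word score >= score).  1.0 at or below the minimum score."""
    scores, survival = score_distribution(motif, resolution)
    return _lookup_pvalue(scores, survival, score)


def _lookup_pvalue(scores: np.ndarray, survival: np.ndarray, score: float) -> float:
    i = int(np.searchsorted(scores, score - 1e-9, side="left"))
    if i >= len(scores):
        return 0.0
    return float(survival[i])


# -- scanning -----------------------------------------------------------------


def _window_scores(codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Scores of every window; NaN where the window contains a non-ACGT letter."""
    w = lod.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (win >= 0).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        idx = win[valid].astype(np.int64)
        scores[valid] = lod[idx, np.arange(w)].sum(axis=1)
    return scores


def scan_window(
    motif: MotifModel,
    seq: str,
    p_threshold: float = 1e-4,
    chrom: str = ".",
    offset: int = 0,
    resolution: int = 1000,
) -> list[MotifHit]:
    """Scan one sequence (both strands) for motif hits with p <= p_threshold."""
    w = motif.width
    if len(seq) < w:
        return []
    codes = _encode(seq.upper())
    scores_dist, survival = score_distribution(motif, resolution)
    lod = motif.log_odds()
    lod_rc = lod[::-1, ::-1]
    hits: list[MotifHit] = []
    for strand, m in (("+", lod), ("-", lod_rc)):
        sc = _window_scores(codes, m)
        for i in np.flatnonzero(np.isfinite(sc)):
            p = _lookup_pvalue(scores_dist, survival, sc[i])
            if p <= p_threshold:
                start = offset + int(i)
                iv = GenomicInterval(chrom, start, start + w, strand)
                if motif.anchor is None:
                    anchor_pos = start
                elif strand == "+":
                    anchor_pos = start + motif.anchor
                else:
                    anchor_pos = start + w - 1 - motif.anchor
                hits.append(MotifHit(iv, strand, float(sc[i]), p, anchor_pos))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan(
    motif: MotifModel,
    genome: GenomeSequence,
    p_threshold: float = 1e-4,
    region: GenomicInterval | None = None,
    resolution: int = 1000,
) -> list[MotifHit]:
    """Scan a genome (or one region of it) on both strands."""
    if region is not None:
        seq = genome[region.chrom][region.start : region.end]
        return scan_window(
            motif, seq, p_threshold, chrom=region.chrom, offset=region.start,
            resolution=resolution,
        )
    hits: list[MotifHit] = []
    for chrom in genome:
        hits.extend(
            scan_window(motif, genome[chrom], p_threshold, chrom=chrom, resolution=resolution)
        )
    return hits


# -- ZOOPS EM -----------------------------------------------------------------


@dataclass
class EMResult:
    model: MotifModel
    gamma: float  # occurrence probability per window
    loglik_trace: list[float]
    responsibilities: list[np.ndarray]  # per window, per start position
    n_iter: int

    @property
    def information_content(self) -> float:
        return self.model.information_content()

    def map_sites(self, min_responsibility: float = 0.5) -> list[int | None]:
        """Max-responsibility start per window, None where absence wins."""
        out: list[int | None] = []
        for z in self.responsibilities:
            if z.sum() < min_responsibility:
                out.append(None)
            else:
                out.append(int(z.argmax()))
        return out


def refine_motif_em(
    seqs: Sequence[str],
    init: MotifModel,
    max_iter: int = 200,
    tol: float = 1e-4,
    gamma0: float = 0.5,
    min_pseudocount: float = 1e-3,
) -> EMResult:
    """Zero-or-one-occurrence-per-sequence (ZOOPS) EM refinement of a motif.

    Each window either contains one motif occurrence (at a uniform prior over
    start positions) or is pure background.  The observed-data log-likelihood is
    guaranteed non-decreasing and asserted so each iteration.
    """
    w = init.width
    if any(len(s) < w for s in seqs):
        raise ValueError(f"all windows must be at least motif width {w}")
    bg = init.background
    pc = max(init.pseudocount, min_pseudocount)
    coded = [_encode(s.upper()) for s in seqs]
    theta = init.matrix.copy()
    gamma = gamma0
    ll_trace: list[float] = []
    resp: list[np.ndarray] = []
    last_theta = theta
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        model = MotifModel(init.name, theta, bg, pseudocount=pc, anchor=init.anchor)
        lod = model.log_odds()
        resp = []
        ll = 0.0
        counts = np.zeros((4, w))
        occ_sum = 0.0
        for codes in coded:
            sc = _window_scores(codes, lod)
            m = len(sc)
            odds = np.where(np.isfinite(sc), np.exp2(np.clip(sc, -700, 700)), 0.0)
            prior = gamma / m if m else 0.0
            denom = (1.0 - gamma) + prior * odds.sum()
            z = prior * odds / denom
            resp.append(z)
            ll += math.log(max(denom, 1e-300))
            occ_sum += z.sum()
            for j in np.flatnonzero(z > 1e-12):
                word = codes[j : j + w]
                ok = word >= 0
                counts[word[ok], np.flatnonzero(ok)] += z[j]
        ll_trace.append(ll)
        if len(ll_trace) > 1:
            assert ll >= ll_trace[-2] - 1e-8 * max(1.0, abs(ll)), "EM log-likelihood decreased"
        new_theta = counts + pc * bg[:, None]
        new_theta /= new_theta.sum(axis=0, keepdims=True)
        gamma = min(max(occ_sum / len(seqs), 1e-6), 1 - 1e-6)
        delta = float(np.abs(new_theta - theta).max())
        last_theta, theta = theta, new_theta
        if delta < tol:
            break
    final = MotifModel(init.name, theta, bg, pseudocount=pc, anchor=init.anchor)
    return EMResult(final, gamma, ll_trace, resp, n_iter)


# -- B2 anchoring -------------------------------------------------------------


def assign_b2(
    origin_id: str,
    a_anchor: int,
    a_strand: str,
    chrom: str,
    genome: GenomeSequence,
    b2: MotifModel,
    window: int = 150,
    p_threshold: float = 1e-4,
    resolution: int = 1000,
) -> B2Assignment | None:
    """Scan the 150 bp anchor-to-anchor window downstream of the A-element.

    "Downstream" follows origin-local orientation (the A-element strand).  A hit
    is orientation-"correct" when it lies on the strand opposite to the
    A-element, the geometry required for head-to-head MCM2-7 double-hexamer
    formation.  Hits are ordered by anchor distance.
    """
    if a_strand not in ("+", "-"):
        return None
    w = b2.width
    L = genome.chrom_length(chrom)
    if a_strand == "+":
        lo, hi = a_anchor, min(L, a_anchor + window + w)
    else:
        lo, hi = max(0, a_anchor - window - w), a_anchor + 1
    if hi - lo < w:
        return B2Assignment(origin_id, [], [], [])
    region = GenomicInterval(chrom, lo, hi)
    hits = scan(b2, genome, p_threshold, region=region, resolution=resolution)
    kept: list[tuple[int, MotifHit]] = []
    for h in hits:
        dist = h.anchor_pos - a_anchor if a_strand == "+" else a_anchor - h.anchor_pos
        if 1 <= dist <= window:
            kept.append((dist, h))
    kept.sort(key=lambda t: t[0])
    ordered = [h for _, h in kept]
    dists = [d for d, _ in kept]
    orients = ["correct" if h.strand != a_strand else "incorrect" for h in ordered]
    return B2Assignment(origin_id, ordered, orients, dists)


# -- MEME minimal format ------------------------------------------------------


def read_meme_motif(path: str | Path, name: str | None = None) -> MotifModel:
    """Read one motif from MEME minimal motif text format.

    An optional ``# ANCHOR <col>`` comment line sets the anchor column; otherwise
    the anchor defaults to the most A-informative column for names containing
    "ACS"/"A-element" and the most T-informative column for names containing
    "B2", else None.
    """
    lines = Path(path).read_text().splitlines()
    bg = np.full(4, 0.25)
    anchor: int | None = None
    motifs: dict[str, tuple[np.ndarray, int | None]] = {}
    i = 0
    current: str | None = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("# ANCHOR"):
            anchor = int(line.split()[-1])
        elif line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[k]: float(parts[k + 1]) for k in range(0, len(parts), 2)}
            bg = np.array([freq.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            current = line.split()[1]
            anchor = None
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w\s*=\s*(\d+)", line)
            if not m:
                raise ValueError(f"{path}: missing w= in matrix header")
            w = int(m.group(1))
            rows = []
            for k in range(1, w + 1):
                rows.append([float(x) for x in lines[i + k].split()])
            i += w
            mat = np.array(rows).T  # file rows are positions; we store 4 x w
            motifs[current or "motif"] = (mat, anchor)
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no motif found")
    key = name if name is not None else next(iter(motifs))
    if key not in motifs:
        raise KeyError(f"motif {key!r} not in {path} (has {list(motifs)})")
    mat, anchor = motifs[key]
    mat = mat / mat.sum(axis=0, keepdims=True)
    model = MotifModel(key, mat, bg, anchor=anchor)
    if model.anchor is None:
        up = key.upper()
        if "B2" in up:
            model.anchor = model.default_anchor("T")
        elif "ACS" in up or "A-ELEMENT" in up or up.startswith("A_"):
            model.anchor = model.default_anchor("A")
    return model


def write_meme_motif(motif: MotifModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.4f}" for b, f in zip(BASES, motif.background)) + "\n\n")
        fh.write(f"MOTIF {motif.name}\n")
        if motif.anchor is not None:
            fh.write(f"# ANCHOR {motif.anchor}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {motif.width} nsites= 100 E= 0\n"
        )
        for j in range(motif.width):
            fh.write(" ".join(f"{motif.matrix[b, j]:.6f}" for b in range(4)) + "\n")


def packaged_motif(which: str) -> MotifModel:
    """Load one of the shipped motif models ("ACS" or "B2")."""
    data = Path(__file__).parent / "data"
    fname = {"ACS": "acs_motif.txt", "B2": "b2_motif.txt"}[which]
    return read_meme_motif(data / fname)
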