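"""Synthetic genomes, origin truth, and ChIP-Exo tag tracks.

The generator plants the origin architecture the analysis assumes — an A-element
(ACS) sampled from a PWM, optional B2-elements at a configurable A-to-B2 spacing
distribution (inverted relative to the A-element when orientation-correct), an
AT-skewed inter-element stretch, phase-specific ORC footprints, an MCM2-7
double-hexamer (DH) footprint, multi-DH origins, and G1-only non-origin ORC
sites upstream of gene TSSs — and emits stranded exonuclease-boundary tag
pileups around each protected footprint.

Default parameters are the study conditions of the genome-wide yeast origin
survey this package models: ORC footprints of 53 bp (G2/S) and 79 bp (G1), a
64 bp DH footprint, an A-B2 spacing mixture peaked at 66 bp with 12 bp-comb
side modes, B2 presence/orientation/multiplicity rates of 0.727/0.808/0.370,
a 93 % DH-in-ORC overlap rate and single/dominant/multi peak-class rates of
0.415/0.255/0.33.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GenomeSequence, TagTrack, revcomp
from .motif import MotifModel, packaged_motif

__all__ = [
    "GeneratorConfig",
    "OriginTruth",
    "NonOriginTruth",
    "GeneTruth",
    "TruthManifest",
    "generate_genome",
    "generate_tags",
    "generate_shape_table",
    "generate_deformation_model",
    "write_genes_gff",
]

BASES = "ACGT"

PHASES = ("G1", "G2", "S")

# Orc2 occupancy change G2 -> G1 per descending-occupancy quartile: -48 %, -17 %,
# +62 %, +231 %; MCM2-7 relative loading C1:C2:C3/C4 = 1 : 0.67 : 0.54.
_ORC_G1_FACTOR = (0.52, 0.83, 1.62, 3.31)
_MCM_FACTOR = (1.0, 0.67, 0.543, 0.543)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic origin world."""

    n_origins: int = 200
    n_chroms: int = 2
    origin_spacing: int = 4000  # bp between successive A-elements
    margin: int = 2000  # chromosome end padding
    background_at: float = 0.62  # genomic AT fraction
    # B2 architecture
    b2_prob: float = 0.727  # origins with any B2 within the search window
    orientation_correct_prob: float = 0.808
    multi_b2_prob: float = 0.370  # of B2-containing origins
    inter_b2_interval: int = 12  # bp between sequential B2 matches
    max_extra_b2: int = 3
    spacing_distribution: dict[int, float] = field(
        default_factory=lambda: {42: 0.10, 54: 0.20, 66: 0.40, 78: 0.20, 90: 0.10}
    )
    at_skew: float = 0.3  # (nA - nT)/(nA + nT) on the A-element strand between elements
    # footprints (bp)
    orc_widths: dict[str, int] = field(
        default_factory=lambda: {"G1": 79, "G2": 53, "S": 53}
    )
    mcm_width: int = 64
    orc_centre_offset: dict[str, int] = field(
        default_factory=lambda: {"G1": 20, "G2": 10, "S": 10}
    )
    dh_centre_jitter: float = 6.0  # sd of DH placement around the 51 bp rule
    dh_overlap_prob: float = 0.93  # DH centre inside the G1 ORC footprint
    # peak classes
    peak_class_probs: dict[str, float] = field(
        default_factory=lambda: {"single": 0.415, "dominant": 0.255, "multi": 0.33}
    )
    secondary_dh_offset: int = 120  # bp downstream of the primary DH
    dominant_secondary_weight: float = 0.3
    # occupancy
    occupancy_sigma: float = 0.5  # lognormal sd of per-origin base weights
    # non-origin ORC sites and genes
    n_nonorigin: int = 40
    n_genes: int = 80
    nonorigin_tss_sd: float = 180.0  # upstream-distance spread
    nonorigin_weight: float = 0.5  # relative to mean origin weight
    # tags
    noise_fraction: float = 0.1
    jitter_sigma: float = 2.0  # boundary jitter sd, bp
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for name in ("b2_prob", "orientation_correct_prob", "multi_b2_prob",
                     "noise_fraction", "dh_overlap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0,1], got {v}")
        if self.mcm_width <= 0 or any(w <= 0 for w in self.orc_widths.values()):
            problems.append("footprint widths must be > 0")
        if abs(sum(self.spacing_distribution.values()) - 1.0) > 1e-6:
            problems.append("spacing_distribution must sum to 1")
        if abs(sum(self.peak_class_probs.values()) - 1.0) > 1e-3:
            problems.append("peak_class_probs must sum to 1")
        return problems


@dataclass
class OriginTruth:
    """Planted architecture of one origin (all positions genomic, 0-based)."""

    origin_id: str
    chrom: str
    a_anchor: int
    a_strand: str
    b2_anchors: list[tuple[int, str, str]]  # (anchor pos, strand, "correct"/"incorrect")
    dh_centre: int
    dh_width: int
    extra_dh: list[tuple[int, float]]  # (centre, weight relative to primary)
    orc_footprints: dict[str, tuple[int, int]]  # phase -> (centre, width)
    weight: float  # base occupancy weight
    orc_phase_weight: dict[str, float]
    mcm_weight: float
    peak_class: str
    dh_in_orc: bool

    def local(self, genomic: int) -> int:
        """Origin-local (downstream-positive) coordinate of a genomic position."""
        return genomic - self.a_anchor if self.a_strand == "+" else self.a_anchor - genomic

    def footprint_edges(self, centre: int, width: int) -> tuple[int, int]:
        """Genomic [left, right] inclusive boundary positions of a footprint."""
        return centre - width // 2, centre + width - 1 - width // 2


@dataclass
class NonOriginTruth:
    site_id: str
    chrom: str
    centre: int
    width: int
    gene_id: str
    tss_distance: int  # signed, upstream negative, gene-local orientation
    phase_weight: dict[str, float]


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class TruthManifest:
    chrom_lengths: dict[str, int]
    origins: list[OriginTruth]
    nonorigin: list[NonOriginTruth]
    genes: list[GeneTruth]
    config: GeneratorConfig

    def origins_frame(self) -> pd.DataFrame:
        rows = []
        for o in self.origins:
            rows.append(
                dict(
                    origin_id=o.origin_id, chrom=o.chrom, a_anchor=o.a_anchor,
                    a_strand=o.a_strand,
                    n_b2=len(o.b2_anchors),
                    b2_anchors=";".join(f"{p}{s}{f[0]}" for p, s, f in o.b2_anchors),
                    dh_centre=o.dh_centre, dh_width=o.dh_width,
                    peak_class=o.peak_class, dh_in_orc=o.dh_in_orc,
                    weight=o.weight, mcm_weight=o.mcm_weight,
                    **{f"orc_{ph}": o.orc_phase_weight[ph] for ph in PHASES},
                )
            )
        return pd.DataFrame(rows)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.origins_frame().to_csv(path / "origin_truth.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(s) for s in self.nonorigin]).to_csv(
            path / "nonorigin_truth.tsv", sep="\t", index=False
        )
        pd.DataFrame([asdict(g) for g in self.genes]).to_csv(
            path / "gene_truth.tsv", sep="\t", index=False
        )
        cfg = asdict(self.config)
        cfg["chrom_lengths"] = dict(self.chrom_lengths)
        with open(path / "generator_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


def _random_background(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=n, p=p)


def _plant(seq: np.ndarray, start: int, word: str) -> None:
    for k, b in enumerate(word):
        if 0 <= start + k < len(seq):
            seq[start + k] = BASES.index(b)


def generate_genome(
    cfg: GeneratorConfig,
    acs: MotifModel | None = None,
    b2: MotifModel | None = None,
) -> tuple[GenomeSequence, TruthManifest]:
    """Generate a genome with planted origin architecture and its truth manifest."""
    problems = cfg.validate()
    if problems:
        raise ValueError("; ".join(problems))
    acs = acs or packaged_motif("ACS")
    b2 = b2 or packaged_motif("B2")
    rng = np.random.default_rng(cfg.seed)

    per_chrom = [cfg.n_origins // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_origins % cfg.n_chroms):
        per_chrom[i] += 1
    chrom_lengths = {
        f"chr{c + 1}": 2 * cfg.margin + max(n, 1) * cfg.origin_spacing
        for c, n in enumerate(per_chrom)
    }
    for chrom, n in zip(chrom_lengths, per_chrom):
        if n and chrom_lengths[chrom] < 2 * cfg.margin + n * 500:
            raise ValueError("genome too small for requested origins")

    seqs: dict[str, np.ndarray] = {
        c: _random_background(rng, L, cfg.background_at) for c, L in chrom_lengths.items()
    }

    spacing_vals = np.array(sorted(cfg.spacing_distribution))
    spacing_p = np.array([cfg.spacing_distribution[v] for v in spacing_vals])
    class_names = list(cfg.peak_class_probs)
    class_p = np.array([cfg.peak_class_probs[k] for k in class_names])

    origins: list[OriginTruth] = []
    oid = 0
    for ci, (chrom, n) in enumerate(zip(chrom_lengths, per_chrom)):
        seq = seqs[chrom]
        for k in range(n):
            a = cfg.margin + k * cfg.origin_spacing + int(
                rng.integers(-cfg.origin_spacing // 8, cfg.origin_spacing // 8 + 1)
            )
            s = "+" if rng.random() < 0.5 else "-"
            sign = 1 if s == "+" else -1

            def g(u: int) -> int:  # local -> genomic
                return a + sign * u

            # B2 architecture
            b2_anchors: list[tuple[int, str, str]] = []
            d_first: int | None = None
            if rng.random() < cfg.b2_prob:
                d_first = int(rng.choice(spacing_vals, p=spacing_p))
                correct = rng.random() < cfg.orientation_correct_prob
                flag = "correct" if correct else "incorrect"
                t = ("-" if s == "+" else "+") if correct else s
                ds = [d_first]
                if rng.random() < cfg.multi_b2_prob:
                    for j in range(1, int(rng.integers(1, cfg.max_extra_b2 + 1)) + 1):
                        ds.append(d_first + j * cfg.inter_b2_interval)
                for d in ds:
                    b2_anchors.append((g(d), t, flag))

            # AT-skew between the A-element and the far end of the B2 stretch
            span_end = (d_first or 66) + 20
            at = cfg.background_at
            p_skew = np.array(
                [at / 2 * (1 + cfg.at_skew), (1 - at) / 2, (1 - at) / 2,
                 at / 2 * (1 - cfg.at_skew)]
            )
            p_skew /= p_skew.sum()
            for u in range(5, span_end):
                pos = g(u)
                if 0 <= pos < len(seq):
                    code = rng.choice(4, p=p_skew)
                    seq[pos] = code if s == "+" else 3 - code

            # plant the A-element
            word = acs.sample(rng)
            if s == "+":
                _plant(seq, a - acs.anchor, word)
            else:
                _plant(seq, a - (acs.width - 1 - acs.anchor), revcomp(word))
            # plant B2 words
            for p, t, _flag in b2_anchors:
                wd = b2.sample(rng)
                if t == "+":
                    _plant(seq, p - b2.anchor, wd)
                else:
                    _plant(seq, p - (b2.width - 1 - b2.anchor), revcomp(wd))

            # footprints (origin-local geometry, mapped to genomic coordinates)
            orc_fp = {
                ph: (g(cfg.orc_centre_offset[ph]), cfg.orc_widths[ph]) for ph in PHASES
            }
            dh_u = (d_first - 51) if d_first is not None else 15
            dh_u += int(round(rng.normal(0, cfg.dh_centre_jitter)))
            in_orc = rng.random() < cfg.dh_overlap_prob
            if not in_orc:
                dh_u += 80 if rng.random() < 0.5 else -80
            dh_centre = g(dh_u)

            pclass = class_names[int(rng.choice(len(class_names), p=class_p))]
            extra: list[tuple[int, float]] = []
            if pclass == "dominant":
                extra.append((g(dh_u + cfg.secondary_dh_offset),
                              cfg.dominant_secondary_weight))
            elif pclass == "multi":
                extra.append((g(dh_u + cfg.secondary_dh_offset),
                              float(rng.uniform(0.8, 1.0))))

            base = float(rng.lognormal(0.0, cfg.occupancy_sigma))
            origins.append(
                OriginTruth(
                    origin_id=f"ori{oid:04d}", chrom=chrom, a_anchor=a, a_strand=s,
                    b2_anchors=b2_anchors, dh_centre=dh_centre, dh_width=cfg.mcm_width,
                    extra_dh=extra, orc_footprints=orc_fp, weight=base,
                    orc_phase_weight={}, mcm_weight=0.0, peak_class=pclass,
                    dh_in_orc=in_orc,
                )
            )
            oid += 1

    # phase-specific occupancy weights: quartile-dependent redistribution
    order = sorted(range(len(origins)), key=lambda i: (-origins[i].weight, i))
    n = len(origins)
    for rank, i in enumerate(order):
        q = min(3, rank * 4 // max(n, 1))
        o = origins[i]
        o.orc_phase_weight = {
            "G2": o.weight,
            "G1": o.weight * _ORC_G1_FACTOR[q],
            "S": o.weight,
        }
        o.mcm_weight = o.weight * _MCM_FACTOR[q]

    # genes in inter-origin gaps, non-origin ORC sites upstream of a subset of TSSs
    genes: list[GeneTruth] = []
    nonorigin: list[NonOriginTruth] = []
    gid = 0
    gene_slots: list[tuple[str, int]] = []
    for chrom, n_ori in zip(chrom_lengths, per_chrom):
        for k in range(max(n_ori - 1, 0)):
            gap_mid = cfg.margin + k * cfg.origin_spacing + cfg.origin_spacing // 2
            gene_slots.append((chrom, gap_mid))
    rng.shuffle(gene_slots)
    mean_w = float(np.mean([o.weight for o in origins])) if origins else 1.0
    for j, (chrom, mid) in enumerate(gene_slots[: cfg.n_genes]):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(500, 1200))
        tss = mid + int(rng.integers(-200, 201))
        if strand == "+":
            g_start, g_end = tss, tss + length
        else:
            g_start, g_end = tss - length + 1, tss + 1
        genes.append(GeneTruth(f"gene{gid:04d}", chrom, g_start, g_end, strand))
        if j < cfg.n_nonorigin:
            up = int(min(abs(rng.normal(0, cfg.nonorigin_tss_sd)), 900))
            centre = tss - up if strand == "+" else tss + up
            nonorigin.append(
                NonOriginTruth(
                    site_id=f"nonori{j:03d}", chrom=chrom, centre=centre, width=53,
                    gene_id=f"gene{gid:04d}", tss_distance=-up,
                    phase_weight={"G1": cfg.nonorigin_weight * mean_w, "G2": 0.0, "S": 0.0},
                )
            )
        gid += 1

    genome = GenomeSequence(
        {c: "".join(BASES[i] for i in seq) for c, seq in seqs.items()}
    )
    manifest = TruthManifest(dict(chrom_lengths), origins, nonorigin, genes, cfg)
    return genome, manifest


def _site_list(
    truth: TruthManifest, protein: str, phase: str
) -> list[tuple[str, int, int, float]]:
    """(chrom, left, right, weight) protected footprints for one protein/phase."""
    sites = []
    for o in truth.origins:
        if protein == "ORC":
            centre, width = o.orc_footprints[phase]
            L, R = o.footprint_edges(centre, width)
            sites.append((o.chrom, L, R, o.orc_phase_weight[phase]))
        else:
            splits = [(o.dh_centre, 1.0)] + list(o.extra_dh)
            tot = sum(w for _, w in splits)
            for centre, w in splits:
                L, R = o.footprint_edges(centre, o.dh_width)
                sites.append((o.chrom, L, R, o.mcm_weight * w / tot))
    if protein == "ORC":
        for s in truth.nonorigin:
            w = s.phase_weight.get(phase, 0.0)
            if w > 0:
                L = s.centre - s.width // 2
                R = s.centre + s.width - 1 - s.width // 2
                sites.append((s.chrom, L, R, w))
    return sites


def generate_tags(
    truth: TruthManifest,
    protein: str,
    phase: str,
    depth: int,
    seed: int | None = None,
) -> TagTrack:
    """Simulate a stranded 5'-end tag track for one protein/phase.

    Per planted footprint [L, R], forward-strand 5' ends fall at
    round(Normal(L, sigma)) and reverse-strand ends at round(Normal(R, sigma));
    site totals are multinomial over occupancy weights, and a noise fraction of
    tags is uniform over the genome on random strands.  The output total equals
    ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if protein not in ("ORC", "MCM"):
        raise ValueError(f"unknown protein {protein!r}")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    cfg = truth.config
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(
        [int(seed) % (2**31), ("ORC", "MCM").index(protein), PHASES.index(phase)]
    )
    rng = np.random.default_rng(ss)

    sites = _site_list(truth, protein, phase)
    weights = np.array([w for _, _, _, w in sites], dtype=float)
    if not len(sites) or weights.sum() <= 0:
        raise ValueError(f"no footprints for {protein}/{phase}")
    n_noise = int(round(cfg.noise_fraction * depth))
    n_signal = depth - n_noise
    counts = rng.multinomial(n_signal, weights / weights.sum())

    track = TagTrack()
    sigma = cfg.jitter_sigma
    for (chrom, L, R, _w), c in zip(sites, counts):
        if c == 0:
            continue
        clen = truth.chrom_lengths[chrom]
        fwd = rng.random(c) < 0.5
        n_f = int(fwd.sum())
        if n_f:
            pos = np.clip(np.rint(rng.normal(L, sigma, n_f)).astype(int), 0, clen - 1)
            track.add_many(chrom, "+", pos)
        if c - n_f:
            pos = np.clip(np.rint(rng.normal(R, sigma, c - n_f)).astype(int), 0, clen - 1)
            track.add_many(chrom, "-", pos)
    # uniform background noise
    chroms = list(truth.chrom_lengths)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    if n_noise:
        which = rng.choice(len(chroms), size=n_noise, p=lengths / lengths.sum())
        for ci in range(len(chroms)):
            m = int((which == ci).sum())
            if not m:
                continue
            pos = rng.integers(0, int(lengths[ci]), size=m)
            strands = rng.random(m) < 0.5
            p_f = pos[strands]
            p_r = pos[~strands]
            if len(p_f):
                track.add_many(chroms[ci], "+", p_f)
            if len(p_r):
                track.add_many(chroms[ci], "-", p_r)
    assert track.total() == depth
    return track


# -- shape table --------------------------------------------------------------

_SHAPE_FEATURES = {
    # name: (mean, sd, reverse-complement symmetric?)
    "MGW": (5.0, 0.6, True),       # minor groove width, Angstrom
    "ProT": (-8.0, 3.0, True),     # propeller twist, degrees
    "EP": (-5.0, 1.0, True),       # electrostatic potential proxy, kT/e
    "Roll": (2.0, 3.0, False),     # step feature, degrees
    "HelT": (34.3, 1.5, False),    # step feature, degrees
}


def generate_shape_table(seed: int = 0) -> pd.DataFrame:
    """Seeded synthetic pentamer shape table (stand-in for a database-derived one).

    One row per pentamer; per-bp symmetric features (MGW, ProT, EP) are equal for
    reverse-complement pentamer pairs by construction.  Step features (Roll,
    HelT) describe the step between the centre bp and its successor.
    """
    rng = np.random.default_rng(seed)
    pentamers = ["".join(p) for p in itertools.product(BASES, repeat=5)]
    values: dict[str, dict[str, float]] = {p: {} for p in pentamers}
    for feat, (mean, sd, symmetric) in _SHAPE_FEATURES.items():
        for p in pentamers:
            rc = revcomp(p)
            if symmetric and rc < p:
                values[p][feat] = values[rc][feat]
            else:
                values[p][feat] = float(mean + sd * rng.standard_normal())
    df = pd.DataFrame.from_dict(values, orient="index")
    df.index.name = "pentamer"
    return df.sort_index()


# -- deformation model --------------------------------------------------------


def generate_deformation_model(seed: int = 0, d: int = 3, n_substates: int = 2):
    """Seeded synthetic two-substate deformation model over dinucleotide steps.

    A stand-in parameter set with the structure of the real model: per-step
    equilibrium coordinates, SPD stiffness matrices, substate offsets and
    nearest-neighbour substate couplings.  Values are in kcal/mol (energies),
    degrees/Angstrom (coordinates).
    """
    from .deform import DeformationModel

    rng = np.random.default_rng(seed)
    contexts = [a + b for a in BASES for b in BASES]
    x0, K, offset = {}, {}, {}
    for ctx in contexts:
        for s in range(n_substates):
            base = rng.normal([34.0, 2.0, 0.0][:d], 3.0)
            x0[(ctx, s)] = base
            A = rng.normal(0, 0.25, size=(d, d))
            K[(ctx, s)] = A @ A.T + 0.05 * np.eye(d)
            offset[(ctx, s)] = float(abs(rng.normal(0, 0.5))) if s else 0.0
    coupling = {}
    for ca in contexts:
        for cb in contexts:
            coupling[(ca, cb)] = rng.normal(0, 0.3, size=(n_substates, n_substates))
    return DeformationModel(contexts=contexts, n_substates=n_substates, dim=d,
                            x0=x0, stiffness=K, offset=offset, coupling=coupling)


def write_genes_gff(genes: Sequence[GeneTruth], path: str | Path) -> None:
    """Write gene truth as GFF3 (1-based inclusive on write)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
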