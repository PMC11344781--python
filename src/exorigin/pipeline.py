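"""End-to-end orchestration: synthetic demo or real inputs, one config, one report.

Stages run in dependency order (simulate -> footprint -> occupancy -> motif ->
architecture -> shape -> deform).  Every stage writes its tables under the run
directory and contributes headline statistics to the JSON report.  With a fixed
seed the whole run is deterministic: running the same config twice produces
byte-identical tables and reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import occupancy as occ_mod
from .footprint import (
    FootprintCall,
    call_site_footprint,
    classify_origin_peaks,
    composite_profile,
    estimate_footprint_width,
    localization_ratio,
    occupancy,
)
from .io import (
    GenomicInterval,
    TssSet,
    read_gff_tss,
    write_fasta,
    write_results,
    write_tags_bedgraph,
)
from .motif import assign_b2, packaged_motif, refine_motif_em
from .shape import aligned_median_profile, write_shape_table
from .simulate import (
    GeneratorConfig,
    generate_deformation_model,
    generate_genome,
    generate_shape_table,
    generate_tags,
    write_genes_gff,
)
from .deform import TargetConformation, baseline_random, compare_elements

log = logging.getLogger("exorigin")

_TRACKS = (("ORC", "G1"), ("ORC", "G2"), ("ORC", "S"), ("MCM", "G1"))

_KNOWN_KEYS = {
    "seed", "outdir", "generator", "depths", "stages", "params",
}
_KNOWN_STAGES = (
    "simulate", "footprint", "occupancy", "motif", "architecture", "shape", "deform",
)
_KNOWN_PARAMS = {
    "b2_window", "p_threshold", "refine_b2", "spectrum_range", "spectrum_permutations",
    "occupancy_window", "downstream_window", "origin_halfwidth", "shape_halfwidth",
    "deform_length", "baseline_n",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "exorigin_run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    depths: dict[str, int] = field(
        default_factory=lambda: {
            "ORC_G1": 150_000, "ORC_G2": 150_000, "ORC_S": 150_000, "MCM_G1": 150_000,
        }
    )
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _KNOWN_STAGES}
    )
    params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        problems = _validate_raw(raw)
        if problems:
            raise ValueError("; ".join(problems))
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "outdir" in raw:
            cfg.outdir = str(raw["outdir"])
        gen = dict(raw.get("generator") or {})
        gen.setdefault("seed", cfg.seed)
        cfg.generator = GeneratorConfig(**gen)
        cfg.depths.update(raw.get("depths") or {})
        cfg.stages.update(raw.get("stages") or {})
        cfg.params.update(raw.get("params") or {})
        return cfg


def validate_config(path: str | Path) -> list[str]:
    """Problems that make a config unrunnable; empty list iff runnable."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        raise IOError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        return [f"invalid YAML: {exc}"]
    return _validate_raw(raw)


def _validate_raw(raw: dict) -> list[str]:
    problems: list[str] = []
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    for key in raw:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown key {key!r}")
    gen = raw.get("generator") or {}
    valid_gen = set(GeneratorConfig.__dataclass_fields__)
    for key in gen:
        if key not in valid_gen:
            problems.append(f"unknown generator key {key!r}")
    try:
        gcfg = GeneratorConfig(**{k: v for k, v in gen.items() if k in valid_gen})
        problems.extend(gcfg.validate())
    except (TypeError, ValueError) as exc:
        problems.append(str(exc))
    for name, depth in (raw.get("depths") or {}).items():
        key = name.replace("_", " ").split()
        if name not in {f"{p}_{ph}" for p, ph in _TRACKS}:
            problems.append(f"unknown depths key {name!r}")
        elif not isinstance(depth, int) or depth <= 0:
            problems.append(f"depths.{name} must be a positive integer")
    for key, val in (raw.get("stages") or {}).items():
        if key not in _KNOWN_STAGES:
            problems.append(f"unknown stage {key!r}")
        elif not isinstance(val, bool):
            problems.append(f"stages.{key} must be boolean")
    for key in raw.get("params") or {}:
        if key not in _KNOWN_PARAMS:
            problems.append(f"unknown params key {key!r}")
    return problems


@dataclass
class RunReport:
    stages: dict[str, str] = field(default_factory=dict)  # name -> ok | failed | skipped
    stats: dict[str, Any] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {"stages": self.stages, "stats": self.stats, "outputs": self.outputs}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _round(x: float, nd: int = 4) -> float:
    return float(np.round(float(x), nd))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all enabled stages on the synthetic demo world."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    stats = report.stats

    enabled = config.stages
    failed = False

    # ---------------------------------------------------------------- simulate
    genome = manifest = None
    tracks: dict[tuple[str, str], Any] = {}
    if enabled.get("simulate", True):
        try:
            genome, manifest = generate_genome(config.generator)
            write_fasta(genome, out / "genome.fa")
            manifest.to_dir(out / "truth")
            write_genes_gff(manifest.genes, out / "genes.gff3")
            ori_rows = pd.DataFrame(
                dict(
                    chrom=o.chrom, start=o.a_anchor - 100, end=o.a_anchor + 101,
                    name=o.origin_id, score=0, strand=o.a_strand,
                )
                for o in manifest.origins
            )
            write_results(ori_rows, out / "origins.bed", format="bed")
            for protein, phase in _TRACKS:
                depth = int(config.depths.get(f"{protein}_{phase}", 150_000))
                tr = generate_tags(manifest, protein, phase, depth, seed=config.seed)
                tracks[(protein, phase)] = tr
                write_tags_bedgraph(
                    tr,
                    out / f"tags_{protein}_{phase}_fwd.bedgraph",
                    out / f"tags_{protein}_{phase}_rev.bedgraph",
                )
            stats["n_origins"] = len(manifest.origins)
            stats["n_nonorigin_planted"] = len(manifest.nonorigin)
            report.stages["simulate"] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.exception("simulate stage failed")
            report.stages["simulate"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["simulate"] = "skipped"

    if manifest is None:
        for s in _KNOWN_STAGES[1:]:
            report.stages[s] = report.stages.get(s, "skipped")
        report.to_json(out / "report.json")
        if failed:
            raise RuntimeError("simulate stage failed")
        return report

    anchors = [(o.chrom, o.a_anchor, o.a_strand) for o in manifest.origins]
    halfwidth = int(config.params.get("origin_halfwidth", 250))
    annotations = {
        o.origin_id: arch.OriginAnnotation(o.origin_id, o.chrom, o.a_anchor, o.a_strand)
        for o in manifest.origins
    }

    # --------------------------------------------------------------- footprint
    if enabled.get("footprint", True):
        try:
            comp_rows = []
            for protein, phase in _TRACKS:
                prof = composite_profile(tracks[(protein, phase)], anchors, halfwidth)
                width, left, right = estimate_footprint_width(prof)
                stats[f"footprint_width_{protein}_{phase}"] = int(width)
                for off, f, r in zip(prof.offsets, prof.forward, prof.reverse):
                    comp_rows.append(
                        dict(protein=protein, phase=phase, offset=int(off),
                             forward=int(f), reverse=int(r))
                    )
            write_results(pd.DataFrame(comp_rows), out / "composite_profiles.tsv")

            fp_rows = []
            for o in manifest.origins:
                # +/- 100 bp holds every planted footprint boundary while
                # excluding secondary DH peaks of multi-peak origins
                region = GenomicInterval(
                    o.chrom, max(0, o.a_anchor - 100), o.a_anchor + 101
                )
                for protein, phase in _TRACKS:
                    call = call_site_footprint(tracks[(protein, phase)], region)
                    ann = annotations[o.origin_id]
                    if protein == "MCM":
                        ann.dh_call = call
                    else:
                        ann.orc_calls[phase] = call
                    if isinstance(call, FootprintCall):
                        fp_rows.append(
                            dict(origin_id=o.origin_id, protein=protein, phase=phase,
                                 chrom=o.chrom, start=call.left, end=call.right + 1,
                                 width=call.width, centre=call.centre,
                                 n_tags=call.n_tags)
                        )
            write_results(pd.DataFrame(fp_rows), out / "footprints.tsv")

            mcm = tracks[("MCM", "G1")]
            locs = []
            for o in manifest.origins:
                ann = annotations[o.origin_id]
                centre = (
                    ann.dh_call.centre
                    if isinstance(ann.dh_call, FootprintCall)
                    else o.dh_centre
                )
                v = localization_ratio(mcm, o.chrom, centre)
                if np.isfinite(v):
                    locs.append(v)
            stats["mcm_localization_60_800_mean_pct"] = _round(100 * np.mean(locs), 2)

            classes = {"single": 0, "dominant": 0, "multi": 0, "no call": 0}
            for o in manifest.origins:
                region = GenomicInterval(
                    o.chrom, max(0, o.a_anchor - 300), o.a_anchor + 301
                )
                pc = classify_origin_peaks(mcm, region, footprint_width=o.dh_width)
                classes[pc.label] += 1
            n_called = sum(v for k, v in classes.items() if k != "no call")
            for k in ("single", "dominant", "multi"):
                stats[f"peak_class_frac_{k}"] = _round(
                    classes[k] / n_called if n_called else float("nan")
                )
            report.stages["footprint"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("footprint stage failed")
            report.stages["footprint"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["footprint"] = "skipped"

    # --------------------------------------------------------------- occupancy
    if enabled.get("occupancy", True):
        try:
            win = int(config.params.get("occupancy_window", 100))
            ids = [o.origin_id for o in manifest.origins]
            occ_by = {}
            for protein, phase in _TRACKS:
                tr = tracks[(protein, phase)]
                lib = tr.total()
                vals = []
                for o in manifest.origins:
                    ann = annotations[o.origin_id]
                    call = ann.dh_call if protein == "MCM" else ann.orc_calls.get(phase)
                    centre = (
                        call.centre if isinstance(call, FootprintCall)
                        else o.orc_footprints[phase][0] if protein == "ORC"
                        else o.dh_centre
                    )
                    vals.append(occupancy(tr, o.chrom, centre, window=win, library_size=lib))
                occ_by[(protein, phase)] = vals
            clusters = occ_mod.assign_quartile_clusters(occ_by[("ORC", "G2")], ids)
            quintiles = occ_mod.assign_quintiles(occ_by[("MCM", "G1")], ids)
            for o, c, m in zip(manifest.origins, clusters, quintiles):
                ann = annotations[o.origin_id]
                ann.cluster = c
                ann.quintile = m
                ann.mcm_occupancy = occ_by[("MCM", "G1")][ids.index(o.origin_id)]
                ann.orc_occupancy = {
                    ph: occ_by[("ORC", ph)][ids.index(o.origin_id)]
                    for ph in ("G1", "G2", "S")
                }
            changes = occ_mod.phase_change(
                occ_by[("ORC", "G2")], occ_by[("ORC", "G1")], clusters
            )
            for grp, pct in changes.items():
                stats[f"orc_g2_to_g1_pct_change_{grp}"] = _round(pct, 1)
            for grp in sorted(set(clusters)):
                idx = [i for i, c in enumerate(clusters) if c == grp]
                _, p = occ_mod.paired_signed_rank(
                    [occ_by[("ORC", "G2")][i] for i in idx],
                    [occ_by[("ORC", "G1")][i] for i in idx],
                )
                stats[f"orc_g2_vs_g1_signed_rank_p_{grp}"] = float(f"{p:.3e}")
            occ_table = pd.DataFrame(
                dict(
                    origin_id=ids,
                    cluster=clusters,
                    quintile=quintiles,
                    orc_g1=occ_by[("ORC", "G1")],
                    orc_g2=occ_by[("ORC", "G2")],
                    orc_s=occ_by[("ORC", "S")],
                    mcm_g1=occ_by[("MCM", "G1")],
                )
            )
            write_results(occ_table, out / "origin_occupancy.tsv")

            origin_ivs = [
                GenomicInterval(o.chrom, max(0, o.a_anchor - 200), o.a_anchor + 201)
                for o in manifest.origins
            ]
            sites = occ_mod.discover_nonorigin_sites(
                tracks[("ORC", "G1")], tracks[("ORC", "G2")], origin_ivs,
                manifest.chrom_lengths,
            )
            tss = read_gff_tss(out / "genes.gff3") if (out / "genes.gff3").exists() else TssSet(
                [(g.chrom, g.tss, g.strand, g.gene_id) for g in manifest.genes]
            )
            summary = occ_mod.annotate_tss_proximity(sites, tss, cutoffs=(380,))
            stats["nonorigin_n_sites"] = int(len(sites))
            widths = [s.footprint_width for s in sites if np.isfinite(s.footprint_width)]
            stats["nonorigin_median_footprint_bp"] = (
                _round(np.median(widths), 1) if widths else float("nan")
            )
            stats["nonorigin_frac_within_380bp_tss"] = _round(
                summary["frac_within_380bp"].iloc[0]
            )
            stats["nonorigin_frac_upstream_1kbp"] = _round(
                summary["frac_upstream_1kbp"].iloc[0]
            )
            site_rows = pd.DataFrame(
                dict(
                    chrom=s.interval.chrom, start=s.interval.start, end=s.interval.end,
                    name=f"site{i:03d}", score=0, strand=".",
                    centre=s.centre, occ_g1=_round(s.occupancy_g1),
                    occ_g2=_round(s.occupancy_g2),
                    footprint_width=s.footprint_width,
                    tss_distance=s.tss_distance, gene_id=s.gene_id,
                    promoter=s.promoter,
                )
                for i, s in enumerate(sites)
            )
            write_results(site_rows, out / "nonorigin_sites.tsv")
            if len(site_rows):
                write_results(site_rows, out / "nonorigin_sites.bed", format="bed")
            report.stages["occupancy"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("occupancy stage failed")
            report.stages["occupancy"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["occupancy"] = "skipped"

    # ------------------------------------------------------------------- motif
    if enabled.get("motif", True):
        try:
            b2_model = packaged_motif("B2")
            if config.params.get("refine_b2", False):
                windows = []
                for o in manifest.origins:
                    iv = GenomicInterval(
                        o.chrom, max(0, o.a_anchor - 20), o.a_anchor + 161,
                        o.a_strand,
                    )
                    windows.append(genome.fetch(iv))
                b2_model = refine_motif_em(windows, b2_model, max_iter=50).model
            window = int(config.params.get("b2_window", 150))
            p_thr = float(config.params.get("p_threshold", 1e-4))
            b2_rows = []
            for o in manifest.origins:
                asn = assign_b2(
                    o.origin_id, o.a_anchor, o.a_strand, o.chrom, genome, b2_model,
                    window=window, p_threshold=p_thr,
                )
                annotations[o.origin_id].b2 = asn
                for hit, orient, dist in zip(asn.hits, asn.orientations, asn.distances):
                    b2_rows.append(
                        dict(origin_id=o.origin_id, chrom=o.chrom,
                             start=hit.interval.start, end=hit.interval.end,
                             strand=hit.strand, anchor=hit.anchor_pos,
                             distance=dist, orientation=orient,
                             score=_round(hit.score, 3), pvalue=float(f"{hit.pvalue:.3e}"))
                    )
            write_results(pd.DataFrame(b2_rows), out / "b2_assignments.tsv")
            report.stages["motif"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("motif stage failed")
            report.stages["motif"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["motif"] = "skipped"

    ann_list = [annotations[o.origin_id] for o in manifest.origins]

    # ------------------------------------------------------------ architecture
    if enabled.get("architecture", True) and report.stages.get("motif") == "ok":
        try:
            tally, orient, intervals = arch.b2_multiplicity(
                [a.b2 for a in ann_list]
            )
            n_with = sum(v for k, v in tally.items() if k != "0")
            stats["b2_origins_with_motif"] = int(n_with)
            stats["b2_frac_correct_orientation"] = _round(
                orient["correct"] / max(orient["correct"] + orient["incorrect"], 1)
            )
            stats["b2_single_motif_origins"] = int(tally["1"])
            stats["b2_multi_motif_origins"] = int(tally["2-5"] + tally[">5"])
            if intervals:
                stats["b2_modal_inter_b2_bp"] = int(
                    pd.Series(intervals).mode().iloc[0]
                )

            dists = []
            for a in ann_list:
                if a.b2 is not None and a.b2.first_correct is not None:
                    dists.append(a.b2.first_correct[1])
            if dists:
                stats["a_b2_modal_distance_bp"] = int(pd.Series(dists).mode().iloc[0])

            frac, n_eval, n_excl = arch.dh_overlap_fraction(ann_list, phase="G1")
            stats["dh_centre_in_orc_g1_frac"] = _round(frac)

            down_frac, n_down = arch.downstream_window_fraction(
                ann_list, window=int(config.params.get("downstream_window", 66))
            )
            stats["b2_within_66bp_of_dh_edge_frac"] = _round(down_frac)

            centre_d, edge_d, med_c, med_e = arch.mcm_to_b2_distance(ann_list)
            stats["mcm_to_b2_median_centre_bp"] = _round(med_c, 1)
            stats["mcm_to_b2_median_edge_bp"] = _round(med_e, 1)

            rng_lo, rng_hi = config.params.get("spectrum_range", (41, 141))
            spec = arch.spacing_spectrum(
                dists,
                bp_range=(int(rng_lo), int(rng_hi)),
                n_permutations=int(config.params.get("spectrum_permutations", 1000)),
                seed=config.seed,
            )
            stats["spacing_period_bp"] = spec.period
            stats["spacing_period_pvalue"] = _round(spec.period_pvalue)
            spec_df = pd.DataFrame(
                dict(
                    distance=spec.distances, count=spec.counts,
                    smoothed=np.round(spec.smoothed, 4),
                    extremum=[
                        "peak" if d in spec.peaks else
                        "valley" if d in spec.valleys else ""
                        for d in spec.distances
                    ],
                )
            )
            write_results(spec_df, out / "spectrum.tsv")

            if spec.peaks:
                table, share = arch.peak_valley_enrichment(ann_list, spec)
                stats["mcm_abundance_share_at_peaks"] = _round(share)

            geo_rows = []
            for a in ann_list:
                fc = a.b2.first_correct if a.b2 is not None else None
                geo_rows.append(
                    dict(
                        origin_id=a.origin_id, chrom=a.chrom, a_anchor=a.a_anchor,
                        a_strand=a.a_strand, cluster=a.cluster, quintile=a.quintile,
                        n_b2=a.b2.multiplicity if a.b2 else 0,
                        first_correct_b2_distance=fc[1] if fc else np.nan,
                        dh_centre=(
                            a.dh_call.centre
                            if isinstance(a.dh_call, FootprintCall) else np.nan
                        ),
                        dh_width=(
                            a.dh_call.width
                            if isinstance(a.dh_call, FootprintCall) else np.nan
                        ),
                        mcm_occupancy=_round(a.mcm_occupancy)
                        if np.isfinite(a.mcm_occupancy) else np.nan,
                    )
                )
            write_results(pd.DataFrame(geo_rows), out / "origins.tsv")
            report.stages["architecture"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("architecture stage failed")
            report.stages["architecture"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["architecture"] = (
            "skipped"
            if not enabled.get("architecture", True)
            else "skipped: motif stage unavailable"
        )

    # ------------------------------------------------------------------- shape
    if enabled.get("shape", True):
        try:
            table = generate_shape_table(config.seed)
            write_shape_table(table, out / "shape_table.tsv")
            hw = int(config.params.get("shape_halfwidth", 30))
            windows = {"A": [], "B2": []}
            for o in manifest.origins:
                iv = GenomicInterval(
                    o.chrom, o.a_anchor - hw, o.a_anchor + hw + 1, o.a_strand
                )
                windows["A"].append(genome.fetch(iv))
                a = annotations[o.origin_id]
                if a.b2 is not None and a.b2.first_correct is not None:
                    hit, _ = a.b2.first_correct
                    iv = GenomicInterval(
                        o.chrom, hit.anchor_pos - hw, hit.anchor_pos + hw + 1,
                        hit.strand,
                    )
                    windows["B2"].append(genome.fetch(iv))
            prof_rows = []
            for element, seqs in windows.items():
                if len(seqs) < 3:
                    continue
                for feature in table.columns:
                    ap = aligned_median_profile(
                        seqs, table, feature, ci_boot=200, seed=config.seed
                    )
                    for off, med, lo, hi in zip(
                        ap.offsets, ap.median, ap.ci_low, ap.ci_high
                    ):
                        prof_rows.append(
                            dict(element=element, feature=feature, offset=int(off),
                                 median=_round(med), ci_low=_round(lo),
                                 ci_high=_round(hi), n=ap.n_sequences)
                        )
            write_results(pd.DataFrame(prof_rows), out / "shape_profiles.tsv")
            report.stages["shape"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("shape stage failed")
            report.stages["shape"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["shape"] = "skipped"

    # ------------------------------------------------------------------ deform
    if enabled.get("deform", True):
        try:
            model = generate_deformation_model(config.seed)
            L = int(config.params.get("deform_length", 41))
            rng = np.random.default_rng(config.seed)
            target = TargetConformation(
                step_coords=rng.normal([34.0, 2.0, 0.0], 2.0, size=(L - 1, 3)),
                source="synthetic",
            )
            model.to_json(out / "deformation_model.json")
            sets: dict[str, list[str]] = {"A_element": [], "B2_element": []}
            for o in manifest.origins:
                iv = GenomicInterval(
                    o.chrom, o.a_anchor - L // 2, o.a_anchor - L // 2 + L, o.a_strand
                )
                sets["A_element"].append(genome.fetch(iv))
                a = annotations[o.origin_id]
                if a.b2 is not None and a.b2.first_correct is not None:
                    hit, _ = a.b2.first_correct
                    iv = GenomicInterval(
                        o.chrom, hit.anchor_pos - L // 2,
                        hit.anchor_pos - L // 2 + L, hit.strand,
                    )
                    sets["B2_element"].append(genome.fetch(iv))
            gc = 1.0 - config.generator.background_at
            mean, sd, sem, _ = baseline_random(
                model, target, gc,
                n=int(config.params.get("baseline_n", 500)), seed=config.seed,
            )
            table = compare_elements(model, target, sets)
            stats["deformation_random_mean_kcal"] = _round(mean, 1)
            stats["deformation_random_sem_kcal"] = _round(sem, 2)
            for _, row in table.iterrows():
                stats[f"deformation_{row['set']}_mean_kcal"] = _round(row["mean"], 1)
                stats[f"deformation_{row['set']}_sem_kcal"] = _round(row["sem"], 2)
            table.to_csv(out / "energies.tsv", sep="\t", index=False)
            report.stages["deform"] = "ok"
        except Exception as exc:  # noqa: BLE001
            log.exception("deform stage failed")
            report.stages["deform"] = f"failed: {exc}"
            failed = True
    else:
        report.stages["deform"] = "skipped"

    report.outputs = {
        p.name: p.name for p in sorted(out.glob("*.tsv"))
    }
    report.to_json(out / "report.json")
    if failed:
        raise RuntimeError(
            "pipeline stage(s) failed: "
            + ", ".join(k for k, v in report.stages.items() if v.startswith("failed"))
        )
    return report
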