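"""Composite profiles, width estimation, per-site calls, peak classes, occupancy."""

from __future__ import annotations

import numpy as np
import pytest

from exorigin.footprint import (
    CompositeProfile,
    FootprintCall,
    NoCall,
    call_site_footprint,
    classify_origin_peaks,
    composite_profile,
    estimate_footprint_width,
    localization_ratio,
    occupancy,
)
from exorigin.io import GenomicInterval, TagTrack
from exorigin.simulate import GeneratorConfig, generate_genome, generate_tags


def _track(entries):
    tr = TagTrack()
    for chrom, strand, pos, count in entries:
        tr.add(chrom, strand, pos, count)
    return tr


class TestCompositeProfile:
    def test_empty_track_all_zero(self):
        prof = composite_profile(TagTrack(), [("c1", 100, "+")], 50)
        assert prof.forward.sum() == 0 and prof.reverse.sum() == 0
        assert prof.n_tags == 0 and prof.n_anchors == 1

    def test_single_tag_offset(self):
        tr = _track([("c1", "+", 105, 1)])
        prof = composite_profile(tr, [("c1", 100, "+")], 50)
        assert prof.forward[50 + 5] == 1
        assert prof.forward.sum() == 1

    def test_minus_anchor_flips_offsets_and_strands(self):
        # mirror-image tags around two anchors on opposite strands
        tr = _track([("c1", "+", 95, 2), ("c1", "-", 110, 3),
                     ("c2", "-", 205, 2), ("c2", "+", 190, 3)])
        prof_plus = composite_profile(tr, [("c1", 100, "+")], 50)
        prof_minus = composite_profile(tr, [("c2", 200, "-")], 50)
        assert np.array_equal(prof_plus.forward, prof_minus.forward)
        assert np.array_equal(prof_plus.reverse, prof_minus.reverse)

    def test_flip_symmetry_of_mirrored_dataset(self, rng):
        """Reverse-complement-mirroring the whole dataset leaves the profile fixed."""
        L = 1000
        tr = TagTrack()
        entries = []
        for _ in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(0, L))
            entries.append((strand, pos))
            tr.add("c1", strand, pos)
        mirrored = TagTrack()
        for strand, pos in entries:
            mirrored.add("c1", "-" if strand == "+" else "+", L - 1 - pos)
        anchors = [("c1", 300, "+"), ("c1", 700, "-")]
        m_anchors = [("c1", L - 1 - p, "-" if s == "+" else "+") for _, p, s in anchors]
        p1 = composite_profile(tr, anchors, 80)
        p2 = composite_profile(mirrored, m_anchors, 80)
        assert np.array_equal(p1.forward, p2.forward)
        assert np.array_equal(p1.reverse, p2.reverse)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            composite_profile(TagTrack(), [("c1", 1, "+")], 0)
        with pytest.raises(ValueError):
            composite_profile(TagTrack(), [], 10)


class TestWidthEstimation:
    def test_spike_construction_width_64(self):
        prof = CompositeProfile(
            50, np.zeros(101), np.zeros(101), n_anchors=1, n_tags=2
        )
        prof.forward[50 - 32] = 10
        prof.reverse[50 + 31] = 10
        width, left, right = estimate_footprint_width(prof)
        assert (width, left, right) == (64, -32, 31)

    def test_anti_oriented_signal_raises(self):
        prof = CompositeProfile(50, np.zeros(101), np.zeros(101), 1, 2)
        prof.forward[80] = 5
        prof.reverse[20] = 5
        with pytest.raises(ValueError, match="no protected region"):
            estimate_footprint_width(prof)

    @pytest.mark.parametrize("protein,phase,planted", [
        ("ORC", "G2", 53), ("ORC", "G1", 79), ("MCM", "G1", 64),
    ])
    def test_planted_width_recovery(self, small_world, protein, phase, planted):
        _, man = small_world
        tr = generate_tags(man, protein, phase, 50_000, seed=11)
        anchors = [(o.chrom, o.a_anchor, o.a_strand) for o in man.origins]
        width, _, _ = estimate_footprint_width(composite_profile(tr, anchors, 250))
        assert abs(width - planted) <= 2

    def test_subsampling_invariance(self, small_world, rng):
        """Width is stable under 50% uniform tag subsampling (+/- 2 bp)."""
        _, man = small_world
        tr = generate_tags(man, "MCM", "G1", 50_000, seed=13)
        anchors = [(o.chrom, o.a_anchor, o.a_strand) for o in man.origins]
        w_full, _, _ = estimate_footprint_width(composite_profile(tr, anchors, 250))
        sub = TagTrack()
        for chrom, strand in tr.keys():
            pos, cnt = tr.arrays(chrom, strand)
            kept = rng.binomial(cnt, 0.5)
            for p, k in zip(pos, kept):
                if k:
                    sub.add(chrom, strand, int(p), int(k))
        w_sub, _, _ = estimate_footprint_width(composite_profile(sub, anchors, 250))
        assert abs(w_sub - w_full) <= 2


class TestSiteCalls:
    def test_exact_boundaries_without_jitter(self):
        tr = _track([("c1", "+", 468, 30), ("c1", "-", 531, 30)])
        call = call_site_footprint(tr, GenomicInterval("c1", 400, 601))
        assert isinstance(call, FootprintCall)
        assert (call.left, call.right, call.width) == (468, 531, 64)
        assert call.centre == (468 + 531) // 2

    def test_one_stranded_region_is_no_call(self):
        tr = _track([("c1", "+", 500, 50)])
        call = call_site_footprint(tr, GenomicInterval("c1", 400, 601))
        assert isinstance(call, NoCall)

    def test_insufficient_tags_is_no_call(self):
        tr = _track([("c1", "+", 468, 3), ("c1", "-", 531, 3)])
        call = call_site_footprint(tr, GenomicInterval("c1", 400, 601))
        assert isinstance(call, NoCall)

    def test_median_centre_error_on_planted_sites(self, small_world, small_tracks):
        _, man = small_world
        tr = small_tracks[("MCM", "G1")]
        errors = []
        for o in man.origins:
            region = GenomicInterval(o.chrom, o.a_anchor - 100, o.a_anchor + 101)
            call = call_site_footprint(tr, region)
            if isinstance(call, FootprintCall):
                errors.append(abs(call.centre - o.dh_centre))
        assert len(errors) > 50
        assert np.median(errors) <= 2


class TestLocalization:
    def test_all_tags_inside_inner_window(self):
        tr = _track([("c1", "+", 498, 10), ("c1", "-", 502, 10)])
        assert localization_ratio(tr, "c1", 500) == 1.0

    def test_uniform_tags_approach_window_ratio(self, rng):
        tr = TagTrack()
        tr.add_many("c1", "+", rng.integers(0, 801, size=20_000))
        r = localization_ratio(tr, "c1", 400, inner=60, outer=800)
        assert abs(r - 60 / 800) < 0.01  # ~5 sigma binomial slack

    def test_empty_outer_window_is_nan(self):
        assert np.isnan(localization_ratio(TagTrack(), "c1", 500))

    def test_monotone_in_inner_width(self, rng):
        tr = TagTrack()
        tr.add_many("c1", "+", rng.integers(0, 801, size=5000))
        ratios = [localization_ratio(tr, "c1", 400, inner=i) for i in (300, 200, 100, 60, 20)]
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))


class TestPeakClasses:
    def _dh_track(self, sites, depth_per=400, seed=0):
        """sites: list of (centre, weight); 64 bp footprints, sigma 2."""
        rng = np.random.default_rng(seed)
        tr = TagTrack()
        total_w = sum(w for _, w in sites)
        for centre, w in sites:
            n = int(depth_per * w / total_w * len(sites))
            L, R = centre - 32, centre + 31
            for _ in range(n):
                if rng.random() < 0.5:
                    tr.add("c1", "+", int(round(rng.normal(L, 2))))
                else:
                    tr.add("c1", "-", int(round(rng.normal(R, 2))))
        return tr

    def test_single_planted_dh(self):
        tr = self._dh_track([(500, 1.0)])
        pc = classify_origin_peaks(tr, GenomicInterval("c1", 200, 801))
        assert pc.label == "single"
        assert len(pc.peak_positions) == 1
        assert abs(pc.peak_positions[0] - 500) <= 10

    def test_equal_pair_is_multi(self):
        tr = self._dh_track([(450, 1.0), (570, 1.0)])
        pc = classify_origin_peaks(tr, GenomicInterval("c1", 200, 801))
        assert pc.label == "multi"

    def test_seventy_thirty_pair_is_dominant(self):
        tr = self._dh_track([(450, 0.7), (570, 0.3)])
        pc = classify_origin_peaks(tr, GenomicInterval("c1", 200, 801))
        assert pc.label == "dominant"

    def test_empty_region_is_no_call(self):
        pc = classify_origin_peaks(TagTrack(), GenomicInterval("c1", 200, 801))
        assert pc.label == "no call"

    def test_planted_classes_recovered(self):
        cfg = GeneratorConfig(n_origins=60, n_chroms=1, seed=21)
        _, man = generate_genome(cfg)
        tr = generate_tags(man, "MCM", "G1", 120_000, seed=21)
        hits = total = 0
        for o in man.origins:
            region = GenomicInterval(o.chrom, o.a_anchor - 300, o.a_anchor + 301)
            pc = classify_origin_peaks(tr, region, footprint_width=o.dh_width)
            if pc.label == "no call":
                continue
            total += 1
            hits += pc.label == o.peak_class
        assert total >= 50
        assert hits / total >= 0.8


class TestOccupancy:
    def test_zero_tags(self):
        assert occupancy(TagTrack(), "c1", 500, library_size=1000) == 0.0

    def test_per_million_arithmetic(self):
        tr = _track([("c1", "+", 500, 50)])
        assert occupancy(tr, "c1", 500, window=100, library_size=1_000_000) == 50.0

    def test_depth_doubling_leaves_normalised_value_stable(self, small_world):
        _, man = small_world
        o = man.origins[0]
        v = []
        for depth in (40_000, 80_000):
            tr = generate_tags(man, "ORC", "G2", depth, seed=5)
            v.append(occupancy(tr, o.chrom, o.orc_footprints["G2"][0], library_size=depth))
        assert v[0] > 0
        assert abs(v[1] - v[0]) / v[0] < 0.35  # sampling error only
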