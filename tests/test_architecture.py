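"""Origin geometry: distances, overlap, multiplicity, periodicity, AT skew."""

from __future__ import annotations

import numpy as np
import pytest

from exorigin.architecture import (
    OriginAnnotation,
    at_skew,
    b2_multiplicity,
    dh_overlap_fraction,
    downstream_window_fraction,
    element_distance,
    mcm_to_b2_distance,
    peak_valley_enrichment,
    spacing_spectrum,
)
from exorigin.footprint import FootprintCall, NoCall
from exorigin.io import GenomicInterval
from exorigin.motif import B2Assignment, MotifHit


def _hit(anchor, strand="-", chrom="c1"):
    iv = GenomicInterval(chrom, max(0, anchor - 6), anchor + 7, strand)
    return MotifHit(iv, strand, 10.0, 1e-5, anchor)


def _ann(
    origin_id="o1",
    a_anchor=1000,
    a_strand="+",
    b2_dists=(66,),
    orientations=None,
    dh_centre=None,
    dh_width=64,
    orc_g1=None,
    mcm_occ=1.0,
    quintile="M1",
):
    orientations = orientations or ["correct"] * len(b2_dists)
    sign = 1 if a_strand == "+" else -1
    hits = [_hit(a_anchor + sign * d, strand="-" if a_strand == "+" else "+") for d in b2_dists]
    asn = B2Assignment("o1", hits, list(orientations), list(b2_dists))
    ann = OriginAnnotation(origin_id, "c1", a_anchor, a_strand, b2=asn,
                           mcm_occupancy=mcm_occ, quintile=quintile)
    if dh_centre is not None:
        # boundaries chosen so the call's derived centre equals dh_centre
        L = dh_centre - (dh_width - 1) // 2
        R = L + dh_width - 1
        ann.dh_call = FootprintCall(GenomicInterval("c1", L - 10, R + 11), L, R, 100)
    if orc_g1 is not None:
        L, R = orc_g1
        ann.orc_calls["G1"] = FootprintCall(GenomicInterval("c1", L - 10, R + 11), L, R, 100)
    return ann


class TestElementDistance:
    def test_plus_strand(self):
        assert element_distance(100, 166, "+") == 66

    def test_equal_anchors(self):
        assert element_distance(100, 100, "+") == 0

    def test_minus_strand_downstream_is_leftward(self):
        assert element_distance(100, 34, "-") == 66

    def test_upstream_is_negative(self):
        assert element_distance(100, 80, "+") == -20


class TestDhOverlap:
    def test_all_inside(self):
        anns = [_ann(dh_centre=1015, orc_g1=(981, 1059)) for _ in range(4)]
        frac, n_eval, n_excl = dh_overlap_fraction(anns)
        assert (frac, n_eval, n_excl) == (1.0, 4, 0)

    def test_hand_three_of_four(self):
        anns = [
            _ann(dh_centre=1015, orc_g1=(981, 1059)),
            _ann(dh_centre=1059, orc_g1=(981, 1059)),  # boundary inclusive
            _ann(dh_centre=1100, orc_g1=(981, 1059)),  # outside
            _ann(dh_centre=990, orc_g1=(981, 1059)),
        ]
        frac, n_eval, _ = dh_overlap_fraction(anns)
        assert frac == 0.75 and n_eval == 4

    def test_missing_calls_excluded_and_counted(self):
        anns = [_ann(dh_centre=1015, orc_g1=(981, 1059)), _ann(dh_centre=None)]
        anns[1].orc_calls["G1"] = NoCall("x")
        frac, n_eval, n_excl = dh_overlap_fraction(anns)
        assert (n_eval, n_excl) == (1, 1)

    def test_generator_planted_rate(self):
        from exorigin.simulate import GeneratorConfig, generate_genome

        cfg = GeneratorConfig(n_origins=300, dh_overlap_prob=0.9, seed=51,
                              dh_centre_jitter=0.0)
        _, man = generate_genome(cfg)
        anns = []
        for o in man.origins:
            centre, width = o.orc_footprints["G1"]
            L, R = o.footprint_edges(centre, width)
            anns.append(_ann(a_anchor=o.a_anchor, a_strand=o.a_strand,
                             dh_centre=o.dh_centre, orc_g1=(min(L, R), max(L, R))))
        frac, n_eval, _ = dh_overlap_fraction(anns)
        assert abs(frac - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n_eval)


class TestB2Multiplicity:
    def test_empty(self):
        tally, orient, intervals = b2_multiplicity([])
        assert tally == {"0": 0, "1": 0, "2-5": 0, ">5": 0}
        assert intervals == []

    def test_counting_fixture(self):
        assignments = [
            None,
            _ann(b2_dists=(66,)).b2,
            _ann(b2_dists=(66,)).b2,
            _ann(b2_dists=(54, 66, 78)).b2,
            _ann(b2_dists=(42, 54, 66)).b2,
        ]
        tally, orient, intervals = b2_multiplicity(assignments)
        assert tally == {"0": 1, "1": 2, "2-5": 2, ">5": 0}
        assert sorted(intervals) == [12, 12, 12, 12]

    def test_modal_inter_b2_interval(self):
        assignments = [_ann(b2_dists=(42, 54, 66, 78)).b2 for _ in range(10)]
        _, _, intervals = b2_multiplicity(assignments)
        assert set(intervals) == {12}


class TestDownstreamWindow:
    def test_one_bp_past_edge_counted(self):
        # DH centre 1000 width 64: downstream edge local 32; B2 at 33 counted
        ann = _ann(b2_dists=(33,), dh_centre=1000)
        frac, n = downstream_window_fraction([ann])
        assert (frac, n) == (1.0, 1)

    def test_window_boundary_exclusive(self):
        ann_in = _ann(b2_dists=(32 + 66,), dh_centre=1000)
        ann_out = _ann(b2_dists=(32 + 67,), dh_centre=1000)
        assert downstream_window_fraction([ann_in])[0] == 1.0
        assert downstream_window_fraction([ann_out])[0] == 0.0

    def test_incorrect_orientation_not_evaluated(self):
        ann = _ann(b2_dists=(40,), orientations=["incorrect"], dh_centre=1000)
        frac, n = downstream_window_fraction([ann])
        assert n == 0 and np.isnan(frac)


class TestMcmToB2:
    def test_printed_convention_51_19(self):
        # DH centre local 15, width 64, B2 at 66 -> centre 51, edge 51 - 32 = 19
        ann = _ann(b2_dists=(66,), dh_centre=1015)
        centre_d, edge_d, med_c, med_e = mcm_to_b2_distance([ann])
        assert centre_d == [51] and edge_d == [19]
        assert (med_c, med_e) == (51.0, 19.0)

    def test_centre_equals_anchor(self):
        ann = _ann(b2_dists=(66,), dh_centre=1066)
        centre_d, edge_d, _, _ = mcm_to_b2_distance([ann])
        assert centre_d == [0] and edge_d == [-32]

    def test_centre_minus_edge_is_half_width(self):
        rng = np.random.default_rng(6)
        anns = [
            _ann(b2_dists=(int(d),), dh_centre=1000 + int(rng.integers(-20, 20)))
            for d in rng.integers(40, 100, size=30)
        ]
        centre_d, edge_d, _, _ = mcm_to_b2_distance(anns)
        for c, e, ann in zip(centre_d, edge_d, anns):
            assert c - e == ann.dh_call.width // 2

    def test_minus_strand_symmetry(self):
        plus = _ann(a_strand="+", b2_dists=(66,), dh_centre=1015)
        minus = _ann(a_strand="-", b2_dists=(66,), dh_centre=985)
        assert mcm_to_b2_distance([plus])[0] == mcm_to_b2_distance([minus])[0]


class TestSpacingSpectrum:
    def test_comb_period_recovered(self):
        rng = np.random.default_rng(2)
        comb = [42, 54, 66, 78, 90]
        dists = list(rng.choice(comb, p=[0.1, 0.2, 0.4, 0.2, 0.1], size=500))
        spec = spacing_spectrum(dists, seed=2)
        assert spec.period == 12
        for c in comb:
            assert any(abs(p - c) <= 1 for p in spec.peaks)

    def test_uniform_distances_no_periodicity(self):
        rng = np.random.default_rng(3)
        dists = list(rng.integers(41, 142, size=500))
        spec = spacing_spectrum(dists, seed=3)
        assert spec.period is None
        assert spec.period_pvalue >= 0.05

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError):
            spacing_spectrum([66] * 10)

    def test_extrema_structure(self):
        rng = np.random.default_rng(4)
        dists = list(rng.choice([42, 54, 66, 78, 90], size=400))
        spec = spacing_spectrum(dists, seed=4)
        assert spec.peaks and spec.valleys
        # peaks and valleys interleave along the axis
        merged = sorted([(p, "p") for p in spec.peaks] + [(v, "v") for v in spec.valleys])
        kinds = "".join(k for _, k in merged)
        assert "pp" not in kinds and "vv" not in kinds


class TestPeakValleyEnrichment:
    def _spectrum(self):
        rng = np.random.default_rng(5)
        dists = list(rng.choice([42, 54, 66, 78, 90], size=400))
        return spacing_spectrum(dists, seed=5)

    def test_all_origins_at_peaks_share_one(self):
        spec = self._spectrum()
        anns = [_ann(b2_dists=(66,), dh_centre=1015, mcm_occ=2.0) for _ in range(10)]
        table, share = peak_valley_enrichment(anns, spec)
        assert share == 1.0

    def test_high_occupancy_at_peaks_increases_share(self):
        spec = self._spectrum()
        anns = [_ann(b2_dists=(66,), mcm_occ=2.0, quintile="M1") for _ in range(50)] + [
            _ann(b2_dists=(60,), mcm_occ=1.0, quintile="M5") for _ in range(50)
        ]
        table, share = peak_valley_enrichment(anns, spec)
        assert share == pytest.approx(2 / 3, abs=0.05)
        assert table["M1"]["peak"] == 50
        assert table["M5"]["valley"] == 50

    def test_labels_partition_origins(self):
        spec = self._spectrum()
        rng = np.random.default_rng(8)
        anns = [_ann(b2_dists=(int(d),)) for d in rng.integers(41, 141, size=60)]
        table, _ = peak_valley_enrichment(anns, spec)
        assert sum(sum(v.values()) for v in table.values()) == 60


class TestAtSkew:
    def test_poly_a_and_poly_t(self):
        assert np.allclose(at_skew("A" * 30, 5), 1.0)
        assert np.allclose(at_skew("T" * 30, 5), -1.0)

    def test_hand_twenty_mer(self):
        seq = "AATTGGCCAATTAAAATTTT"
        window = 5
        out = at_skew(seq, window)
        for i in range(len(seq)):
            lo, hi = max(0, i - 2), min(len(seq), i + 3)
            na = seq[lo:hi].count("A")
            nt = seq[lo:hi].count("T")
            if na + nt:
                assert out[i] == pytest.approx((na - nt) / (na + nt))
            else:
                assert np.isnan(out[i])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            at_skew("ACGT", 4)
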