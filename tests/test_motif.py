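"""PWM scoring, exact p-values vs enumeration, scanning symmetry, ZOOPS EM, B2 logic."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from exorigin.io import GenomeSequence, revcomp
from exorigin.motif import (
    MotifModel,
    assign_b2,
    log_odds_score,
    read_meme_motif,
    refine_motif_em,
    scan,
    scan_window,
    score_distribution,
    score_pvalue,
    write_meme_motif,
)

from conftest import random_motif

BASES = "ACGT"


def enumerate_pvalue(motif: MotifModel, score: float) -> float:
    """Independent oracle: exhaustive sum over all 4^w background words."""
    lod = motif.log_odds()
    p = 0.0
    for word in itertools.product(range(4), repeat=motif.width):
        s = sum(lod[b, j] for j, b in enumerate(word))
        if s >= score - 1e-9:
            p += float(np.prod([motif.background[b] for b in word]))
    return p


class TestScoring:
    def test_uniform_motif_scores_zero(self):
        m = MotifModel("u", np.full((4, 5), 0.25), pseudocount=0.0)
        assert log_odds_score(m, "ACGTA") == pytest.approx(0.0)

    def test_hand_arithmetic_w2(self):
        mat = np.array([[0.7, 0.1], [0.1, 0.1], [0.1, 0.1], [0.1, 0.7]])
        m = MotifModel("h", mat, pseudocount=0.0)
        expected = np.log2(0.7 / 0.25) + np.log2(0.1 / 0.25)
        assert log_odds_score(m, "AC") == pytest.approx(expected)

    def test_reverse_complement_score_symmetry(self, rng):
        for _ in range(20):
            m = random_motif(rng, 6)
            m.background = np.full(4, 0.25)
            word = "".join(rng.choice(list(BASES), size=6))
            assert log_odds_score(m, word) == pytest.approx(
                log_odds_score(m.reverse_complement(), revcomp(word)), abs=1e-9
            )

    def test_word_with_n_rejected(self):
        m = MotifModel("u", np.full((4, 3), 0.25))
        with pytest.raises(ValueError):
            log_odds_score(m, "ANA")


class TestScorePvalue:
    def test_unique_best_word_uniform_background(self, rng):
        mat = np.full((4, 3), 0.05)
        for j, b in enumerate((0, 2, 3)):
            mat[b, j] = 0.85
        m = MotifModel("t", mat / mat.sum(0), pseudocount=0.0)
        best = max(
            log_odds_score(m, "".join(w))
            for w in itertools.product(BASES, repeat=3)
        )
        assert score_pvalue(m, best) == pytest.approx(1 / 64)

    def test_minimal_score_has_p_one(self, rng):
        m = random_motif(rng, 4)
        scores, survival = score_distribution(m)
        assert survival[0] == pytest.approx(1.0)
        assert score_pvalue(m, scores[0] - 5.0) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_score(self, rng):
        m = random_motif(rng, 5)
        grid = np.linspace(-20, 20, 101)
        ps = [score_pvalue(m, s) for s in grid]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_dp_matches_enumeration(self, rng):
        """DP survival equals brute-force enumeration for every achievable score."""
        for _ in range(5):
            w = int(rng.integers(2, 7))
            m = random_motif(rng, w)
            scores, survival = score_distribution(m)
            probe = rng.choice(len(scores), size=min(25, len(scores)), replace=False)
            for i in probe:
                assert survival[i] == pytest.approx(
                    enumerate_pvalue(m, float(scores[i])), abs=1e-6
                )


class TestScan:
    def test_planted_consensus_found_once(self, rng):
        m = random_motif(rng, 8, alpha=0.1)
        word = m.consensus
        bg = "".join(rng.choice(list(BASES), size=400))
        seq = bg[:200] + word + bg[200:]
        thr = score_pvalue(m, log_odds_score(m, word))
        hits = scan_window(m, seq, p_threshold=thr)
        plus = [h for h in hits if h.strand == "+"]
        assert any(h.start == 200 for h in plus)

    def test_sequence_shorter_than_motif(self, rng):
        m = random_motif(rng, 8)
        assert scan_window(m, "ACGT") == []

    def test_reverse_complement_mirror(self, rng):
        m = random_motif(rng, 6)
        m.anchor = 2
        seq = "".join(rng.choice(list(BASES), size=300))
        fwd_hits = scan_window(m, seq, p_threshold=1e-2)
        rc_hits = scan_window(m, revcomp(seq), p_threshold=1e-2)
        L = len(seq)
        mirrored = sorted(
            (L - h.interval.end, "-" if h.strand == "+" else "+", round(h.score, 6))
            for h in rc_hits
        )
        original = sorted(
            (h.interval.start, h.strand, round(h.score, 6)) for h in fwd_hits
        )
        assert mirrored == original

    def test_anchor_position_strand_aware(self):
        m = MotifModel("a", np.full((4, 4), 0.25), anchor=1)
        hits = scan_window(m, "ACGTACGT", p_threshold=1.0)
        for h in hits:
            if h.strand == "+":
                assert h.anchor_pos == h.interval.start + 1
            else:
                assert h.anchor_pos == h.interval.start + 4 - 1 - 1


class TestEM:
    def _windows_with_planted(self, rng, motif, n, occurrence, length=60):
        windows, positions = [], []
        for _ in range(n):
            seq = list("".join(rng.choice(list(BASES), size=length)))
            if rng.random() < occurrence:
                j = int(rng.integers(0, length - motif.width + 1))
                word = motif.sample(rng)
                seq[j : j + motif.width] = word
                positions.append(j)
            else:
                positions.append(None)
            windows.append("".join(seq))
        return windows, positions

    def test_identical_word_fixed_point(self, rng):
        word = "ACGTACG"
        windows = ["TT" + word + "GG"] * 30
        mat = np.full((4, 7), 0.1)
        for j, b in enumerate(word):
            mat[BASES.index(b), j] = 0.7
        init = MotifModel("i", mat / mat.sum(0))
        res = refine_motif_em(windows, init, max_iter=50)
        assert res.model.consensus == word

    def test_planted_recovery_and_null_specificity(self, rng, b2_motif):
        windows, positions = self._windows_with_planted(rng, b2_motif, 150, 0.8)
        perturbed = MotifModel(
            "init",
            0.7 * b2_motif.matrix + 0.3 * np.full((4, b2_motif.width), 0.25),
            b2_motif.background,
        )
        res = refine_motif_em(windows, perturbed, max_iter=60, tol=1e-3)
        sites = res.map_sites()
        planted = [(s, p) for s, p in zip(sites, positions) if p is not None]
        correct = sum(s == p for s, p in planted)
        assert correct / len(planted) >= 0.9
        # log-likelihood trace is non-decreasing (EM guarantee)
        assert all(b >= a - 1e-6 for a, b in zip(res.loglik_trace, res.loglik_trace[1:]))
        null_windows = ["".join(rng.choice(list(BASES), size=60)) for _ in range(150)]
        res_null = refine_motif_em(null_windows, perturbed, max_iter=60, tol=1e-3)
        assert res_null.information_content < res.information_content

    def test_window_shorter_than_motif_rejected(self, b2_motif):
        with pytest.raises(ValueError):
            refine_motif_em(["ACGT"], b2_motif)


class TestAssignB2:
    def _genome_with(self, a_anchor, a_strand, b2_motif, placements, length=2000):
        """placements: list of (anchor_pos, strand) B2 consensus plantings."""
        rng = np.random.default_rng(42)
        seq = list("".join(rng.choice(list("AC"), size=length)))  # B2-hostile bg
        word = b2_motif.consensus
        for pos, strand in placements:
            if strand == "+":
                start = pos - b2_motif.anchor
                w = word
            else:
                start = pos - (b2_motif.width - 1 - b2_motif.anchor)
                w = revcomp(word)
            seq[start : start + len(w)] = w
        return GenomeSequence({"c1": "".join(seq)})

    def test_correct_orientation_at_66bp(self, b2_motif):
        g = self._genome_with(1000, "+", b2_motif, [(1066, "-")])
        asn = assign_b2("o1", 1000, "+", "c1", g, b2_motif)
        assert asn.multiplicity == 1
        assert asn.orientations == ["correct"]
        assert asn.distances == [66]

    def test_same_strand_is_incorrect(self, b2_motif):
        g = self._genome_with(1000, "+", b2_motif, [(1066, "+")])
        asn = assign_b2("o1", 1000, "+", "c1", g, b2_motif)
        assert asn.orientations == ["incorrect"]

    def test_minus_strand_origin_downstream_is_leftward(self, b2_motif):
        g = self._genome_with(1000, "-", b2_motif, [(934, "+")])
        asn = assign_b2("o1", 1000, "-", "c1", g, b2_motif)
        assert asn.distances == [66]
        assert asn.orientations == ["correct"]

    def test_out_of_window_hit_ignored(self, b2_motif):
        g = self._genome_with(1000, "+", b2_motif, [(1180, "-")])
        asn = assign_b2("o1", 1000, "+", "c1", g, b2_motif)
        assert asn.multiplicity == 0

    def test_missing_anchor_strand(self, b2_motif):
        g = self._genome_with(1000, "+", b2_motif, [])
        assert assign_b2("o1", 1000, ".", "c1", g, b2_motif) is None

    def test_orientation_fraction_matches_generator(self):
        from exorigin.simulate import GeneratorConfig, generate_genome
        from exorigin.motif import packaged_motif

        cfg = GeneratorConfig(n_origins=200, b2_prob=1.0,
                              orientation_correct_prob=0.8, multi_b2_prob=0.0, seed=17)
        genome, man = generate_genome(cfg)
        b2 = packaged_motif("B2")
        correct = incorrect = 0
        for o in man.origins:
            asn = assign_b2(o.origin_id, o.a_anchor, o.a_strand, o.chrom, genome, b2,
                            p_threshold=1e-3)
            if asn.multiplicity:
                if asn.orientations[0] == "correct":
                    correct += 1
                else:
                    incorrect += 1
        frac = correct / (correct + incorrect)
        # binomial 99% CI around 0.8 with n ~ 200
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / (correct + incorrect))


class TestMemeFormat:
    def test_round_trip(self, tmp_path, rng):
        m = random_motif(rng, 9)
        m.name = "TEST"
        m.anchor = 4
        write_meme_motif(m, tmp_path / "m.txt")
        back = read_meme_motif(tmp_path / "m.txt")
        assert back.name == "TEST"
        assert back.anchor == 4
        assert np.allclose(back.matrix, m.matrix, atol=1e-6)
        assert np.allclose(back.background, m.background, atol=1e-4)

    def test_packaged_anchors(self, acs_motif, b2_motif):
        # conserved central adenine of the ACS, conserved thymidine of B2
        assert acs_motif.matrix[0, acs_motif.anchor] > 0.9
        assert b2_motif.matrix[3, b2_motif.anchor] > 0.9
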