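"""PWM construction and both-strand scanning against exhaustive oracles."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsnpscan._seq import revcomp
from rsnpscan.formats import PFM
from rsnpscan.motif import (count_homotypic_sites, pfm_to_pwm, relative_score,
                            scan_snp, window_relative_scores)
from rsnpscan.scoring import hwf_of

from conftest import brute_force_scan, random_seq

BASES = "ACGT"


class TestPfmToPwm:
    def test_uniform_column_gives_zero_weights(self):
        pfm = PFM(matrix_id="U", tf_name="U",
                  counts=np.array([[5.0, 9], [5, 1], [5, 1], [5, 1]]))
        pwm = pfm_to_pwm(pfm)
        np.testing.assert_allclose(pwm.weights[:, 0], 0.0, atol=1e-12)

    def test_fully_uniform_matrix_cannot_be_scored(self):
        pfm = PFM(matrix_id="U2", tf_name="U2", counts=np.full((4, 2), 5.0))
        pwm = pfm_to_pwm(pfm)  # construction is fine, scoring is undefined
        with pytest.raises(ValueError, match="degenerate"):
            relative_score(pwm, "AC")

    def test_consensus_column_weight_matches_direct_arithmetic(self, toy_pfm):
        pwm = pfm_to_pwm(toy_pfm, pseudocount=0.8)
        expected = math.log2((10 + 0.8 * 0.25) / (10 + 0.8) / 0.25)
        assert pwm.weights[0, 0] == pytest.approx(expected)

    def test_matches_biopython_log_odds(self, random_pfm):
        """Independent oracle: Biopython's PSSM with the same pseudocount split."""
        motifs = pytest.importorskip("Bio.motifs")
        pc, bg = 0.8, {b: 0.25 for b in BASES}
        m = motifs.Motif(counts={b: list(random_pfm.counts[i])
                                 for i, b in enumerate(BASES)})
        m.pseudocounts = {b: pc * bg[b] for b in BASES}
        m.background = bg
        pssm = m.pssm
        ours = pfm_to_pwm(random_pfm, pseudocount=pc)
        for i, b in enumerate(BASES):
            np.testing.assert_allclose(ours.weights[i], pssm[b], atol=1e-10)

    def test_score_max_equals_exhaustive_maximum(self, random_pwm):
        w = random_pwm.width
        raws = []
        for combo in itertools.product(range(4), repeat=w):
            raws.append(sum(random_pwm.weights[b, j] for j, b in enumerate(combo)))
        assert max(raws) == pytest.approx(random_pwm.score_max)
        assert min(raws) == pytest.approx(random_pwm.score_min)

    def test_invalid_inputs_raise(self, toy_pfm):
        with pytest.raises(ValueError):
            pfm_to_pwm(toy_pfm, pseudocount=0.0)
        with pytest.raises(ValueError):
            pfm_to_pwm(toy_pfm, background=(0.9, 0.1, 0.0, 0.0))


class TestRelativeScore:
    def test_consensus_and_anticonsensus_attain_bounds(self, random_pwm):
        consensus = "".join(BASES[b] for b in random_pwm.weights.argmax(axis=0))
        worst = "".join(BASES[b] for b in random_pwm.weights.argmin(axis=0))
        assert relative_score(random_pwm, consensus) == pytest.approx(1.0)
        assert relative_score(random_pwm, worst) == pytest.approx(0.0)

    def test_dimer_scores_match_brute_force_normalization(self, toy_pfm):
        """All 16 dimers against (raw - min)/(max - min) computed from counts."""
        pc = 0.8
        pwm = pfm_to_pwm(toy_pfm, pseudocount=pc)
        weight = {}
        for i, b in enumerate(BASES):
            for j in range(2):
                weight[b, j] = math.log2(
                    (toy_pfm.counts[i, j] + pc * 0.25)
                    / (toy_pfm.counts[:, j].sum() + pc) / 0.25)
        raws = {d: weight[d[0], 0] + weight[d[1], 1]
                for d in ("".join(p) for p in itertools.product(BASES, repeat=2))}
        lo, hi = min(raws.values()), max(raws.values())
        for dimer, raw in raws.items():
            assert relative_score(pwm, dimer) == pytest.approx((raw - lo) / (hi - lo))

    def test_wrong_length_and_n_rejected(self, random_pwm):
        with pytest.raises(ValueError):
            relative_score(random_pwm, "ACG")
        with pytest.raises(ValueError):
            relative_score(random_pwm, "ACGNAC")

    def test_revcomp_invariance(self, random_pfm, random_pwm):
        """Scoring a window equals scoring its reverse complement with the
        reverse-complemented matrix."""
        rc_pfm = PFM(matrix_id="RC", tf_name="RC",
                     counts=random_pfm.counts[::-1, ::-1].copy())
        rc_pwm = pfm_to_pwm(rc_pfm)
        rng = np.random.default_rng(5)
        for _ in range(50):
            win = random_seq(rng, random_pwm.width)
            assert relative_score(random_pwm, win) == pytest.approx(
                relative_score(rc_pwm, revcomp(win)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(data=st.data())
    def test_monotone_in_window_base_count(self, data):
        """Raising the count of the window's own base never lowers its RBS."""
        w = data.draw(st.integers(2, 4))
        counts = np.array(data.draw(st.lists(
            st.lists(st.integers(0, 20), min_size=w, max_size=w),
            min_size=4, max_size=4)), dtype=float)
        counts[0] += 1  # guarantee a positive entry per column
        window = "".join(data.draw(st.sampled_from(BASES)) for _ in range(w))
        col = data.draw(st.integers(0, w - 1))
        pfm = PFM(matrix_id="H", tf_name="H", counts=counts)
        bumped = counts.copy()
        bumped[BASES.index(window[col]), col] += data.draw(st.integers(1, 10))
        pfm2 = PFM(matrix_id="H2", tf_name="H2", counts=bumped)
        try:
            before = relative_score(pfm_to_pwm(pfm), window)
            after = relative_score(pfm_to_pwm(pfm2), window)
        except ValueError:
            return  # degenerate matrix (score_min == score_max)
        assert after >= before - 1e-9


class TestScanSnp:
    def test_matches_exhaustive_enumeration_on_random_sequences(self, random_pwm):
        rng = np.random.default_rng(99)
        for _ in range(40):
            seq = random_seq(rng, 50)
            off = int(rng.integers(0, 50))
            alt = BASES[(BASES.index(seq[off]) + 1) % 4]
            seq_minor = seq[:off] + alt + seq[off + 1:]
            got = scan_snp(random_pwm, seq, seq_minor, off)
            key, o, strand, ra, rb = brute_force_scan(random_pwm, seq, seq_minor, off)
            assert got is not None
            assert max(got[0].rbs, got[1].rbs) == pytest.approx(key)
            assert (got[0].offset, got[0].strand) == (o, strand)
            assert (got[0].rbs, got[1].rbs) == (pytest.approx(ra), pytest.approx(rb))

    def test_both_alleles_reported_at_the_same_window(self, random_pwm):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 60)
        seq_minor = seq[:30] + ("A" if seq[30] != "A" else "C") + seq[31:]
        ws_major, ws_minor = scan_snp(random_pwm, seq, seq_minor, 30)
        assert (ws_major.offset, ws_major.strand) == (ws_minor.offset, ws_minor.strand)

    def test_destroying_a_consensus_site_scores_major_one(self, random_pwm):
        consensus = "".join(BASES[b] for b in random_pwm.weights.argmax(axis=0))
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 20) + consensus + random_seq(rng, 20)
        off = 20 + 2
        worst = BASES[int(random_pwm.weights[:, 2].argmin())]
        if worst == seq[off]:
            worst = BASES[int(np.argsort(random_pwm.weights[:, 2])[1])]
        minor = seq[:off] + worst + seq[off + 1:]
        ws_major, ws_minor = scan_snp(random_pwm, seq, minor, off)
        assert ws_major.rbs == pytest.approx(1.0)
        assert ws_minor.rbs < 1.0

    def test_palindromic_matrix_ties_resolve_to_plus(self):
        # counts palindromic under reverse complement: both strands score
        # identically at every window, so the reported strand must be '+'
        counts = np.zeros((4, 4))
        for j, b in enumerate("ACGT"):
            counts["ACGT".index(b), j] = 10.0
        counts += 1
        pwm = pfm_to_pwm(PFM(matrix_id="P", tf_name="PAL", counts=counts))
        rng = np.random.default_rng(12)
        seq = random_seq(rng, 30)
        minor = seq[:15] + ("G" if seq[15] != "G" else "T") + seq[16:]
        plus, minus = window_relative_scores(pwm, seq)
        np.testing.assert_allclose(plus, minus, atol=1e-12)
        ws_major, _ = scan_snp(pwm, seq, minor, 15)
        assert ws_major.strand == "+"

    def test_candidate_set_truncates_at_sequence_edges(self, random_pwm):
        seq = "ACGTAC"
        minor = "CCGTAC"
        ws_major, _ = scan_snp(random_pwm, seq, minor, 0)
        assert ws_major.offset == 0  # only one in-bounds window

    def test_windows_containing_n_are_skipped(self, random_pwm):
        seq = "NNNNN" + "ACGTACGTAC"
        minor = seq[:7] + "G" + seq[8:]
        result = scan_snp(random_pwm, seq, minor, 7)
        ws_major, _ = result
        assert ws_major.offset >= 5  # windows overlapping the Ns were skipped

    def test_all_n_neighbourhood_gives_no_site(self, random_pwm):
        seq = "N" * 20
        minor = seq[:10] + "A" + seq[11:]
        assert scan_snp(random_pwm, seq, minor, 10) is None


class TestHomotypicSites:
    def make(self, pwm, planted_at, rng):
        consensus = "".join(BASES[b] for b in pwm.weights.argmax(axis=0))
        seq = list(random_seq(rng, 400))
        for o in planted_at:
            seq[o:o + pwm.width] = consensus
        return "".join(seq)

    def test_single_planted_site(self, recovery_fixture):
        pwm = recovery_fixture.pwms()[0]
        rng = np.random.default_rng(21)
        seq = self.make(pwm, [100], rng)
        assert count_homotypic_sites(pwm, seq) == 1

    def test_two_separated_sites_give_hr_two_hwf_half(self, recovery_fixture):
        pwm = recovery_fixture.pwms()[0]
        rng = np.random.default_rng(22)
        seq = self.make(pwm, [100, 300], rng)
        hr = count_homotypic_sites(pwm, seq)
        assert hr == 2 and hwf_of(hr) == 0.5

    def test_overlapping_tandem_suppressed_to_one(self, recovery_fixture):
        pwm = recovery_fixture.pwms()[0]
        consensus = "".join(BASES[b] for b in pwm.weights.argmax(axis=0))
        rng = np.random.default_rng(23)
        # two overlapping copies: offset and offset + w//2 share sequence
        seq = list(random_seq(rng, 300))
        seq[100:100 + pwm.width] = consensus
        seq[100 + pwm.width // 2:100 + pwm.width // 2 + pwm.width] = consensus
        hr = count_homotypic_sites(pwm, "".join(seq))
        assert hr == 1

    def test_minus_strand_sites_are_counted(self, recovery_fixture):
        pwm = recovery_fixture.pwms()[0]
        consensus = "".join(BASES[b] for b in pwm.weights.argmax(axis=0))
        rng = np.random.default_rng(24)
        seq = list(random_seq(rng, 300))
        seq[50:50 + pwm.width] = revcomp(consensus)
        assert count_homotypic_sites(pwm, "".join(seq)) == 1
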