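"""The affinity-impact / HR / HWF / FIF chain and the calling pipeline."""
import numpy as np
import pytest

from rsnpscan.formats import PFM, AccessibilityTrack, SNPRecord
from rsnpscan.motif import pfm_to_pwm
from rsnpscan.promoter import PromoterSpec, build_pseudopromoter
from rsnpscan.scoring import (Category, RSNPCall, ScanConfig, affinity_impact,
                              call_rsnps, categorize, fif_of, hwf_of)
from rsnpscan.synthdata import ANCHOR_COL, MOTIF_WIDTH, _make_pfms

from conftest import random_seq

BASES = "ACGT"


class TestAffinityImpact:
    @pytest.mark.parametrize("rbs_m,rbs_n,expected", [
        (0.87, 0.70, -19.54),   # published value -19.57, within 2-dp input rounding
        (0.80, 0.93, 16.25),    # published value 16.53, within input rounding
        (0.5, 0.5, 0.0),
        (0.80, 0.61, -23.75),
    ])
    def test_signed_percent_change(self, rbs_m, rbs_n, expected):
        assert round(affinity_impact(rbs_m, rbs_n), 2) == expected

    def test_zero_major_score_is_undefined(self):
        with pytest.raises(ValueError):
            affinity_impact(0.0, 0.5)


class TestHwfFif:
    @pytest.mark.parametrize("hr,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_hwf_is_exact_reciprocal(self, hr, expected):
        assert hwf_of(hr) == expected

    def test_hwf_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hwf_of(0)

    @pytest.mark.parametrize("impact,hr,expected", [
        (-23.68, 2, -11.84),
        (-20.76, 1, -20.76),
        (0.0, 3, 0.0),
    ])
    def test_fif_is_impact_times_hwf(self, impact, hr, expected):
        assert round(fif_of(impact, hr), 2) == expected

    @pytest.mark.parametrize("impact", [-23.68, 16.53, -11.2, 40.0])
    @pytest.mark.parametrize("hr", [1, 2, 3])
    def test_doubling_hr_halves_fif_magnitude(self, impact, hr):
        assert abs(fif_of(impact, 2 * hr)) == pytest.approx(abs(fif_of(impact, hr)) / 2)


class TestCategorize:
    def test_strong_positive_fif_suggests_new_tfbs(self):
        assert categorize(11.51, 0.86, 0.96) is Category.new_tfbs_suggested

    def test_strong_negative_fif_is_decreased_affinity(self):
        assert categorize(-19.57, 0.87, 0.70) is Category.decreased_affinity

    def test_small_fif_below_threshold(self):
        assert categorize(5.0, 0.80, 0.84) is Category.below_threshold
        assert categorize(-10.0, 0.85, 0.76) is Category.below_threshold  # gate is strict

    def test_strict_creation_reading_labels_strong_major_as_increased(self):
        assert categorize(11.51, 0.86, 0.96,
                          creation_requires_weak_major=True) is Category.increased_affinity
        assert categorize(20.0, 0.70, 0.95,
                          creation_requires_weak_major=True) is Category.new_tfbs_suggested


class TestRSNPCallInvariants:
    def test_inconsistent_fif_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            RSNPCall(gene_symbol="G", rsid="rs1", cell_line="Hcm", tf_name="T",
                     rbs_major=0.9, rbs_minor=0.7, affinity_impact_pct=-22.2,
                     hr=2, fif=-22.2, category=Category.decreased_affinity)

    def test_emitted_calls_satisfy_invariants(self, recovery_fixture):
        calls = call_rsnps(recovery_fixture.build_promoters(),
                           recovery_fixture.pwms(), recovery_fixture.tracks,
                           recovery_fixture.scan_config())
        assert calls
        for c in calls:
            assert c.hwf == 1.0 / c.hr
            assert c.fif == pytest.approx(c.affinity_impact_pct * c.hwf)
            assert np.sign(c.fif) == np.sign(c.affinity_impact_pct)
            assert abs(c.fif) > 10.0
            assert max(c.rbs_major, c.rbs_minor) >= 0.80
        assert calls == sorted(calls, key=RSNPCall.sort_key)


def _single_tf_setup(two_sites: bool):
    """A promoter with one (or two) planted consensus sites of one TF and a
    destroyer SNP in the first site's anchor column."""
    rng = np.random.default_rng(4242)
    (pfm,) = _make_pfms(rng, n_tfs=1, width=MOTIF_WIDTH)
    consensus = pfm.consensus
    worst = BASES[int(pfm.counts[:, ANCHOR_COL].argmin())]
    seq = list(random_seq(rng, 2000))
    seq[400:400 + MOTIF_WIDTH] = consensus
    if two_sites:
        seq[1200:1200 + MOTIF_WIDTH] = consensus
    genome = {"chrT": "".join(seq) + random_seq(rng, 50)}
    snp = SNPRecord(rsid="rs_t", chrom="chrT", pos=400 + ANCHOR_COL + 1,
                    major_allele=consensus[ANCHOR_COL], minor_allele=worst, maf=0.3)
    spec = PromoterSpec(gene_symbol="GT", chrom="chrT", tss=2001)
    pp = build_pseudopromoter(spec, genome, [snp])
    track = AccessibilityTrack(cell_line="Hcm",
                               intervals=(("chrT", snp.pos - 5, snp.pos + 5),))
    return pp, pfm_to_pwm(pfm), track


class TestCallRsnps:
    def test_planted_destroyer_in_peak_yields_one_decreased_call(self):
        pp, pwm, track = _single_tf_setup(two_sites=False)
        calls = call_rsnps([pp], [pwm], [track])
        assert len(calls) == 1
        c = calls[0]
        assert c.category is Category.decreased_affinity
        assert c.rbs_major == pytest.approx(1.0) and c.hr == 1

    def test_same_snp_outside_every_peak_yields_no_calls(self):
        pp, pwm, _ = _single_tf_setup(two_sites=False)
        empty = AccessibilityTrack(cell_line="Hcm", intervals=(("chrT", 1900, 1950),))
        assert call_rsnps([pp], [pwm], [empty]) == []

    def test_second_identical_site_halves_fif(self):
        # the gate is lowered so the HWF-discounted two-site call still
        # surfaces and the halving can be compared at full precision
        cfg = ScanConfig(fif_threshold=5.0)
        pp1, pwm, track = _single_tf_setup(two_sites=False)
        pp2, _, _ = _single_tf_setup(two_sites=True)
        (one,) = call_rsnps([pp1], [pwm], [track], cfg)
        (two,) = call_rsnps([pp2], [pwm], [track], cfg)
        assert two.hr == 2 * one.hr == 2
        assert abs(two.fif) == pytest.approx(abs(one.fif) / 2)
        assert two.affinity_impact_pct == pytest.approx(one.affinity_impact_pct)

    def test_rare_snps_excluded_unless_configured(self):
        pp, pwm, track = _single_tf_setup(two_sites=False)
        rare = SNPRecord(rsid="rs_t", chrom="chrT", pos=pp.snps[0][0].pos,
                         major_allele=pp.snps[0][0].major_allele,
                         minor_allele=pp.snps[0][0].minor_allele, maf=0.005)
        pp_rare = build_pseudopromoter(
            PromoterSpec(gene_symbol="GT", chrom="chrT", tss=2001),
            {"chrT": pp.sequence + "A" * 50}, [rare])
        assert call_rsnps([pp_rare], [pwm], [track]) == []
        kept = call_rsnps([pp_rare], [pwm], [track],
                          ScanConfig(require_common=False))
        assert len(kept) == 1

    def test_empty_inputs_give_empty_result(self):
        assert call_rsnps([], [], [], ScanConfig()) == []
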