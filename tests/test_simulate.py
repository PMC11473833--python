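"""Synthetic-data generator: signal model, cohorts, sticks, templates."""

import dataclasses

import numpy as np
import pytest

from casplex import simulate as sim
from casplex.alleles import CHANNELS, GENOTYPES, assay_states, channel_levels


class TestSignalModel:
    def test_ntc_trace_noiseless_closed_form(self, noiseless_params):
        tr = sim.generate_trace("NTC", "FAM", noiseless_params, seed=0)
        p = noiseless_params
        expected = p.baseline + p.amplitude_low_fraction * p.amplitude_high * (
            1 - np.exp(-p.rate * tr.times))
        np.testing.assert_allclose(tr.rfus, expected, rtol=1e-12)
        # with f_low = 0.02 the NTC stays within a few percent of baseline scale
        assert tr.rfus.max() <= p.baseline + 0.021 * p.amplitude_high

    def test_same_seed_bitwise_identical(self, default_params):
        a = sim.generate_trace("G1G2", "HEX", default_params, seed=42)
        b = sim.generate_trace("G1G2", "HEX", default_params, seed=42)
        assert np.array_equal(a.rfus, b.rfus)

    def test_het_to_hom_amplitude_ratio_is_f_med(self, noiseless_params):
        """One of two alleles being the target halves the FAM amplitude."""
        het = sim.generate_trace("G0G1", "FAM", noiseless_params, seed=0)
        hom = sim.generate_trace("G1G1", "FAM", noiseless_params, seed=0)
        b = noiseless_params.baseline
        ratio = (het.rfus[-1] - b) / (hom.rfus[-1] - b)
        assert ratio == pytest.approx(noiseless_params.amplitude_med_fraction, rel=1e-12)

    def test_final_rfu_monotone_in_level(self, noiseless_params):
        finals = {lvl: sim.generate_trace(g, "FAM", noiseless_params, seed=0).rfus[-1]
                  for g, lvl in (("G0G0", "low"), ("G0G1", "med"), ("G1G1", "high"))}
        assert finals["low"] < finals["med"] < finals["high"]

    def test_unknown_channel_and_genotype_rejected(self, default_params):
        with pytest.raises(ValueError, match="channel"):
            sim.generate_trace("G0G0", "CY5", default_params, seed=0)
        with pytest.raises(ValueError, match="genotype"):
            sim.generate_trace("G3G3", "FAM", default_params, seed=0)

    @pytest.mark.parametrize("field,value", [
        ("amplitude_high", -1.0), ("amplitude_low_fraction", 0.6),
        ("rate", 0.0), ("noise_sd", -1.0), ("duration", 30.0)])
    def test_invalid_params_rejected(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(sim.SignalModelParams(), **{field: value})


class TestLevelMap:
    def test_fam_level_tracks_g1_allele_count(self):
        for g in GENOTYPES:
            fam, hex_, tex = channel_levels(g)
            n_g1 = g.count("G1")
            assert fam == ("low", "med", "high")[n_g1]
            assert hex_ == ("high" if "G2" in g else "low")
            assert tex == ("low" if g == "G2G2" else "high")

    def test_standards_drive_their_target_channels(self):
        """sG1G1 is the FAM/TEX positive standard, sG2G2 the HEX one."""
        s11 = [sim.signal_level("standard_sG1G1", ch) for ch in CHANNELS]
        s22 = [sim.signal_level("standard_sG2G2", ch) for ch in CHANNELS]
        assert s11 == ["high", "low", "high"]
        assert s22 == ["low", "high", "low"]
        assert [sim.signal_level("NTC", ch) for ch in CHANNELS] == ["low"] * 3


class TestCohort:
    def test_trace_counts(self, noiseless_params):
        cohort = sim.generate_cohort(1, noiseless_params, seed=0)
        sample_traces = [t for t in cohort.plate.traces if t.role == "sample"]
        assert len(sample_traces) == 6 * 3 * 6   # genotypes x channels x replicates
        assert len(cohort.truth) == 6

    def test_label_marginals_exact(self, small_cohort):
        from collections import Counter
        counts = Counter(small_cohort.truth.values())
        assert counts == {g: 5 for g in GENOTYPES}

    def test_cohort_deterministic_under_seed(self, default_params):
        a = sim.generate_cohort(2, default_params, seed=3)
        b = sim.generate_cohort(2, default_params, seed=3)
        for ta, tb in zip(a.plate.traces, b.plate.traces):
            assert ta.well == tb.well and np.array_equal(ta.rfus, tb.rfus)

    def test_batches_have_standards_and_ntc(self, default_params):
        cohort = sim.generate_cohort(2, default_params, n_batches=2, seed=4)
        for batch in cohort.plate.batches():
            for ch in CHANNELS:
                assert cohort.plate.standards(ch, batch)
                assert cohort.plate.ntc(ch, batch)


class TestStickImages:
    def test_hom_g1_band_pattern(self):
        """G1G1: mutant-sensing (streptavidin) band faint, wt band dark."""
        g1, _ = sim.generate_stick_image("hom", "wt", seed=0, noise_sd=0.0)
        img, lay = g1.image, g1.layout
        strep = lay.streptavidin.slice(img).mean()
        antidig = lay.anti_digoxigenin.slice(img).mean()
        assert strep > antidig + 100   # faint (light) vs dark

    def test_het_both_test_bands_faint(self):
        g1, g2 = sim.generate_stick_image("het", "het", seed=0, noise_sd=0.0)
        for stick in (g1, g2):
            img, lay = stick.image, stick.layout
            blank = lay.blank.slice(img).mean()
            assert lay.streptavidin.slice(img).mean() > blank - 15
            assert lay.anti_digoxigenin.slice(img).mean() > blank - 15

    def test_control_band_darker_than_blank_everywhere(self):
        for pair in sim.VALID_STATE_PAIRS:
            for stick in sim.generate_stick_image(*pair, seed=1):
                img, lay = stick.image, stick.layout
                assert lay.control.slice(img).mean() < lay.blank.slice(img).mean()

    def test_inconsistent_state_pair_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sim.generate_stick_image("hom", "het", seed=0)

    def test_state_pairs_match_allele_content(self):
        assert set(sim.VALID_STATE_PAIRS) == {assay_states(g) for g in GENOTYPES}


class TestTemplates:
    def test_g2_allele_six_shorter(self, template):
        al = template.alleles
        assert len(al["wt"]) - len(al["G2"]) == 6
        assert len(al["wt"]) - len(al["G1G2"]) == 6

    def test_g1_allele_hamming_distance_one(self, template):
        al = template.alleles
        diff = [i for i, (a, b) in enumerate(zip(al["wt"], al["G1"])) if a != b]
        assert diff == [template.g1_pos]
        assert al["wt"][template.g1_pos] == "A" and al["G1"][template.g1_pos] == "G"

    def test_hexamer_present_in_wt_absent_in_g2(self, template):
        a, b = template.g2_interval
        assert template.wt[a:b] == "TTATAA"
        assert template.alleles["G2"][a:a + 6] != "TTATAA"

    def test_variant_spacing(self, template):
        assert template.g2_interval[0] - template.g1_pos == 138

    def test_short_context_rejected(self):
        with pytest.raises(ValueError, match="context_len"):
            sim.generate_templates(100, seed=0)

    def test_fasta_round_trip(self, template, tmp_path):
        from Bio import SeqIO
        path = tmp_path / "alleles.fa"
        sim.write_templates_fasta(template, path)
        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert recs == template.alleles
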