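"""Design rules: crRNA geometry, PAM scanning, primer constraints."""

import math
import re

import numpy as np
import pytest

from casplex import simulate as sim
from casplex.design import (PAM_MOTIFS, SPACER_LENGTH, T7_OVERHANG,
                            design_cas12a_crrnas, design_deletion_tiling,
                            design_rpa_primers, design_snp_crrnas, primer_tm,
                            revcomp_dna, revcomp_rna, scan_pam)


class TestSnpCrRNAs:
    def test_winner_geometry_present(self, template):
        designs = design_snp_crrnas(template.wt, template.g1_pos)
        assert any(d.mismatch_positions == (1, 4) for d in designs)
        assert all(d.variant_offset == 3 for d in designs)

    def test_spacer_length_28(self, template):
        designs = design_snp_crrnas(template.wt, template.g1_pos)
        assert {len(d.spacer) for d in designs} == {28}
        assert {d.dr_end for d in designs} == {"5p"}

    def test_mismatch_sets_are_singletons_and_pairs_excluding_snp(self, template):
        designs = design_snp_crrnas(template.wt, template.g1_pos)
        sets = {d.mismatch_positions for d in designs}
        assert len(sets) == 10
        assert all(3 not in s for s in sets)
        assert all(set(s) <= {1, 2, 4, 5} for s in sets)

    def test_spacers_differ_from_perfect_revcomp_only_at_mismatches(self, template):
        """Positional diff oracle against the mutant-allele reverse complement."""
        mutant = template.alleles["G1"]
        for d in design_snp_crrnas(template.wt, template.g1_pos):
            a, b = d.target_window
            perfect = revcomp_rna(mutant[a:b])
            diffs = [i for i, (x, y) in enumerate(zip(d.spacer, perfect)) if x != y]
            expected = sorted(d.spacer_index(p) for p in d.mismatch_positions)
            assert diffs == expected

    def test_mismatch_base_pairs_with_neither_allele(self, template):
        comp = {"A": "U", "C": "G", "G": "C", "T": "A"}
        for d in design_snp_crrnas(template.wt, template.g1_pos):
            for p in d.mismatch_positions:
                tmpl_base = template.wt[d.template_coord(p)]
                assert d.spacer[d.spacer_index(p)] != comp[tmpl_base]

    def test_coordinate_round_trip_recovers_snp(self, template):
        for d in design_snp_crrnas(template.wt, template.g1_pos):
            assert d.template_coord(d.variant_offset) == template.g1_pos

    def test_insufficient_flank_rejected(self, template):
        with pytest.raises(ValueError, match="flank"):
            design_snp_crrnas(template.wt, 5)


class TestDeletionTiling:
    def test_full_overlap_count_and_step(self, template):
        designs = design_deletion_tiling(template.wt, template.g2_interval)
        assert len(designs) == 30 - 6 + 1
        starts = [d.target_window[0] for d in designs]
        assert all(b - a == 1 for a, b in zip(starts, starts[1:]))
        assert {len(d.spacer) for d in designs} == {30}
        assert {d.dr_end for d in designs} == {"3p"}

    def test_zero_mismatch_spacers_are_exact_revcomp(self, template):
        for d in design_deletion_tiling(template.wt, template.g2_interval):
            a, b = d.target_window
            assert d.spacer == revcomp_rna(template.wt[a:b])

    def test_every_spacer_loses_six_pairings_on_deletion_allele(self, template):
        """The deletion removes >=6 of each wt spacer's target bases."""
        a, b = template.g2_interval
        for d in design_deletion_tiling(template.wt, template.g2_interval):
            wa, wb = d.target_window
            overlap = min(wb, b) - max(wa, a)
            assert overlap >= 6   # full-overlap mode contains the hexamer

    def test_partial_mode_requires_one_base_overlap(self, template):
        designs = design_deletion_tiling(template.wt, template.g2_interval,
                                         mode="partial")
        assert len(designs) == 6 + 30 - 1
        a, b = template.g2_interval
        for d in designs:
            wa, wb = d.target_window
            assert min(wb, b) - max(wa, a) >= 1


class TestPamScan:
    def test_canonical_hit_at_offset_zero(self):
        sites = scan_pam("TTTAGGGCCC", strand="+")
        assert any(s.start == 0 and s.motif == "TTTV" for s in sites)

    def test_all_a_sequence_no_hits(self):
        assert scan_pam("A" * 100) == []

    def test_matches_regex_oracle_on_random_sequence(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        patterns = {"TTTV": "TTT[ACG]", "TCTV": "TCT[ACG]",
                    "TTCV": "TTC[ACG]", "CTTV": "CTT[ACG]"}
        expected = 0
        for pat in patterns.values():
            expected += len(re.findall(f"(?={pat})", seq))
            expected += len(re.findall(f"(?={pat})", revcomp_dna(seq)))
        assert len(scan_pam(seq)) == expected

    def test_minus_strand_coordinates(self):
        # forward GCAAA: revcomp TTTGC -> minus-strand TTTG at fwd [0,4)? check
        seq = "GCAAA"
        hits = [s for s in scan_pam(seq) if s.strand == "-"]
        for s in hits:
            assert revcomp_dna(seq[s.start:s.end]) == s.sequence
            assert s.sequence[:3] in ("TTT", "TCT", "TTC", "CTT")


class TestCas12a:
    def test_spacers_are_20nt_and_pam_adjacent(self, template):
        designs = design_cas12a_crrnas(template.wt, template.g2_interval)
        assert designs, "expected at least one PAM-anchored design near the deletion"
        for d in designs:
            assert len(d.spacer) == SPACER_LENGTH["LbaCas12a"]
            assert d.pam is not None and len(d.pam) == 4

    def test_protospacer_covers_variant(self, template):
        a, b = template.g2_interval
        for d in design_cas12a_crrnas(template.wt, template.g2_interval):
            wa, wb = d.target_window
            assert wa < b and wb > a


class TestPrimers:
    def test_emitted_pairs_satisfy_all_constraints(self, template):
        pairs = design_rpa_primers(template.wt, [template.g1_pos, template.g2_interval])
        assert pairs
        a, b = template.g2_interval
        for p in pairs:
            assert 25 <= len(p.forward) <= 30 and 25 <= len(p.reverse) <= 30
            assert 57 <= p.tm_forward <= 67 and 57 <= p.tm_reverse <= 67
            s, e = p.amplicon
            assert s <= template.g1_pos < e and s <= a and b <= e
            assert p.forward_full == T7_OVERHANG + p.forward
            assert p.amplicon_length == e - s
            # orientation: reverse primer is the revcomp of the 3' window
            assert p.reverse == revcomp_dna(template.wt[e - len(p.reverse):e])
            assert template.wt[s:s + len(p.forward)] == p.forward

    def test_no_feasible_pair_gives_empty_list(self):
        # a pure-AT template cannot reach the Tm window
        pairs = design_rpa_primers("AT" * 200, [(190, 210)])
        assert pairs == []

    def test_tm_matches_independent_nearest_neighbor_reimplementation(self):
        """Duplicate-implementation oracle for the thermodynamic model."""
        NN = {"AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
              "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
              "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
              "GG": (-8.0, -19.9)}

        def oracle_tm(seq, Na=50.0, dnac1=250.0):
            dh = ds = 0.0
            for base in (seq[0], seq[-1]):
                if base in "AT":
                    dh, ds = dh + 2.3, ds + 4.1
                else:
                    dh, ds = dh + 0.1, ds - 2.8
            for i in range(len(seq) - 1):
                pair = seq[i:i + 2]
                h, s = NN.get(pair) or NN[revcomp_dna(pair)]
                dh, ds = dh + h, ds + s
            ds += 0.368 * (len(seq) - 1) * math.log(Na / 1000.0)
            return (1000 * dh) / (ds + 1.987 * math.log(dnac1 * 1e-9)) - 273.15

        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(25, 31)) | 1   # odd length: never self-complementary
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert primer_tm(seq) == pytest.approx(oracle_tm(seq), abs=0.1)
        assert primer_tm("ACGT" * 7) == pytest.approx(oracle_tm("ACGT" * 7), abs=0.1)
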