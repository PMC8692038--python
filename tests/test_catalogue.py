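"""Repeat decomposition, motif grammar scanning, family classification,
and composition statistics."""

import numpy as np
import pytest

from silkforge.catalogue import (RepeatUnit, classify_family,
                                 classify_family_rotation_invariant,
                                 composition_stats, decompose_repeats,
                                 grammar_for, load_grammars, scan_motifs)
from silkforge.simgen import build_gene

AA = list("ACDEFGHIKLMNPQRSTVWY")

ALL_FAMILIES = ["MaSp1", "MaSp2", "MaSp3", "MaSp4", "MaSp5",
                "MiSp1B", "MiSp1C", "MiSp1D", "Flag"]


def _rand_aa(n, seed):
    return "".join(np.random.default_rng(seed).choice(AA, n))


class TestDecompose:
    def test_tandem_with_flanks_recovers_units(self):
        unit = "GPGSQGPGSQAAAAAA"
        prot = _rand_aa(50, 1) + unit * 6 + _rand_aa(50, 2)
        units = decompose_repeats(prot, period_min=4, period_max=60)
        assert len(units) == 6
        assert all(len(u.aa_seq) == 16 for u in units)
        # flanks excluded: every unit is a rotation of the true unit
        assert all(u.aa_seq in unit * 2 for u in units)

    def test_random_proteins_are_non_repetitive(self):
        for s in range(50):
            assert decompose_repeats(_rand_aa(300, 100 + s),
                                     period_min=4, period_max=100) == []

    def test_exact_dipeptide_tandem(self):
        units = decompose_repeats("GA" * 30, period_min=2, period_max=20)
        assert len(units) == 30
        assert all(u.aa_seq in ("GA", "AG") for u in units)

    def test_shift_stability(self):
        unit = "GPGGXSGPGGQGGAAAA".replace("X", "Y")
        prot = unit * 8
        base = decompose_repeats(prot, period_min=4, period_max=60)
        shifted = decompose_repeats(_rand_aa(25, 3) + prot,
                                    period_min=4, period_max=60)
        assert abs(len(base) - len(shifted)) <= 1
        assert len(shifted[0].aa_seq) == len(base[0].aa_seq)

    def test_too_short_protein_rejected(self):
        with pytest.raises(ValueError):
            decompose_repeats("GAGA", period_min=4, period_max=10)


class TestScanMotifs:
    def test_masp4_unit_hits_and_neutral_tail(self):
        unit = scan_motifs(RepeatUnit("GPGPQGPGPQVSVVSTTVS"),
                           grammar_for("MaSp4"))
        assert [h for h in unit.motif_hits if h[0] == "GPGPQ"] == \
            [("GPGPQ", 0), ("GPGPQ", 5)]
        assert unit.tail_kind == "poly_X"
        assert unit.tail_seq == "VSVVSTTVS"

    def test_masp5_unit_tail_free(self):
        unit = scan_motifs(RepeatUnit("GGLGGSGGSGGR"), grammar_for("MaSp5"))
        motifs = {h[0] for h in unit.motif_hits}
        assert {"GGLGGSG", "GSGGR"} <= motifs
        assert unit.tail_kind == "none"

    def test_polyalanine_only_unit(self):
        unit = scan_motifs(RepeatUnit("AAAAAA"), grammar_for("MaSp2"))
        assert unit.tail_kind == "poly_A"
        assert not any(h[0] in grammar_for("MaSp2").core_motifs
                       for h in unit.motif_hits)

    def test_hit_offsets_index_verbatim_occurrences(self):
        rng = np.random.default_rng(4)
        g = grammar_for("MaSp2")
        for _ in range(100):
            seq = "".join(rng.choice(AA, 30)) + "GPGSQ" + \
                "".join(rng.choice(AA, 10))
            unit = scan_motifs(RepeatUnit(seq), g)
            for motif, off in unit.motif_hits:
                assert seq[off:off + len(motif)] == motif


class TestClassify:
    def test_masp4_on_masp2_clade_ntd_is_not_a_conflict(self):
        units = [RepeatUnit("GPGPQGPGPQVSVVSTTVS")] * 5
        label, info = classify_family(units, ntd_assignment="MaSp2")
        assert label == "MaSp4"
        assert info["conflict"] is False

    def test_sggrggy_units_are_masp3(self):
        units = [RepeatUnit("SGGRGGYSGGRGGYAAAAA")] * 4
        label, _ = classify_family(units)
        assert label == "MaSp3"

    def test_polyA_GA_tails_with_misp_ntd_fall_in_misp1b_d_group(self):
        units = [RepeatUnit("GGAGGYGGGAGGYGGAGAGA")] * 4
        label, info = classify_family(units, ntd_assignment="MiSp")
        assert label in ("MiSp1B", "MiSp1D")
        assert info["conflict"] is False

    def test_conflicting_ntd_sets_flag_but_keeps_motif_winner(self):
        units = [RepeatUnit("GPGPQGPGPQVSVVSTTVS")] * 5
        label, info = classify_family(units, ntd_assignment="Flag")
        assert label == "MaSp4"
        assert info["conflict"] is True

    def test_empty_units_give_other(self):
        label, info = classify_family([])
        assert label == "other"
        assert all(v == 0.0 for v in info["scores"].values())

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_round_trip_through_gene_builder(self, family):
        gene = build_gene(family, n_repeats=8, repeat_len_aa=40, seed=5)
        label, _ = classify_family(gene.repeats)
        assert label == family

    @pytest.mark.parametrize("family", ALL_FAMILIES)
    def test_round_trip_through_decomposition(self, family):
        gene = build_gene(family, n_repeats=8, repeat_len_aa=40, seed=6)
        units = decompose_repeats(gene.protein, period_min=5, period_max=80)
        assert units
        label, _ = classify_family_rotation_invariant(units)
        assert label == family


class TestComposition:
    def test_ten_percent_cysteine_flags_crp(self):
        rep = composition_stats("CGGGGGGGGG", crp_threshold=0.05)
        assert rep.cys_fraction == pytest.approx(0.10)
        assert rep.is_crp

    def test_pure_alanine(self):
        rep = composition_stats("AAAA")
        assert rep.fractions == {"A": 1.0}
        assert not rep.is_crp

    def test_fractions_match_brute_force_counts(self):
        seq = _rand_aa(200, 7)
        rep = composition_stats(seq)
        assert sum(rep.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        for aa, frac in rep.fractions.items():
            assert frac == seq.count(aa) / 200

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            composition_stats("AAB")


def test_grammar_table_content():
    """The packaged grammar carries the diagnostic bark-spider motifs."""
    g = {x.family: x for x in load_grammars()}
    assert g["MaSp4"].core_motifs == ["GPGPQ"]
    assert "VSVVSTTVS" in g["MaSp4"].tail_motifs
    assert set(g["MaSp5"].core_motifs) == {"GGLGGSG", "GSGGR"}
    assert g["MaSp5"].tail_rule == "none"
    assert "SGGRGGY" in g["MaSp3"].core_motifs
    assert "GPGSQ" in g["MaSp2"].core_motifs
    assert {"SSSVAISL", "ISISAAAS"} <= set(g["MaSp1"].tail_motifs)
    assert g["MaSp4"].clade == "MaSp2"
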