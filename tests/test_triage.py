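"""Restriction scanning, strategy classification, hydropathy triage, mass and modules."""

import pytest

from isoclone.fixtures import FixtureSpec, random_cds
from isoclone.sequence_model import BAMHI, BGLII, ECORI, ENZYMES, MFEI, AnnotatedSegment, TargetGene
from isoclone.triage import (
    classify_strategy,
    detect_membrane_segments,
    hydropathy_profile,
    predicted_mass,
    scan_sites,
    split_modules,
    triage_target,
    trim_target,
)
from conftest import random_dna

# Independent oracle: average residue masses (Da); protein mass = sum + one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def naive_find_all(seq, motif):
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


class TestScanSites:
    @pytest.mark.parametrize(
        "seq,enzyme,hits",
        [("GGATCC", BAMHI, [0]), ("AAAAAA", ECORI, []),
         ("AGGATCCGGATCC", BAMHI, [1, 7]), ("CAATTG" * 2, MFEI, [0, 6])],
    )
    def test_hand_cases(self, seq, enzyme, hits):
        assert scan_sites(seq, enzyme) == hits

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(50):
            seq = random_dna(rng, 1000)
            for enz in ENZYMES.values():
                assert scan_sites(seq, enz) == naive_find_all(seq, enz.site)


class TestClassifyStrategy:
    def site_free(self, seed=11):
        return random_cds(FixtureSpec(seed=seed, n_codons=120, id="x"))

    def test_clean_cds_gets_native_pair(self):
        a = classify_strategy(self.site_free())
        assert (a.forward_enzyme, a.reverse_enzyme) == (BAMHI, ECORI)
        assert a.status == "assigned"

    @pytest.mark.parametrize(
        "implants,expected",
        [({"BamHI": [20]}, ("BglII", "EcoRI")),
         ({"EcoRI": [20]}, ("BamHI", "MfeI")),
         ({"BamHI": [20], "EcoRI": [40]}, ("BglII", "MfeI"))],
    )
    def test_internal_sites_force_isocaudomer(self, implants, expected):
        t = random_cds(FixtureSpec(seed=3, n_codons=120, implant_sites=implants, id="x"))
        a = classify_strategy(t)
        assert (a.forward_enzyme.name, a.reverse_enzyme.name) == expected

    def test_both_forward_sites_internal_eliminates(self):
        t = random_cds(FixtureSpec(seed=5, n_codons=120,
                                   implant_sites={"BamHI": [20], "BglII": [40]}, id="x"))
        a = classify_strategy(t)
        assert a.status == "eliminated_restriction"
        assert a.forward_enzyme is None and a.reverse_enzyme is None

    def test_never_assigns_an_internally_cutting_enzyme(self, rng):
        for seed in range(30):
            implants = [{}, {"BamHI": [20]}, {"EcoRI": [30]},
                        {"BamHI": [20], "EcoRI": [40]}][seed % 4]
            t = random_cds(FixtureSpec(seed=seed, n_codons=100, implant_sites=implants, id="x"))
            a = classify_strategy(t)
            if a.status == "assigned":
                assert not scan_sites(t.cds, a.forward_enzyme)
                assert not scan_sites(t.cds, a.reverse_enzyme)


class TestHydropathy:
    def test_poly_leucine_window_mean(self):
        assert hydropathy_profile("L" * 19, 19)[9] == pytest.approx(3.8)

    def test_poly_aspartate_window_mean(self):
        assert hydropathy_profile("D" * 19, 19)[9] == pytest.approx(-3.5)

    def test_edges_carry_no_score(self):
        scores = hydropathy_profile("L" * 25, 19)
        assert scores[:9] == [None] * 9 and scores[-9:] == [None] * 9
        assert all(s is not None for s in scores[9:-9])

    def test_profile_of_symmetric_sequence_is_symmetric(self):
        seq = "LDDLLDDL" * 4
        seq = seq + seq[::-1]
        scores = [s for s in hydropathy_profile(seq, 9) if s is not None]
        assert scores == pytest.approx(scores[::-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            hydropathy_profile("L" * 30, 18)


class TestDetectMembraneSegments:
    def test_idealized_signal_peptide(self):
        protein = "M" + "L" * 25 + "Q" * 200
        segments = detect_membrane_segments(protein)
        assert len(segments) == 1
        seg = segments[0]
        assert seg.kind == "signal_peptide"
        assert seg.start <= 35 and seg.end <= 35
        # boundaries within half a window of the implanted 1-26 stretch
        assert abs(seg.start - 1) <= 9 and abs(seg.end - 26) <= 9

    def test_all_polar_protein_has_no_segments(self):
        assert detect_membrane_segments("Q" * 300) == []

    def test_two_implanted_tm_helices_recovered(self):
        protein = "Q" * 99 + "L" * 25 + "Q" * 75 + "L" * 25 + "Q" * 76
        segments = detect_membrane_segments(protein)
        assert [s.kind for s in segments] == ["transmembrane", "transmembrane"]
        for seg, (true_start, true_end) in zip(segments, [(100, 124), (200, 224)]):
            assert abs(seg.start - true_start) <= 9
            assert abs(seg.end - true_end) <= 9


class TestPredictedMass:
    def test_glycine(self):
        assert predicted_mass("G") == pytest.approx(0.07507, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            predicted_mass("")

    def test_agrees_with_residue_mass_table(self, clean_target):
        protein = clean_target.protein
        expected = (sum(RESIDUE_MASS[aa] for aa in protein) + 18.02) / 1000
        assert predicted_mass(protein) == pytest.approx(expected, rel=1e-4)


class TestTrimTarget:
    def test_annotated_sp_removed_at_codon_23(self):
        t = random_cds(FixtureSpec(seed=7, n_codons=200, signal_peptide=True, id="x"))
        assert t.annotations == [AnnotatedSegment("signal_peptide", 1, 22)]
        rep = trim_target(t, use_annotations=True)
        assert rep.retained_interval[0] == 67
        assert rep.retained_cds == t.cds[66 : rep.retained_interval[1]]
        assert len(rep.retained_cds) % 3 == 0

    def test_membrane_riddled_protein_eliminated(self):
        tm = [(20, 50), (60, 90), (100, 130), (140, 170), (175, 195)]
        t = random_cds(FixtureSpec(seed=8, n_codons=200, tm_segments=tm, id="x"))
        rep = trim_target(t, use_annotations=True)
        assert rep.eliminated and "throughout" in rep.reason

    def test_soluble_protein_fully_retained_and_in_range(self, clean_target):
        rep = trim_target(clean_target, use_annotations=True)
        assert not rep.eliminated
        assert rep.retained_cds == clean_target.cds
        assert rep.mass_in_range
        assert 7 <= rep.predicted_mass_kda <= 140

    def test_single_cterm_tm_keeps_nterm_span(self):
        t = random_cds(FixtureSpec(seed=9, n_codons=200, tm_segments=[(160, 185)], id="x"))
        rep = trim_target(t, use_annotations=True)
        assert not rep.eliminated
        assert rep.retained_interval == (1, 159 * 3)

    def test_detection_path_matches_annotation_path_on_sp_fixture(self):
        # polar stretch right after the hydrophobic SP keeps the detected
        # boundary within half a window of the constructed one
        t = random_cds(FixtureSpec(seed=10, n_codons=200, signal_peptide=True, id="x"))
        cds = t.cds[:66] + "CAG" * 18 + t.cds[120:]
        polar = TargetGene(id="x", cds=cds)
        rep = trim_target(polar, use_annotations=False)
        assert rep.removed_segments and rep.removed_segments[0].kind == "signal_peptide"
        assert abs(rep.retained_interval[0] - 67) <= 9 * 3


class TestSplitModules:
    def test_single_module_covering_protein_is_identity(self, clean_target):
        plen = len(clean_target.protein)
        out = split_modules(clean_target, [AnnotatedSegment("module", 1, plen)])
        assert len(out) == 2
        assert out[1].cds == clean_target.cds[: plen * 3]

    def test_two_modules_tile_into_300nt_children(self):
        t = random_cds(FixtureSpec(seed=12, n_codons=201, id="p"))
        mods = [AnnotatedSegment("module", 1, 100), AnnotatedSegment("module", 101, 200)]
        out = split_modules(t, mods)
        assert [len(c.cds) for c in out[1:]] == [300, 300]
        assert [c.id for c in out[1:]] == ["p_m1", "p_m2"]
        from isoclone.sequence_model import translate
        assert translate(out[1].cds) + translate(out[2].cds) == t.protein

    def test_overlapping_modules_rejected(self, clean_target):
        mods = [AnnotatedSegment("module", 1, 100), AnnotatedSegment("module", 90, 150)]
        with pytest.raises(ValueError, match="overlap"):
            split_modules(clean_target, mods)

    def test_children_inherit_domain(self, clean_target):
        out = split_modules(clean_target, [AnnotatedSegment("module", 2, 60)])
        assert out[1].domain_of_life == clean_target.domain_of_life


class TestTriagePipeline:
    def test_mass_elimination_for_tiny_target(self):
        t = random_cds(FixtureSpec(seed=13, n_codons=40, id="tiny"))
        r = triage_target(t)
        assert r.assignment.status == "eliminated_mass"

    def test_restriction_precedes_membrane(self):
        t = random_cds(
            FixtureSpec(seed=14, n_codons=200,
                        implant_sites={"BamHI": [30], "BglII": [40]},
                        tm_segments=[(60, 90), (100, 130), (140, 170)], id="x")
        )
        assert triage_target(t).assignment.status == "eliminated_restriction"
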