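"""Pathway templates, expected through-bond peaks and observed-peak selection."""

import pytest

from shiftassign import (
    ObservedPeak,
    ObservedPeakList,
    ProteinSequence,
    enumerate_atoms,
    expected_peaks_throughbond,
    select_observed_peaks,
    spectrum_definition,
)
from shiftassign.experiments import read_library, write_library


def peaks_as_keys(peaks):
    return [tuple(a.key for a in p.atoms) for p in peaks]


@pytest.fixture
def aaa():
    return enumerate_atoms(ProteinSequence.from_one_letter("AAA"))


class TestSpectrumDefinitions:
    def test_default_tolerances(self):
        sd = spectrum_definition("HNCA")
        assert sd.tolerances == (0.03, 0.4, 0.4)

    def test_aliases(self):
        assert spectrum_definition("[1H,15N]-HSQC").name == "N15HSQC"
        assert spectrum_definition("HCCH-TOCSY").name == "HCCHTOCSY"
        assert spectrum_definition("13C-NOESY").kind == "NOESY"

    def test_unknown_name_lists_supported(self):
        with pytest.raises(KeyError, match="supported"):
            spectrum_definition("HNCACB-FANTASY")

    def test_library_round_trip(self, tmp_path):
        path = tmp_path / "spectra.lib"
        write_library(path, {"strong": 0.93})
        defs, probs = read_library(path)
        assert probs["strong"] == 0.93
        assert defs["HNCA"].kind == "through-bond"
        assert len(defs["N15HSQC"].dimensions) == 2


class TestThroughBondTemplates:
    def test_hnca_on_tripeptide(self, aaa):
        peaks = expected_peaks_throughbond(spectrum_definition("HNCA"), aaa)
        assert peaks_as_keys(peaks) == [
            ((2, "HN"), (2, "N"), (2, "CA")),
            ((2, "HN"), (2, "N"), (1, "CA")),
            ((3, "HN"), (3, "N"), (3, "CA")),
            ((3, "HN"), (3, "N"), (2, "CA")),
        ]
        probs = [p.probability for p in peaks]
        assert probs == [0.95, 0.8, 0.95, 0.8]

    def test_hsqc_skips_terminus_and_proline(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("APA"))
        peaks = expected_peaks_throughbond(spectrum_definition("N15HSQC"), atoms)
        assert peaks_as_keys(peaks) == [((3, "HN"), (3, "N"))]

    def test_cbcaconh_on_glycines_drops_cb(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("GG"))
        peaks = expected_peaks_throughbond(spectrum_definition("CBCACONH"), atoms)
        # glycine has no CB: only the CA(i-1) peak per amide
        assert peaks_as_keys(peaks) == [((2, "HN"), (2, "N"), (1, "CA"))]

    def test_template_closure(self):
        """Every expected peak's atoms exist in the atom set; no proline or
        first-residue HN is ever referenced."""
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("MPAGWPTK"))
        for name in ("N15HSQC", "C13HSQC", "HNCA", "HNCO", "CBCANH",
                     "CBCACONH", "HBHACONH", "HCCONH", "HCCHTOCSY", "CCHTOCSY"):
            for peak in expected_peaks_throughbond(spectrum_definition(name), atoms):
                for a in peak.atoms:
                    assert atoms.get(*a.key) is not None

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_hnca_count_law_against_hand_enumeration(self, n):
        """Proline-free chain: residues 2..n give 2 peaks each except that
        residue 2's sequential partner is residue 1 (which exists), so the
        count is 2(n-1); verified by brute-force enumeration."""
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("A" * n))
        peaks = expected_peaks_throughbond(spectrum_definition("HNCA"), atoms)
        brute = 0
        for i in range(2, n + 1):
            brute += 1  # intra CA(i)
            if i - 1 >= 1:
                brute += 1  # sequential CA(i-1)
        assert len(peaks) == brute

    def test_monotonicity_adding_residues(self):
        """Extending the chain never removes peaks for existing residues."""
        short = enumerate_atoms(ProteinSequence.from_one_letter("MKV"))
        long = enumerate_atoms(ProteinSequence.from_one_letter("MKVLA"))
        sd = spectrum_definition("CBCANH")
        short_keys = set(map(tuple, peaks_as_keys(expected_peaks_throughbond(sd, short))))
        long_keys = set(map(tuple, peaks_as_keys(expected_peaks_throughbond(sd, long))))
        assert short_keys <= long_keys

    def test_noesy_template_rejected(self, aaa):
        with pytest.raises(ValueError, match="through-bond"):
            expected_peaks_throughbond(spectrum_definition("N15NOESY"), aaa)


class TestSelectObservedPeaks:
    def make_list(self, scores, spectrum="HNCA", intensities=None):
        peaks = [
            ObservedPeak(i + 1, (8.0, 120.0, 55.0), s,
                         0.0 if intensities is None else intensities[i])
            for i, s in enumerate(scores)
        ]
        return ObservedPeakList(spectrum, peaks)

    def test_top_k_by_confidence(self):
        plist = self.make_list([0.2, 0.9, 0.5, 0.8, 0.1, 0.7, 0.65, 0.3, 0.4, 0.95])
        kept = select_observed_peaks(plist, expected_count=4)
        assert [p.id for p in kept.peaks] == [2, 4, 6, 10]  # order preserved

    def test_fewer_than_expected_keeps_all(self):
        plist = self.make_list([0.2, 0.4])
        assert len(select_observed_peaks(plist, expected_count=10)) == 2

    def test_noesy_threshold_at_0_1(self):
        plist = self.make_list([0.05, 0.1, 0.95], spectrum="N15NOESY")
        kept = select_observed_peaks(plist)
        assert [p.confidence for p in kept.peaks] == [0.1, 0.95]

    def test_tie_break_intensity_then_id(self):
        plist = self.make_list([0.5, 0.5, 0.5], intensities=[1.0, 3.0, 1.0])
        kept = select_observed_peaks(plist, expected_count=2)
        assert [p.id for p in kept.peaks] == [1, 2]

    def test_missing_expected_count_rejected(self):
        with pytest.raises(ValueError):
            select_observed_peaks(self.make_list([0.5]))

    def test_negative_expected_count_rejected(self):
        with pytest.raises(ValueError):
            select_observed_peaks(self.make_list([0.5]), expected_count=-1)

    def test_empty_list(self):
        assert len(select_observed_peaks(ObservedPeakList("HNCA", []), 5)) == 0
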