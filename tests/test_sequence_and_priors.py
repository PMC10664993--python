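"""Atom enumeration and Gaussian shift priors."""

import pytest

from shiftassign import (
    Atom,
    ProteinSequence,
    enumerate_atoms,
    predicted_priors,
    statistical_priors,
)
from shiftassign.priors import PREDICTED_SD
from shiftassign.sequence import read_fasta, read_seq, write_seq


class TestProteinSequence:
    def test_one_letter_round_trip(self):
        seq = ProteinSequence.from_one_letter("MKVLA")
        assert seq.residues == ("MET", "LYS", "VAL", "LEU", "ALA")
        assert seq.one_letter() == "MKVLA"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ProteinSequence(())

    def test_unknown_code_carries_position(self):
        with pytest.raises(ValueError, match="position 2"):
            ProteinSequence(("ALA", "XXX"))

    def test_numbering(self):
        seq = ProteinSequence.from_one_letter("GA", first_residue_number=5)
        assert list(seq.numbers) == [5, 6]
        assert seq.residue_type(6) == "ALA"


class TestEnumerateAtoms:
    def test_internal_glycine_complement(self):
        # glycine in a chain context: HN, N, CA, HA2, HA3, C
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AGA"))
        names = {a.atom_name for a in atoms.residue_atoms(2)}
        assert names == {"HN", "N", "CA", "HA2", "HA3", "C"}

    def test_proline_and_nterminus_lack_hn(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("APA"))
        assert atoms.get(1, "HN") is None  # N-terminal amide proton excluded
        assert atoms.get(2, "HN") is None  # proline has no amide proton
        assert atoms.get(3, "HN") is not None

    def test_nucleus_labels(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AW"))
        assert atoms[(1, "CA")].nucleus == "13C"
        assert atoms[(2, "NE1")].nucleus == "15N"
        assert atoms[(2, "HE1")].nucleus == "1H"

    def test_atom_name_normalization(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AA"))
        assert atoms.get(2, "H") == atoms.get(2, "HN")
        assert atoms.get(1, "C'") == atoms.get(1, "C")

    @pytest.mark.parametrize("seq_str", ["ACDEFGHIKLMNPQRSTVWY"])
    def test_full_complement_has_priors(self, seq_str):
        """Every assignable atom of every residue type gets exactly one prior."""
        atoms = enumerate_atoms(ProteinSequence.from_one_letter(seq_str))
        priors = statistical_priors(atoms)
        assert len(priors) == len(atoms)
        assert all(p.sd > 0 for p in priors)


class TestStatisticalPriors:
    def test_pass_through_of_table_values(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AA"))
        table = {
            (a.residue_type, a.atom_name): (53.1, 2.0) for a in atoms.atoms
        }
        priors = statistical_priors(atoms, table)
        prior = priors[atoms[(1, "CA")]]
        assert prior.mean == 53.1 and prior.sd == 2.0
        assert prior.source == "statistics"

    def test_missing_entry_names_atom(self):
        from shiftassign.shift_stats import default_statistics

        atoms = enumerate_atoms(ProteinSequence.from_one_letter("W"))
        table = dict(default_statistics())
        del table[("TRP", "NE1")]
        with pytest.raises(KeyError, match="NE1"):
            statistical_priors(atoms, table)


class TestPredictedPriors:
    def test_prediction_overrides_with_default_sd(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AAAAA"))
        target = atoms[(5, "CA")]
        priors = predicted_priors(atoms, [(target, 58.2)])
        assert priors[target].mean == pytest.approx(58.2)
        assert priors[target].sd == pytest.approx(0.77)
        assert priors[target].source == "predicted"

    def test_nitrogen_default_sd(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AAAAA"))
        target = atoms[(5, "N")]
        priors = predicted_priors(atoms, [(target, 119.0)])
        assert priors[target].mean == pytest.approx(119.0)
        assert priors[target].sd == pytest.approx(1.98)

    def test_all_default_sds_match_predictor_rmsd(self):
        assert PREDICTED_SD == {
            "C": 0.85, "CA": 0.77, "CB": 0.86, "HN": 0.39, "HA": 0.20, "N": 1.98,
        }

    def test_empty_predictions_are_a_noop(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("ADA"))
        stat = statistical_priors(atoms)
        pred = predicted_priors(atoms, [], statistical=stat)
        assert all(pred[a].mean == stat[a].mean for a in atoms.atoms)

    def test_side_chain_prediction_rejected(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AW"))
        with pytest.raises(ValueError, match="non-backbone"):
            predicted_priors(atoms, [(atoms[(2, "NE1")], 129.0)])

    def test_substitution_locality(self):
        """Predictions change only the six backbone atom names."""
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("KWD"))
        stat = statistical_priors(atoms)
        preds = [
            (atoms[(n, name)], 50.0)
            for n in (2, 3)
            for name in ("CA", "CB")
        ]
        pred = predicted_priors(atoms, preds, statistical=stat)
        changed = {a.key for a in atoms.atoms if pred[a].mean != stat[a].mean}
        assert changed == {(2, "CA"), (2, "CB"), (3, "CA"), (3, "CB")}


class TestSequenceIO:
    def test_fasta_round_trip(self, tmp_path):
        path = tmp_path / "seq.fasta"
        path.write_text(">protein\nMKVL\nAG\n")
        assert read_fasta(path).one_letter() == "MKVLAG"

    def test_seq_file_round_trip(self, tmp_path):
        seq = ProteinSequence.from_one_letter("MKV", first_residue_number=3)
        path = tmp_path / "p.seq"
        write_seq(seq, path)
        back = read_seq(path)
        assert back == seq

    def test_non_consecutive_numbering_rejected(self, tmp_path):
        path = tmp_path / "bad.seq"
        path.write_text("ALA 1\nGLY 3\n")
        with pytest.raises(ValueError, match="consecutive"):
            read_seq(path)
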