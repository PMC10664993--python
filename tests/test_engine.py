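"""Mapping engine: score definition, optimization, and the exhaustive oracle."""

import numpy as np
import pytest

import shiftassign as sa
from shiftassign import EngineParams, MappingSolution, exhaustive_search, run_single, score
from shiftassign.synthetic import NOISELESS

from conftest import make_problem


def tiny_instance(n_res=3, truth_seed=0, spectra=("N15HSQC",)):
    return make_problem("AKV"[:n_res] if n_res <= 3 else "AKVLG"[:n_res],
                        spectra, truth_seed=truth_seed)


class TestScore:
    def test_empty_mapping_is_minus_lambda_sum_p(self):
        p = tiny_instance()
        params = EngineParams()
        empty = MappingSolution({}, {}, 0.0)
        value = score(empty, p["expected"], p["observed"], p["priors"], params, p["spectra"])
        expected_value = -params.unmapped_penalty * sum(e.probability for e in p["expected"])
        assert value == pytest.approx(expected_value)

    def test_perfect_mapping_at_prior_means(self):
        """All peaks mapped with zero deviation and shifts at prior means:
        score = Σp + β·n_atoms."""
        seq = sa.ProteinSequence.from_one_letter("AK")
        atom_set = sa.enumerate_atoms(seq)
        priors = sa.statistical_priors(atom_set)
        sdef = sa.spectrum_definition("N15HSQC")
        expected = sa.expected_peaks_throughbond(sdef, atom_set)
        # one observed peak exactly at the prior means of the expected atoms
        positions = tuple(priors[a].mean for a in expected[0].atoms)
        observed = {"N15HSQC": sa.ObservedPeakList(
            "N15HSQC", [sa.ObservedPeak(1, positions, 1.0, 1.0)])}
        params = EngineParams()
        sol = MappingSolution({0: 1}, {a.key: priors[a].mean for a in expected[0].atoms}, 0.0)
        value = score(sol, expected, observed, priors, params)
        n_atoms = len(expected[0].atoms)
        assert value == pytest.approx(
            expected[0].probability + params.prior_weight * n_atoms
        )

    def test_infeasible_mapping_rejected(self):
        """Two peaks of the same amide mapped to positions 0.2 ppm apart in
        1H force a shift that violates the 0.03 ppm tolerance for both."""
        seq = sa.ProteinSequence.from_one_letter("AK")
        atom_set = sa.enumerate_atoms(seq)
        priors = sa.statistical_priors(atom_set)
        hsqc = sa.expected_peaks_throughbond(sa.spectrum_definition("N15HSQC"), atom_set)
        hn, n = hsqc[0].atoms
        mu_h, mu_n = priors[hn].mean, priors[n].mean
        observed = {
            "N15HSQC": sa.ObservedPeakList("N15HSQC", [
                sa.ObservedPeak(1, (mu_h, mu_n), 1.0, 1.0),
                sa.ObservedPeak(2, (mu_h + 0.2, mu_n), 1.0, 1.0),
            ])
        }
        bad = MappingSolution({0: 1, 1: 2}, {}, 0.0)
        with pytest.raises(ValueError):
            score(bad, [hsqc[0], hsqc[0]], observed, priors, EngineParams())


class TestRunSingle:
    def test_noiseless_recovery_unique_instance(self):
        """Observed peaks exactly at prior means with all-distinct residue
        types make the instance unique; every touched atom is recovered."""
        seq = sa.ProteinSequence.from_one_letter("AKVLG")
        atom_set = sa.enumerate_atoms(seq)
        priors = sa.statistical_priors(atom_set)
        sdefs = {n: sa.spectrum_definition(n) for n in ("N15HSQC", "HNCA")}
        expected = []
        for n, sd in sdefs.items():
            expected += sa.expected_peaks_throughbond(sd, atom_set)
        truth = {a.key: priors[a].mean for a in atom_set.atoms}
        observed, _ = sa.simulate_peak_lists(expected, truth, NOISELESS, sdefs)
        sol = run_single(expected, observed, priors, EngineParams(seed=1), sdefs)
        assert len(sol.mapping) == len(expected)
        for key, value in sol.shifts.items():
            assert value == pytest.approx(truth[key], abs=1e-6)

    def test_empty_observed_gives_empty_mapping(self):
        p = tiny_instance()
        observed = {k: sa.ObservedPeakList(k, []) for k in p["observed"]}
        sol = run_single(p["expected"], observed, p["priors"], EngineParams(seed=0),
                         p["spectra"])
        assert sol.mapping == {} and sol.shifts == {}

    def test_seeded_determinism(self):
        p = make_problem("AKVL", ("N15HSQC", "HNCA"), truth_seed=5)
        s1 = run_single(p["expected"], p["observed"], p["priors"], EngineParams(seed=9),
                        p["spectra"])
        s2 = run_single(p["expected"], p["observed"], p["priors"], EngineParams(seed=9),
                        p["spectra"])
        assert s1.mapping == s2.mapping
        assert s1.shifts == s2.shifts
        assert s1.score == s2.score

    def test_score_never_below_empty(self):
        p = make_problem("AKVL", ("N15HSQC",), truth_seed=2)
        params = EngineParams(seed=4)
        sol = run_single(p["expected"], p["observed"], p["priors"], params, p["spectra"])
        empty = -params.unmapped_penalty * sum(e.probability for e in p["expected"])
        assert sol.score >= empty

    def test_no_expected_peaks_rejected(self):
        p = tiny_instance()
        with pytest.raises(ValueError):
            run_single([], p["observed"], p["priors"], EngineParams())

    def test_feasibility_of_returned_mapping(self):
        """Every mapped peak respects per-dimension tolerances given the
        returned shifts (re-scored without error)."""
        p = make_problem("AKVLG", ("N15HSQC", "HNCA", "CBCANH"), truth_seed=7)
        params = EngineParams(seed=2)
        sol = run_single(p["expected"], p["observed"], p["priors"], params, p["spectra"])
        value = score(sol, p["expected"], p["observed"], p["priors"], params, p["spectra"])
        assert value == pytest.approx(sol.score, abs=1e-9)


class TestExhaustiveOracle:
    def test_single_peak_two_candidates(self):
        seq = sa.ProteinSequence.from_one_letter("AK")
        atom_set = sa.enumerate_atoms(seq)
        priors = sa.statistical_priors(atom_set)
        sdef = sa.spectrum_definition("N15HSQC")
        expected = sa.expected_peaks_throughbond(sdef, atom_set)[:1]
        mu = [priors[a].mean for a in expected[0].atoms]
        near = sa.ObservedPeak(1, tuple(mu), 1.0, 1.0)
        far = sa.ObservedPeak(2, (mu[0] + 0.5, mu[1] + 3.0), 1.0, 1.0)
        observed = {"N15HSQC": sa.ObservedPeakList("N15HSQC", [near, far])}
        sol = exhaustive_search(expected, observed, priors)
        assert sol.mapping == {0: 1}

    def test_zero_expected_peaks(self):
        p = tiny_instance()
        sol = exhaustive_search([], p["observed"], p["priors"])
        assert sol.mapping == {} and sol.score == 0.0

    def test_too_large_instance_rejected(self):
        p = make_problem("AKVLGAKVLG", ("N15HSQC", "HNCA", "CBCANH"), truth_seed=1)
        with pytest.raises(ValueError, match="too large"):
            exhaustive_search(p["expected"], p["observed"], p["priors"],
                              max_combinations=10)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimality_dominance(self, seed):
        """run_single never exceeds the exhaustive optimum on random small
        instances."""
        p = make_problem("AKV", ("N15HSQC", "HNCA"), truth_seed=seed)
        expected = p["expected"][:6]
        heur = run_single(expected, p["observed"], p["priors"],
                          EngineParams(seed=seed), p["spectra"])
        best = exhaustive_search(expected, p["observed"], p["priors"],
                                 EngineParams(seed=seed), p["spectra"])
        assert heur.score <= best.score + 1e-9

    def test_overlap_capacity_strictly_helps(self):
        """Two expected peaks sharing one observed peak score strictly better
        than under an exclusive mapping."""
        seq = sa.ProteinSequence.from_one_letter("AK")
        atom_set = sa.enumerate_atoms(seq)
        priors = sa.statistical_priors(atom_set)
        sdef = sa.spectrum_definition("N15HSQC")
        base = sa.expected_peaks_throughbond(sdef, atom_set)[0]
        expected = [base, base]  # genuine overlap: identical atom tuples
        mu = tuple(priors[a].mean for a in base.atoms)
        observed = {"N15HSQC": sa.ObservedPeakList(
            "N15HSQC", [sa.ObservedPeak(1, mu, 1.0, 1.0)])}
        shared = exhaustive_search(expected, observed, priors)
        exclusive = exhaustive_search(expected, observed, priors,
                                      allow_shared_observed=False)
        assert shared.score > exclusive.score + 1e-6
        assert len(shared.mapping) == 2
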