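"""Synthetic benchmark generator: shift truths, peak simulation, concatenation."""

import numpy as np
import pytest

import shiftassign as sa
from shiftassign import NoiseModel
from shiftassign.synthetic import Domain, concatenate_domains, NOISELESS
from shiftassign import topology

from conftest import make_problem


class TestSampleTrueShifts:
    def test_seeded_reproducibility(self):
        atoms = sa.enumerate_atoms(sa.ProteinSequence.from_one_letter("MKVLA"))
        priors = sa.statistical_priors(atoms)
        t1 = sa.sample_true_shifts(priors, seed=3)
        t2 = sa.sample_true_shifts(priors, seed=3)
        assert t1 == t2

    def test_values_within_three_sd(self):
        atoms = sa.enumerate_atoms(sa.ProteinSequence.from_one_letter("MKWLAGHED"))
        priors = sa.statistical_priors(atoms)
        truth = sa.sample_true_shifts(priors, seed=1)
        for p in priors:
            assert abs(truth[p.atom.key] - p.mean) <= 3 * p.sd + 1e-9

    def test_monte_carlo_mean(self):
        """Sample mean of repeated draws approaches the prior mean."""
        atoms = sa.enumerate_atoms(sa.ProteinSequence.from_one_letter("AA"))
        priors = sa.statistical_priors(atoms)
        target = atoms[(1, "CA")]
        prior = priors[target]
        draws = [
            sa.sample_true_shifts(priors, seed=s)[target.key] for s in range(400)
        ]
        se = prior.sd / np.sqrt(len(draws))
        assert abs(np.mean(draws) - prior.mean) < 4 * se

    def test_equivalent_protons_share_one_value(self):
        """Methyl protons and aromatic ring-flip pairs carry a single shift."""
        atoms = sa.enumerate_atoms(sa.ProteinSequence.from_one_letter("AVFL"))
        priors = sa.statistical_priors(atoms)
        truth = sa.sample_true_shifts(priors, seed=5)
        assert truth[(1, "HB1")] == truth[(1, "HB2")] == truth[(1, "HB3")]
        assert truth[(2, "HG11")] == truth[(2, "HG13")]
        assert truth[(3, "HD1")] == truth[(3, "HD2")]
        assert truth[(3, "CE1")] == truth[(3, "CE2")]
        # non-equivalent pairs stay independent
        assert truth[(4, "HB2")] != truth[(4, "HB3")]


class TestSimulatePeakLists:
    def test_noiseless_identity(self):
        p = make_problem("AKVLG", ("N15HSQC", "HNCA"), truth_seed=2)
        total = sum(len(v) for v in p["observed"].values())
        assert total == len(p["expected"])
        for sname, plist in p["observed"].items():
            origins = p["truth_map"][sname]
            for peak, ei in zip(plist.peaks, origins):
                e = p["expected"][ei]
                for pos, atom in zip(peak.positions, e.atoms):
                    assert pos == pytest.approx(p["truth"][atom.key], abs=1e-12)

    def test_artifact_rate_binomial_mean(self):
        p = make_problem("AKVLG", ("N15HSQC", "HNCA"))
        counts = []
        for seed in range(60):
            noise = NoiseModel(position_jitter_sd=0.0, detection=False,
                               artifact_rate=0.5, seed=seed)
            obs, tmap = sa.simulate_peak_lists(p["expected"], p["truth"], noise,
                                               p["spectra"])
            counts.append(sum(len(v) for v in obs.values()))
        n_exp = len(p["expected"])
        mean = np.mean(counts)
        se = np.sqrt(n_exp * 0.5 * 0.5 / len(counts))
        assert mean == pytest.approx(1.5 * n_exp, abs=5 * se + 1)

    def test_detection_follows_observation_probability(self):
        p = make_problem("MQIFVKTLTG", ("N15HSQC", "N15NOESY"))
        kept = []
        for seed in range(30):
            noise = NoiseModel(position_jitter_sd=0.0, detection=True,
                               artifact_rate=0.0, seed=seed)
            obs, _ = sa.simulate_peak_lists(p["expected"], p["truth"], noise,
                                            p["spectra"])
            kept.append(sum(len(v) for v in obs.values()))
        expect = sum(e.probability for e in p["expected"])
        assert np.mean(kept) == pytest.approx(expect, rel=0.05)

    def test_truth_map_marks_artifacts(self):
        p = make_problem("AKVLG", ("N15HSQC",))
        noise = NoiseModel(position_jitter_sd=0.0, detection=False,
                           artifact_rate=3.0, seed=4)
        obs, tmap = sa.simulate_peak_lists(p["expected"], p["truth"], noise,
                                           p["spectra"])
        origins = tmap["N15HSQC"]
        n_art = sum(1 for o in origins if o is None)
        assert n_art >= 1
        assert len(origins) == len(obs["N15HSQC"].peaks)

    def test_artifact_scores_lower_on_average(self):
        p = make_problem("MQIFVKTLTG", ("N15HSQC", "HNCA"))
        noise = NoiseModel(position_jitter_sd=0.0, detection=False,
                           artifact_rate=2.0, seed=0)
        obs, tmap = sa.simulate_peak_lists(p["expected"], p["truth"], noise,
                                           p["spectra"])
        true_scores, art_scores = [], []
        for sname, plist in obs.items():
            for peak, origin in zip(plist.peaks, tmap[sname]):
                (true_scores if origin is not None else art_scores).append(peak.confidence)
        assert np.mean(true_scores) > np.mean(art_scores) + 0.3


class TestConcatenateDomains:
    def make_domain(self, seq_str, seed):
        p = make_problem(seq_str, ("N15HSQC", "N15NOESY"), truth_seed=seed,
                         structure_seed=seed)
        return Domain(p["sequence"], p["bundle"], p["truth"], p["observed"])

    def test_two_domains_with_ten_glycine_linker(self):
        d1 = self.make_domain("MQIFVKTLTG" * 5, 1)  # 50 residues
        d2 = self.make_domain("KTITLEVEPSDT" * 5, 2)  # 60 residues
        combined = concatenate_domains([d1, d2])
        assert len(combined.sequence) == 120  # 50 + 10 + 60
        linker = combined.sequence.residues[50:60]
        assert set(linker) == {"GLY"}

    def test_three_domains_two_linkers(self):
        doms = [self.make_domain("MQIFVKTLTG", s) for s in (1, 2, 3)]
        combined = concatenate_domains(doms)
        assert len(combined.sequence) == 3 * 10 + 2 * 10

    def test_merged_peak_lists_are_the_union(self):
        d1 = self.make_domain("MQIFVKTLTG", 1)
        d2 = self.make_domain("AKVLGAKVLG", 2)
        combined = concatenate_domains([d1, d2])
        n = len(combined.peak_lists["N15NOESY"])
        assert n == len(d1.peak_lists["N15NOESY"]) + len(d2.peak_lists["N15NOESY"])
        ids = [p.id for p in combined.peak_lists["N15NOESY"].peaks]
        assert len(set(ids)) == len(ids)

    def test_truth_renumbered_without_collision(self):
        d1 = self.make_domain("MQIFVKTLTG", 1)
        d2 = self.make_domain("AKVLGAKVLG", 2)
        combined = concatenate_domains([d1, d2])
        assert (1, "CA") in combined.truth
        assert (21, "CA") in combined.truth  # first residue of domain 2
        assert len(combined.truth) == len(d1.truth) + len(d2.truth)

    def test_single_domain_rejected(self):
        with pytest.raises(ValueError):
            concatenate_domains([self.make_domain("MQIFVKTLTG", 1)])

    def test_size_limit_enforced(self):
        doms = [self.make_domain("MQIFVKTLTG" * 5, s) for s in (1, 2)]
        with pytest.raises(ValueError, match="exceeds"):
            concatenate_domains(doms, max_residues=100)

    def test_combined_bundle_is_clash_free_across_domains(self):
        from shiftassign.geometry import clash_score

        d1 = self.make_domain("MQIFVKTLTG", 1)
        d2 = self.make_domain("AKVLGAKVLG", 2)
        combined = concatenate_domains([d1, d2])
        conf = combined.bundle.conformers[0]
        intra1 = clash_score(d1.bundle.conformers[0])
        total = clash_score(conf)
        # concatenation adds no inter-domain clashes beyond the parts' own
        intra2 = clash_score(d2.bundle.conformers[0])
        assert total <= intra1 + intra2 + 2  # linker may graze its neighbours
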