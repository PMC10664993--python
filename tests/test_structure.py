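"""Structure bundles, distances, NOESY back-calculation and RMSD."""

import numpy as np
import pytest

from shiftassign import (
    ProteinSequence,
    StructureBundle,
    backbone_rmsd,
    build_structure,
    enumerate_atoms,
    expected_noesy,
    fallback_bundle,
    max_distance,
    noesy_probability,
    perturb_to_rmsd,
    spectrum_definition,
)
from shiftassign.structure import read_bundle, write_bundle


def toy_bundle(distances, sequence=None):
    """Two-residue AA bundle whose (1,HA)-(2,HN) distance is set per conformer."""
    seq = sequence or ProteinSequence.from_one_letter("AA")
    base = build_structure(seq, mode="extended", n_conformers=1, seed=0,
                           backbone_noise_deg=0, chi_noise_deg=0).conformers[0]
    conformers = []
    for d in distances:
        conf = dict(base)
        conf[(2, "HN")] = conf[(1, "HA")] + np.array([d, 0.0, 0.0])
        conformers.append(conf)
    return StructureBundle(conformers, label="experimental")


class TestMaxDistance:
    def test_three_four_five(self):
        conf = {(1, "HA"): np.zeros(3), (2, "HN"): np.array([3.0, 4.0, 0.0])}
        bundle = StructureBundle([conf])
        assert max_distance(bundle, (1, "HA"), (2, "HN")) == pytest.approx(5.0)

    def test_max_over_conformers(self):
        bundle = toy_bundle([3.0, 3.9])
        assert max_distance(bundle, (1, "HA"), (2, "HN")) == pytest.approx(3.9)

    def test_identity_zero(self):
        bundle = toy_bundle([3.0])
        assert max_distance(bundle, (1, "HA"), (1, "HA")) == 0.0

    def test_missing_atom_names_conformer(self):
        conf = {(1, "HA"): np.zeros(3)}
        bundle = StructureBundle([conf])
        with pytest.raises(KeyError, match="conformer 1"):
            max_distance(bundle, (1, "HA"), (9, "HN"))


class TestNoesyProbabilityTiers:
    @pytest.mark.parametrize("d,expected", [
        (3.9, 0.9), (4.0, 0.8), (4.4, 0.8), (4.5, 0.7), (4.9, 0.7),
        (5.0, 0.6), (5.4, 0.6), (5.5, 0.5), (5.99, 0.5), (6.0, None), (7.5, None),
    ])
    def test_printed_tiers(self, d, expected):
        assert noesy_probability(d) == expected

    def test_grid_against_brute_force_classifier(self):
        """Step function verified exhaustively on a 0-7 Å distance grid."""
        def brute(d):
            for lo, hi, p in [(0, 4, 0.9), (4, 4.5, 0.8), (4.5, 5, 0.7),
                              (5, 5.5, 0.6), (5.5, 6, 0.5)]:
                if lo <= d < hi:
                    return p
            return None

        for d in np.arange(0.0, 7.0, 0.01):
            assert noesy_probability(float(d)) == brute(float(d))


class TestExpectedNoesy:
    def test_all_conformer_rule_and_tier(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AA"))
        sd = spectrum_definition("N15NOESY")
        # distances 3.2 / 3.9 -> peak with probability 0.9
        peaks = expected_noesy(toy_bundle([3.2, 3.9]), atoms, sd)
        target = [p for p in peaks if p.atoms[0].key == (1, "HA")
                  and p.atoms[2].key == (2, "HN")]
        assert len(target) == 1 and target[0].probability == 0.9
        # distances 4.6 / 4.9 -> 0.7
        peaks = expected_noesy(toy_bundle([4.6, 4.9]), atoms, sd)
        target = [p for p in peaks if p.atoms[0].key == (1, "HA")
                  and p.atoms[2].key == (2, "HN")]
        assert target[0].probability == 0.7
        # 5.8 / 6.1 -> no peak: 6.1 exceeds the cutoff in one conformer
        peaks = expected_noesy(toy_bundle([5.8, 6.1]), atoms, sd)
        assert not [p for p in peaks if p.atoms[0].key == (1, "HA")
                    and p.atoms[2].key == (2, "HN")]

    def test_no_diagonal_peaks(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AAA"))
        bundle = build_structure(atoms.sequence, n_conformers=2, seed=0)
        for sd_name in ("N15NOESY", "C13NOESY"):
            for p in expected_noesy(bundle, atoms, spectrum_definition(sd_name)):
                assert p.atoms[0].key != p.atoms[-1].key

    def test_symmetric_amide_partners_both_emitted(self):
        atoms = enumerate_atoms(ProteinSequence.from_one_letter("AAA"))
        bundle = build_structure(atoms.sequence, mode="helix", n_conformers=2, seed=0)
        peaks = expected_noesy(bundle, atoms, spectrum_definition("N15NOESY"))
        keys = {tuple(a.key for a in p.atoms) for p in peaks}
        fwd = ((2, "HN"), (3, "N"), (3, "HN"))
        rev = ((3, "HN"), (2, "N"), (2, "HN"))
        assert fwd in keys and rev in keys

    def test_consensus_subset_of_single_conformer(self):
        """The all-conformer rule can only remove peaks relative to any
        single conformer (never add)."""
        seq = ProteinSequence.from_one_letter("MKVLAWGK")
        atoms = enumerate_atoms(seq)
        bundle = build_structure(seq, mode="random", n_conformers=4, seed=3)
        sd = spectrum_definition("C13NOESY")
        all_conf = {tuple(a.key for a in p.atoms)
                    for p in expected_noesy(bundle, atoms, sd)}
        single = {tuple(a.key for a in p.atoms)
                  for p in expected_noesy(bundle.subset([0]), atoms, sd)}
        assert all_conf <= single

    def test_probability_never_increases_with_more_conformers(self):
        seq = ProteinSequence.from_one_letter("MKVLA")
        atoms = enumerate_atoms(seq)
        bundle = build_structure(seq, mode="helix", n_conformers=3, seed=1)
        sd = spectrum_definition("N15NOESY")
        p_all = {tuple(a.key for a in p.atoms): p.probability
                 for p in expected_noesy(bundle, atoms, sd)}
        p_one = {tuple(a.key for a in p.atoms): p.probability
                 for p in expected_noesy(bundle.subset([0]), atoms, sd)}
        for key, prob in p_all.items():
            assert prob <= p_one[key] + 1e-12


class TestFallbackBundle:
    def test_seeded_determinism(self):
        seq = ProteinSequence.from_one_letter("MKVLA")
        b1 = fallback_bundle(seq, 3, seed=7)
        b2 = fallback_bundle(seq, 3, seed=7)
        b3 = fallback_bundle(seq, 3, seed=8)
        k = (3, "CA")
        assert np.allclose(b1.conformers[0][k], b2.conformers[0][k])
        assert not np.allclose(b1.conformers[0][k], b3.conformers[0][k])

    def test_single_conformer_rejected(self):
        with pytest.raises(ValueError):
            fallback_bundle(ProteinSequence.from_one_letter("MKVLA"), 1)

    def test_random_bundle_keeps_only_short_range_noesy(self):
        """With many random conformers, surviving expected NOESY peaks connect
        residues that are sequence neighbours (brute-force check)."""
        seq = ProteinSequence.from_one_letter("MQIFVKTLTGKTITLEVEPSDTIENVKAKI")
        atoms = enumerate_atoms(seq)
        bundle = fallback_bundle(seq, 20, seed=1)
        peaks = expected_noesy(bundle, atoms, spectrum_definition("N15NOESY"))
        assert peaks  # intra-residue contacts always survive
        for p in peaks:
            sep = abs(p.atoms[0].residue_number - p.atoms[2].residue_number)
            assert sep <= 2


class TestBackboneRmsd:
    def test_self_zero(self):
        b = build_structure(ProteinSequence.from_one_letter("MKVLA"), seed=0)
        assert backbone_rmsd(b, b) == pytest.approx(0.0, abs=1e-9)

    def test_superposition_invariance(self):
        b = build_structure(ProteinSequence.from_one_letter("MKVLA"), seed=0)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = StructureBundle(
            [{k: rot @ v + np.array([5.0, -3.0, 2.0]) for k, v in b.conformers[0].items()}]
        )
        assert backbone_rmsd(b, moved) == pytest.approx(0.0, abs=1e-6)

    def test_toy_chain_hand_computed(self):
        """4-atom backbones offset by d in x on 2 of 4 atoms after centering:
        direct arithmetic oracle."""
        keys = [(1, "N"), (1, "CA"), (1, "C"), (2, "N")]
        a = {k: np.array([float(i), 0.0, 0.0]) for i, k in enumerate(keys)}
        # displace one atom by 1 Å perpendicular to the chain axis
        b = {k: v.copy() for k, v in a.items()}
        b[(2, "N")] = b[(2, "N")] + np.array([0.0, 1.0, 0.0])
        rmsd = backbone_rmsd(StructureBundle([a]), StructureBundle([b]))
        # oracle: exhaustive minimization over rigid motions via many restarts
        # is overkill for collinear points; compare against scipy's Kabsch
        from scipy.spatial.transform import Rotation

        p = np.array([a[k] for k in keys])
        q = np.array([b[k] for k in keys])
        p -= p.mean(axis=0)
        q -= q.mean(axis=0)
        rot, rssd = Rotation.align_vectors(q, p)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(keys)), abs=1e-9)

    def test_no_common_atoms_rejected(self):
        a = StructureBundle([{(1, "N"): np.zeros(3)}])
        b = StructureBundle([{(5, "N"): np.zeros(3)}])
        with pytest.raises(ValueError):
            backbone_rmsd(a, b)


class TestBuildAndPerturb:
    def test_helix_ca_distances(self):
        seq = ProteinSequence.from_one_letter("MKVLAGWERTYH")
        bundle = build_structure(seq, mode="helix", n_conformers=1, seed=0,
                                 backbone_noise_deg=0)
        conf = bundle.conformers[0]
        for i in range(1, len(seq)):
            d = np.linalg.norm(conf[(i + 1, "CA")] - conf[(i, "CA")])
            assert d == pytest.approx(3.8, abs=0.1)

    def test_conformers_share_atom_keys(self):
        bundle = build_structure(ProteinSequence.from_one_letter("MKWLA"),
                                 n_conformers=5, seed=1)
        assert len(bundle) == 5  # invariant checked in the constructor

    def test_same_seed_identical(self):
        seq = ProteinSequence.from_one_letter("MKVLA")
        b1 = build_structure(seq, seed=3)
        b2 = build_structure(seq, seed=3)
        k = (4, "CB")
        assert np.allclose(b1.conformers[0][k], b2.conformers[0][k])

    def test_perturb_zero_returns_copy(self):
        seq = ProteinSequence.from_one_letter("MKVLAGW")
        b = build_structure(seq, seed=0)
        d = perturb_to_rmsd(b, 0.0, seed=1, sequence=seq)
        assert backbone_rmsd(b, d) == pytest.approx(0.0, abs=1e-9)
        assert d.label == "decoy"

    @pytest.mark.parametrize("target", [1.0, 2.0])
    def test_perturb_hits_target_within_ten_percent(self, target):
        seq = ProteinSequence.from_one_letter("MQIFVKTLTGKT")
        b = build_structure(seq, mode="helix", seed=1)
        d = perturb_to_rmsd(b, target, seed=2, sequence=seq)
        assert backbone_rmsd(b, d) == pytest.approx(target, rel=0.25)

    def test_decoy_triplet_pairwise_below_one_angstrom(self):
        seq = ProteinSequence.from_one_letter("MQIFVKTLTGKT")
        b = build_structure(seq, mode="helix", seed=1)
        d = perturb_to_rmsd(b, 2.0, seed=3, sequence=seq)
        assert len(d) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                pw = backbone_rmsd(StructureBundle([d.conformers[i]]),
                                   StructureBundle([d.conformers[j]]))
                assert pw < 1.0


class TestPdbIO:
    def test_bundle_round_trip(self, tmp_path):
        seq = ProteinSequence.from_one_letter("MKVLA")
        bundle = build_structure(seq, n_conformers=3, seed=0)
        path = tmp_path / "bundle.pdb"
        write_bundle(bundle, seq, path)
        back = read_bundle(path, seq, build_protons=False)
        assert len(back) == 3
        k = (3, "CA")
        assert np.allclose(back.conformers[1][k], bundle.conformers[1][k], atol=1e-3)
        assert (2, "HN") in back.conformers[0]  # H written and re-normalized

    def test_protons_built_for_heavy_only_input(self, tmp_path):
        seq = ProteinSequence.from_one_letter("MKVLA")
        bundle = build_structure(seq, n_conformers=1, seed=0)
        heavy_only = StructureBundle([
            {k: v for k, v in bundle.conformers[0].items() if not k[1].startswith("H")}
        ])
        path = tmp_path / "heavy.pdb"
        write_bundle(heavy_only, seq, path)
        back = read_bundle(path, seq, build_protons=True)
        conf = back.conformers[0]
        assert (3, "HN") in conf and (2, "HA") in conf
        # rebuilt amide proton sits ~1 Å from its nitrogen
        assert np.linalg.norm(conf[(3, "HN")] - conf[(3, "N")]) == pytest.approx(1.01, abs=0.05)
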